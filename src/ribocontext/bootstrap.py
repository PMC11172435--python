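"""Gene-level bootstrap machinery shared by the codon and density analyses.

The resampling unit is always the gene: each bootstrap replicate draws
``n_genes`` genes with replacement (multiplicity honored) and recomputes the
pooled statistic from the resampled genes' codon-level tallies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class BootstrapResult:
    """Observed statistic plus its gene-bootstrap distribution summary.

    ``threshold_low``/``threshold_high`` are the two-tailed quantiles of the
    bootstrap distribution at the configured level (``alpha``).  The p-value
    uses the add-one estimator (see :func:`two_tailed_p`) and is capped at 1.
    """

    observed_stat: float
    p_two_tailed: float
    n_boot: int
    seed: int | None
    boot_mean: float
    boot_sd: float
    threshold_low: float
    threshold_high: float
    alpha: float = 0.01
    method: str = "percentile"
    warning: str | None = None

    def __post_init__(self):
        if not (0.0 < self.p_two_tailed <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")


def two_tailed_p(boot: np.ndarray, obs: float) -> float:
    """Small-sample-safe two-tailed bootstrap p-value.

    ``p = 2 * min[(1 + #{boot >= obs}) / (n + 1), (1 + #{boot <= obs}) / (n + 1)]``
    capped at 1; non-finite bootstrap replicates are discarded first.
    """
    boot = np.asarray(boot, dtype=float)
    boot = boot[np.isfinite(boot)]
    n = boot.size
    if n == 0:
        return 1.0
    ge = int(np.sum(boot >= obs))
    le = int(np.sum(boot <= obs))
    p = 2.0 * min((1 + ge) / (n + 1), (1 + le) / (n + 1))
    return min(p, 1.0)


def gene_multiplicities(
    rng: np.random.Generator, n_genes: int, n_boot: int, chunk: int = 2000
):
    """Yield (chunk, n_genes) multiplicity matrices for gene resampling.

    Each row is a draw of ``n_genes`` genes with replacement, encoded as
    per-gene multiplicities (rows sum to ``n_genes``).
    """
    p = np.full(n_genes, 1.0 / n_genes)
    done = 0
    while done < n_boot:
        size = min(chunk, n_boot - done)
        yield rng.multinomial(n_genes, p, size=size).astype(np.float64)
        done += size


def summarize(
    boot: np.ndarray,
    obs: float,
    p: float,
    *,
    n_boot: int,
    seed: int | None,
    alpha: float = 0.01,
    method: str = "percentile",
    warning: str | None = None,
) -> BootstrapResult:
    boot = np.asarray(boot, dtype=float)
    finite = boot[np.isfinite(boot)]
    if finite.size:
        lo, hi = np.quantile(finite, [alpha / 2, 1 - alpha / 2])
        mean, sd = float(finite.mean()), float(finite.std(ddof=1)) if finite.size > 1 else 0.0
    else:
        lo = hi = mean = sd = float("nan")
    return BootstrapResult(
        observed_stat=float(obs),
        p_two_tailed=float(p),
        n_boot=int(n_boot),
        seed=seed,
        boot_mean=float(mean),
        boot_sd=float(sd),
        threshold_low=float(lo),
        threshold_high=float(hi),
        alpha=alpha,
        method=method,
        warning=warning,
    )
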