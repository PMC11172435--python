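"""A-site codon context annotation and the +1 GNN density comparison.

For every sense A-site codon with a defined +1 codon inside the same ORF,
the normalized density is tabulated together with the +1 codon and a flag
for whether the +1 codon starts with G.  Per codon type, the mean density
of instances followed by +1 GNN is compared with the mean of instances not
followed by +1 GNN, with gene-bootstrap inference (genes resampled with
replacement; codon instances pool with equal weight).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bootstrap import gene_multiplicities, two_tailed_p
from .codons import CODON_STRS, STOP_CODONS, codon_to_index, density_group
from .density import CodonDensityMatrix
from .io import OrfSet

logger = logging.getLogger(__name__)

DENSITY_GROUPS = ("NNU(G34)", "NNU(I34)", "NNC", "NNA", "NNG")


@dataclass
class ContextComparison:
    """Density comparison for one A-site codon type: with vs without +1 GNN."""

    asite_codon_type: str
    rfp_class: str
    n_with: int
    n_without: int
    mean_with: float
    mean_without: float
    ratio: float
    percent_elevation: float
    p_two_tailed: float
    n_boot: int
    seed: int | None
    n_genes: int
    flag: str | None = None

    @property
    def two_nt_label(self) -> str:
        return self.asite_codon_type[:2]


def annotate_contexts(
    matrix: CodonDensityMatrix,
    orfs: OrfSet,
    exclude_edge: int = 1,
    keep_stop_next: bool = True,
) -> pd.DataFrame:
    """Codon-instance table (gene, codon_index, asite_codon, plus1_codon,
    gnn_flag, stop_next, density).

    One row per sense A-site codon with a +1 codon inside the same ORF.
    Stop codons never appear as A-site rows; rows whose +1 codon is the stop
    codon are flagged and by default retained (they fall in the "without
    GNN" group since no stop codon starts with G).  The first and last
    ``exclude_edge`` codons of each ORF are excluded.
    """
    stop_mask = np.zeros(64, dtype=bool)
    for s in STOP_CODONS:
        stop_mask[codon_to_index(s)] = True
    gnn_mask = np.zeros(64, dtype=bool)
    gnn_mask[32:48] = True  # codons whose first nucleotide is G

    parts = []
    for gene in matrix:
        if gene not in orfs:
            raise ValueError(f"gene {gene!r} missing from ORF set")
        codons = orfs.codons(gene)
        vec = matrix[gene]
        if vec.size != codons.size:
            raise ValueError(f"density vector length mismatch for gene {gene!r}")
        K = codons.size
        lo, hi = exclude_edge, K - max(exclude_edge, 1)
        if hi <= lo:
            continue
        i = np.arange(lo, hi)
        keep = ~stop_mask[codons[i]]
        if not keep_stop_next:
            keep &= ~stop_mask[codons[i + 1]]
        i = i[keep]
        if i.size == 0:
            continue
        parts.append(
            pd.DataFrame(
                {
                    "gene": gene,
                    "codon_index": i,
                    "asite_codon": CODON_STRS[codons[i]],
                    "plus1_codon": CODON_STRS[codons[i + 1]],
                    "gnn_flag": gnn_mask[codons[i + 1]],
                    "stop_next": stop_mask[codons[i + 1]],
                    "density": vec[i],
                }
            )
        )
    if not parts:
        cols = ["gene", "codon_index", "asite_codon", "plus1_codon",
                "gnn_flag", "stop_next", "density"]
        return pd.DataFrame(columns=cols)
    return pd.concat(parts, ignore_index=True)


def _per_gene_group_stats(sub: pd.DataFrame) -> pd.DataFrame:
    """Per-gene (sum, n) of densities with and without +1 GNN."""
    agg = sub.groupby(["gene", "gnn_flag"])["density"].agg(["sum", "count"])
    agg = agg.unstack("gnn_flag")
    out = pd.DataFrame(index=agg.index)
    for flag, label in ((True, "w"), (False, "wo")):
        out[f"sum_{label}"] = agg.get(("sum", flag), pd.Series(0.0, index=agg.index)).fillna(0.0)
        out[f"n_{label}"] = agg.get(("count", flag), pd.Series(0.0, index=agg.index)).fillna(0.0)
    return out


def context_comparison(
    instances: pd.DataFrame,
    asite_codon_type: str,
    rfp_class: str,
    n_boot: int = 10000,
    seed: int | None = None,
    method: str = "percentile",
) -> ContextComparison:
    """Compare mean normalized density with vs without +1 GNN for one type.

    Observed means pool codon instances with equal weight.  The bootstrap
    resamples genes with replacement; with the default ``"percentile"``
    method the with-minus-without mean difference is recomputed per
    resample and 0 is located two-tailed in that distribution.  The
    ``"null-band"`` method instead locates the observed with-GNN mean in
    the bootstrap distribution of without-GNN means.  Degenerate inputs
    (fewer than 2 genes contributing both groups) yield p = 1 and a flag.
    """
    key = asite_codon_type.upper().replace("T", "U")
    if len(key) == 3:
        sub = instances[instances["asite_codon"] == key]
    elif len(key) == 2:
        sub = instances[instances["asite_codon"].str.startswith(key)]
    else:
        raise ValueError(f"invalid codon type: {asite_codon_type!r}")

    def _degenerate(flag: str, n_w=0, n_wo=0, m_w=np.nan, m_wo=np.nan, n_genes=0):
        ratio = m_w / m_wo if (np.isfinite(m_wo) and m_wo > 0) else np.nan
        return ContextComparison(
            key, rfp_class, int(n_w), int(n_wo), float(m_w), float(m_wo),
            float(ratio), float(100.0 * (ratio - 1.0)) if np.isfinite(ratio) else np.nan,
            1.0, n_boot, seed, n_genes, flag=flag,
        )

    if len(sub) == 0:
        return _degenerate("no instances")
    per_gene = _per_gene_group_stats(sub)
    t = per_gene.to_numpy(dtype=float)  # columns sum_w, n_w, sum_wo, n_wo
    pooled = t.sum(axis=0)
    n_w, n_wo = pooled[1], pooled[3]
    m_w = pooled[0] / n_w if n_w > 0 else np.nan
    m_wo = pooled[2] / n_wo if n_wo > 0 else np.nan
    both = int(np.sum((t[:, 1] > 0) & (t[:, 3] > 0)))
    n_genes = len(per_gene)
    if n_w == 0 or n_wo == 0 or both < 2 or n_genes < 2:
        return _degenerate("insufficient instances", n_w, n_wo, m_w, m_wo, n_genes)

    rng = np.random.default_rng(seed)
    boot_w = np.empty(n_boot)
    boot_wo = np.empty(n_boot)
    done = 0
    for m in gene_multiplicities(rng, n_genes, n_boot):
        r = m @ t
        with np.errstate(invalid="ignore", divide="ignore"):
            boot_w[done : done + len(r)] = np.where(r[:, 1] > 0, r[:, 0] / r[:, 1], np.nan)
            boot_wo[done : done + len(r)] = np.where(r[:, 3] > 0, r[:, 2] / r[:, 3], np.nan)
        done += len(r)
    if method == "percentile":
        p = two_tailed_p(boot_w - boot_wo, 0.0)
    elif method == "null-band":
        p = two_tailed_p(boot_wo, m_w)
    else:
        raise ValueError(f"unknown method: {method!r}")
    ratio = m_w / m_wo
    return ContextComparison(
        key, rfp_class, int(n_w), int(n_wo), float(m_w), float(m_wo),
        float(ratio), float(100.0 * (ratio - 1.0)), float(p),
        n_boot, seed, n_genes,
    )


def context_comparisons(
    instances: pd.DataFrame,
    rfp_class: str,
    codon_types: list[str] | None = None,
    n_boot: int = 10000,
    seed: int | None = None,
    method: str = "percentile",
) -> list[ContextComparison]:
    """Run :func:`context_comparison` for many codon types.

    Each type gets an independent, type-keyed RNG substream so results do
    not depend on the order or subset of types requested.
    """
    if codon_types is None:
        codon_types = sorted(instances["asite_codon"].unique())
    out = []
    for ct in codon_types:
        sub_seed = None if seed is None else [seed, codon_to_index(ct)]
        out.append(
            context_comparison(
                instances, ct, rfp_class, n_boot=n_boot, seed=sub_seed, method=method
            )
        )
    return out


def comparisons_frame(comparisons) -> pd.DataFrame:
    """Tabular view of a ContextComparison collection (stable column order)."""
    cols = [
        "asite_codon_type", "two_nt_label", "rfp_class", "n_with", "n_without",
        "mean_with", "mean_without", "ratio", "percent_elevation",
        "p_two_tailed", "n_boot", "n_genes", "flag",
    ]
    rows = []
    for c in comparisons:
        rows.append(
            [
                c.asite_codon_type, c.two_nt_label, c.rfp_class, c.n_with,
                c.n_without, c.mean_with, c.mean_without, c.ratio,
                c.percent_elevation, c.p_two_tailed, c.n_boot, c.n_genes,
                c.flag if c.flag is not None else "",
            ]
        )
    return pd.DataFrame(rows, columns=cols)


def class_summary(
    comparisons_21: list[ContextComparison],
    comparisons_28: list[ContextComparison],
) -> pd.DataFrame:
    """Group percent elevations into codon classes and compare RFP classes.

    Codon types map to {NNU(G34), NNU(I34), NNC, NNA, NNG} via the decoding
    classification; per group, distribution summaries of percent_elevation
    are reported for each footprint class together with a Welch two-sample
    two-tailed t-test between the 21-nt and 28-nt elevations.  Groups with
    fewer than 2 codon types in either class raise.
    """

    def _group_values(comps):
        values: dict[str, list[float]] = {}
        for c in comps:
            if len(c.asite_codon_type) != 3 or not np.isfinite(c.percent_elevation):
                continue
            g = density_group(c.asite_codon_type)
            values.setdefault(g, []).append(c.percent_elevation)
        return values

    v21 = _group_values(comparisons_21)
    v28 = _group_values(comparisons_28)
    rows = []
    for group in DENSITY_GROUPS:
        a, b = v21.get(group, []), v28.get(group, [])
        if not a and not b:
            continue
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                f"group {group!r} has fewer than 2 codon types in one RFP class"
            )
        a_arr, b_arr = np.array(a), np.array(b)
        tt = stats.ttest_ind(a_arr, b_arr, equal_var=False)
        q21 = np.percentile(a_arr, [25, 50, 75])
        q28 = np.percentile(b_arr, [25, 50, 75])
        rows.append(
            [
                group, len(a), len(b), a_arr.mean(), b_arr.mean(),
                q21[0], q21[1], q21[2], q28[0], q28[1], q28[2],
                float(tt.statistic), float(tt.pvalue),
            ]
        )
    if not rows:
        raise ValueError("no codon groups with data")
    return pd.DataFrame(
        rows,
        columns=[
            "group", "n_types_21nt", "n_types_28nt",
            "mean_elev_21nt", "mean_elev_28nt",
            "q25_21nt", "median_21nt", "q75_21nt",
            "q25_28nt", "median_28nt", "q75_28nt",
            "t_statistic", "t_p_two_tailed",
        ],
    )
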