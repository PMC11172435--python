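"""Model/Results front ends for the two analyses.

``CodonAdjacencyModel`` fits codon-composition statistics on an ORF set:
background nucleotide frequencies, the unconditional and the
adjacency-conditioned position weight matrices, the G1-weight gene
bootstrap and the NNU/NNC abundance test.

``RiboDensityModel`` fits the footprint pipeline: offset calibration, gene
filtering, per-codon density aggregation and normalization, context
annotation, and per-codon-type with/without +1 GNN comparisons.

Both ``fit`` methods return a Results object carrying the estimates, their
bootstrap uncertainty and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import codon_analysis as ca
from . import context as ctx
from . import density as dn
from .bootstrap import BootstrapResult
from .io import ExpressionMap, FootprintCounts, OrfSet, read_footprint_table, read_orf_fasta
from .pwm import Pwm, NucFreqs, adjacency_pwm, background_frequencies, positional_weight_matrix


class CodonAdjacencyModel:
    """Codon adjacency statistics for an ORF set.

    Parameters
    ----------
    orfs : OrfSet
        Coding sequences.
    reference : str
        Codon-class pattern conditioning the adjacency PWM (default "NNU").
    expression : ExpressionMap, optional
        If given, ``fit`` also reports results for the top/bottom
        expression strata.
    """

    def __init__(self, orfs: OrfSet, reference: str = "NNU",
                 expression: ExpressionMap | None = None,
                 stratify_fraction: float = 0.10):
        self.orfs = orfs
        self.reference = reference
        self.expression = expression
        self.stratify_fraction = stratify_fraction

    @classmethod
    def from_fasta(cls, path, reference: str = "NNU", **kwargs) -> "CodonAdjacencyModel":
        return cls(read_orf_fasta(path), reference=reference, **kwargs)

    def fit(self, n_boot: int = 10000, seed: int | None = None,
            method: str = "percentile") -> "CodonAdjacencyResults":
        orfs = self.orfs
        background = background_frequencies(orfs)
        pwm_all = positional_weight_matrix(orfs)
        pwm_cond = adjacency_pwm(orfs, self.reference)
        g1 = ca.g1_weight_bootstrap(
            orfs, self.reference, n_boot=n_boot, seed=seed, method=method
        )
        abundance = ca.nnu_nnc_abundance_test(orfs, n_boot=n_boot, seed=seed)
        strata = {}
        if self.expression is not None:
            top, bottom = ca.stratify_by_expression(
                orfs, self.expression, self.stratify_fraction
            )
            for name, sub in (("top", top), ("bottom", bottom)):
                strata[name] = {
                    "pwm_all": positional_weight_matrix(sub),
                    "pwm_conditional": adjacency_pwm(sub, self.reference),
                }
        return CodonAdjacencyResults(
            model=self, background=background, pwm_all=pwm_all,
            pwm_conditional=pwm_cond, g1_test=g1, abundance_test=abundance,
            strata=strata,
        )


@dataclass
class CodonAdjacencyResults:
    model: CodonAdjacencyModel
    background: NucFreqs
    pwm_all: Pwm
    pwm_conditional: Pwm
    g1_test: BootstrapResult
    abundance_test: BootstrapResult
    strata: dict = field(default_factory=dict)

    @property
    def delta_g1_weight(self) -> float:
        """Conditional minus unconditional position-1 G weight."""
        return self.pwm_conditional.weight(1, "G") - self.pwm_all.weight(1, "G")

    def summary(self) -> str:
        m = self.model
        bg = self.background
        lines = [
            "Codon adjacency analysis",
            "=" * 60,
            f"genes: {len(m.orfs)}   codons: {m.orfs.total_codons()}",
            f"background freqs  A={bg.f_A:.3f} C={bg.f_C:.3f} "
            f"G={bg.f_G:.3f} U={bg.f_U:.3f}",
            f"reference class: {m.reference}",
            f"G1 weight (all codons):        {self.pwm_all.weight(1, 'G'): .4f}",
            f"G1 weight (after {m.reference}):       "
            f"{self.pwm_conditional.weight(1, 'G'): .4f}",
            f"delta G1 weight:               {self.delta_g1_weight: .4f}",
            f"G1 bootstrap p (two-tailed):   {self.g1_test.p_two_tailed:.4g}"
            f"   [{self.g1_test.method}, n_boot={self.g1_test.n_boot}]",
            f"NNU-NNC abundance statistic:   {self.abundance_test.observed_stat: .5f}"
            f"   p={self.abundance_test.p_two_tailed:.4g}",
        ]
        return "\n".join(lines)


class RiboDensityModel:
    """A-site codon density pipeline for one footprint class.

    Parameters
    ----------
    counts : FootprintCounts
        Footprint 5'-end counts.
    orfs : OrfSet
        Matching coding sequences.
    rfp_class : str
        "28nt" (27-30 nt reads) or "21nt" (20-22 nt reads).
    offsets : "default" | "auto" | OffsetTable
        A-site offsets per read length; "auto" calibrates from the data.
    min_len_nt, min_density : gene filters (strict inequalities).
    exclude_edge : int
        Codons trimmed from each ORF end before context statistics.
    deblur : callable, optional
        Hook applied to the counts before any processing
        (``FootprintCounts -> FootprintCounts``).  The default is the
        identity; externally deblurred tables can be substituted here.
    """

    def __init__(
        self,
        counts: FootprintCounts,
        orfs: OrfSet,
        rfp_class: str = "28nt",
        offsets="default",
        min_len_nt: int = 198,
        min_density: float = 0.1,
        exclude_edge: int = 1,
        keep_stop_next: bool = True,
        deblur=None,
    ):
        if deblur is not None:
            counts = deblur(counts)
        self.counts = counts
        self.orfs = orfs
        self.rfp_class = rfp_class
        self.offsets = offsets
        self.min_len_nt = min_len_nt
        self.min_density = min_density
        self.exclude_edge = exclude_edge
        self.keep_stop_next = keep_stop_next

    @classmethod
    def from_files(cls, fasta_path, counts_path, **kwargs) -> "RiboDensityModel":
        return cls(read_footprint_table(counts_path), read_orf_fasta(fasta_path), **kwargs)

    def _resolve_offsets(self) -> dn.OffsetTable:
        if isinstance(self.offsets, dn.OffsetTable):
            return self.offsets
        if self.offsets == "default":
            return dn.OffsetTable.default(self.rfp_class)
        if self.offsets == "auto":
            return dn.calibrate_offsets(self.counts, self.orfs, self.rfp_class)
        raise ValueError(f"offsets must be 'default', 'auto' or an OffsetTable")

    def fit(
        self,
        n_boot: int = 10000,
        seed: int | None = None,
        codon_types: list[str] | None = None,
        method: str = "percentile",
    ) -> "RiboDensityResults":
        offsets = self._resolve_offsets()
        report, retained = dn.filter_genes(
            self.counts, self.orfs, self.rfp_class,
            self.min_len_nt, self.min_density,
        )
        if not retained:
            raise ValueError("no genes pass the length/density filters")
        raw, major = dn.codon_densities(
            self.counts, self.orfs, offsets, self.rfp_class, genes=retained
        )
        matrix = dn.normalize_densities(raw, self.rfp_class, major)
        instances = ctx.annotate_contexts(
            matrix, self.orfs, self.exclude_edge, self.keep_stop_next
        )
        comparisons = ctx.context_comparisons(
            instances, self.rfp_class, codon_types=codon_types,
            n_boot=n_boot, seed=seed, method=method,
        )
        return RiboDensityResults(
            model=self, offsets=offsets, filter_report=report,
            density=matrix, instances=instances, comparisons=comparisons,
            major_frame=major, seed=seed,
        )


@dataclass
class RiboDensityResults:
    model: RiboDensityModel
    offsets: dn.OffsetTable
    filter_report: dn.GeneFilterReport
    density: dn.CodonDensityMatrix
    instances: pd.DataFrame
    comparisons: list[ctx.ContextComparison]
    major_frame: int
    seed: int | None = None

    def comparisons_frame(self) -> pd.DataFrame:
        return ctx.comparisons_frame(self.comparisons)

    def comparison(self, codon_type: str) -> ctx.ContextComparison:
        key = codon_type.upper().replace("T", "U")
        for c in self.comparisons:
            if c.asite_codon_type == key:
                return c
        raise KeyError(codon_type)

    def mean_percent_elevation(self, pattern: str = "NNU") -> float:
        """Mean percent elevation over codon types matching a pattern."""
        from .codons import codon_mask, codon_to_index

        mask = codon_mask(pattern)
        vals = [
            c.percent_elevation
            for c in self.comparisons
            if len(c.asite_codon_type) == 3
            and mask[codon_to_index(c.asite_codon_type)]
            and np.isfinite(c.percent_elevation)
        ]
        if not vals:
            raise ValueError(f"no comparisons match pattern {pattern!r}")
        return float(np.mean(vals))

    def summary(self, alpha: float = 0.01) -> str:
        rep = self.filter_report
        frame = self.comparisons_frame()
        ok = frame[frame["flag"] == ""]
        n_sig = int((ok["p_two_tailed"] < alpha).sum())
        lines = [
            f"Ribosome density analysis [{self.density.rfp_class}]",
            "=" * 60,
            f"genes: {rep.n_input} input, {rep.n_pass_length} pass length, "
            f"{rep.n_pass_density} pass density",
            f"offsets: {self.offsets.source} "
            f"{dict(sorted(self.offsets.offsets.items()))}",
            f"major frame: {self.major_frame}",
            f"codon types compared: {len(self.comparisons)} "
            f"({len(ok)} testable, {n_sig} with p < {alpha:g})",
        ]
        try:
            lines.append(
                f"mean NNU percent elevation (+1 GNN): "
                f"{self.mean_percent_elevation('NNU'):.1f}%"
            )
        except ValueError:
            pass
        return "\n".join(lines)


def compare_rfp_classes(
    results_21: RiboDensityResults, results_28: RiboDensityResults
) -> pd.DataFrame:
    """Group-level summary of percent elevations, 21-nt vs 28-nt footprints."""
    return ctx.class_summary(results_21.comparisons, results_28.comparisons)
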