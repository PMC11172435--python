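"""Synthetic ORF sets and ribosome-footprint profiles with recorded truth.

The generator emulates the statistical structure the density pipeline
assumes: per-gene sequencing depth variation (lognormal), 3-nt periodic
peak structure (one major and two flanking minor peaks), two read-length
classes, and multiplicative A-site dwell elevation for configurable
(A-site, +1) codon-context classes.  ORFs are drawn codon by codon with an
optional adjacency bias: after an NNU codon the probability of each
G-starting codon is multiplied by ``adjacency_bias`` and renormalized.

Counts are Poisson: for gene ``g``, codon ``i`` and frame ``f`` the
expected count is ``depth_g * 3 * dwell(g, i) * frame_weights[f] /
mean_dwell_g`` (so the expected total per gene is ``depth_g * length_g``),
thinned over the read-length mixture.  Each count is placed at 5' position
``(3 i + major_frame + delta_f) - offset(read_length)``; every generated
footprint's A-site lies inside the ORF (5' ends may be negative, i.e.
extend into the 5' UTR), and minor-peak positions falling outside the ORF
are dropped.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codons import CODON_STRS, codon_mask, codon_to_index
from .io import (
    RFP_CLASSES,
    ExpressionMap,
    FootprintCounts,
    OrfSet,
    write_expression_table,
    write_footprint_table,
    write_orf_fasta,
)

#: Dwell multiplier applied by the "paper_effect" preset to A-site NNU
#: codons followed by +1 GNN; the documented headline effect size.
PAPER_EFFECT_MULTIPLIER = 1.4

#: Adjacency odds multiplier applied by the "adjacency" preset.
ADJACENCY_PRESET_BIAS = 1.3

DEFAULT_LENGTH_MIXTURES = {
    "28nt": {27: 0.15, 28: 0.55, 29: 0.20, 30: 0.10},
    "21nt": {20: 0.20, 21: 0.60, 22: 0.20},
}

_FRAME_DELTA = np.array([0, 1, -1])  # major, downstream minor, upstream minor


@dataclass(frozen=True)
class DwellEffect:
    """Multiplicative dwell elevation for an (A-site, +1) codon context."""

    asite: str = "NNU"
    plus1: str = "GNN"
    multiplier: float = PAPER_EFFECT_MULTIPLIER
    rfp_class: str | None = None  # None: applies to every class

    def __post_init__(self):
        if self.multiplier <= 0:
            raise ValueError("dwell multiplier must be > 0")


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset (seed mandatory)."""

    seed: int
    n_genes: int = 100
    min_codons: int = 300  # total codons including start and stop
    max_codons: int = 600
    codon_usage: dict[str, float] | None = None  # default uniform over 61
    adjacency_bias: float = 1.0
    dwell_effects: tuple[DwellEffect, ...] = ()
    frame_weights: tuple[float, float, float] = (0.70, 0.15, 0.15)
    major_frame: int = 0
    depth_median: float = 1.0  # reads per nt, lognormal median
    depth_sigma: float = 0.5
    rfp_class: str = "28nt"
    length_mixture: dict[int, float] | None = None
    true_offsets: dict[int, int] | None = None  # default: every length -> 15
    overdispersion: float = 0.0
    expression_sigma: float = 1.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("SimConfig requires an explicit seed")
        if abs(sum(self.frame_weights) - 1.0) > 1e-9:
            raise ValueError("frame_weights must sum to 1")
        if self.adjacency_bias <= 0:
            raise ValueError("adjacency_bias must be > 0")
        if not (3 <= self.min_codons <= self.max_codons):
            raise ValueError("infeasible ORF length bounds")

    def resolved_mixture(self) -> dict[int, float]:
        mix = self.length_mixture or DEFAULT_LENGTH_MIXTURES[self.rfp_class]
        total = sum(mix.values())
        return {l: w / total for l, w in mix.items()}

    def resolved_offsets(self) -> dict[int, int]:
        if self.true_offsets is not None:
            return dict(self.true_offsets)
        return {l: 15 for l in RFP_CLASSES[self.rfp_class]}


@dataclass
class SimTruth:
    """Ground truth recorded alongside a synthetic dataset."""

    config: SimConfig
    adjacency_pairs: int | None = None  # planted NNU -> +1 GNN pair count
    dwell: dict[str, np.ndarray] = field(default_factory=dict)
    depth: dict[str, float] = field(default_factory=dict)
    expected_reads: dict[str, float] = field(default_factory=dict)

    def expected_normalized_density(self, gene: str) -> np.ndarray:
        """Closed-form expectation of the pipeline's normalized density."""
        d = self.dwell[gene]
        return d / d.mean()


def preset(name: str, seed: int, **overrides) -> SimConfig:
    """Named study presets: ``null``, ``paper_effect``, ``adjacency``."""
    if name == "null":
        base: dict = {}
    elif name == "paper_effect":
        base = {"dwell_effects": (DwellEffect(),)}
    elif name == "adjacency":
        base = {"adjacency_bias": ADJACENCY_PRESET_BIAS}
    else:
        raise ValueError(f"unknown preset: {name!r}")
    base.update(overrides)
    return SimConfig(seed=seed, **base)


def _codon_distributions(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """(base cdf, NNU-conditioned cdf) over the 64 codons (stops mass 0)."""
    p = np.zeros(64)
    if config.codon_usage is None:
        p[:] = 1.0
    else:
        for codon, w in config.codon_usage.items():
            if w < 0:
                raise ValueError("codon usage weights must be >= 0")
            p[codon_to_index(codon)] = w
    p[[codon_to_index(s) for s in ("UAA", "UAG", "UGA")]] = 0.0
    if p.sum() <= 0:
        raise ValueError("codon usage assigns no mass to sense codons")
    p = p / p.sum()
    gnn = codon_mask("GNN")
    p_biased = p * np.where(gnn, config.adjacency_bias, 1.0)
    p_biased = p_biased / p_biased.sum()
    return np.cumsum(p), np.cumsum(p_biased)


def gen_orfs(config: SimConfig) -> tuple[OrfSet, SimTruth]:
    """Generate an ORF set: AUG start, stop-free body, one stop codon."""
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_genes
    lengths = rng.integers(config.min_codons, config.max_codons + 1, size=n)
    cdf_base, cdf_biased = _codon_distributions(config)
    max_len = int(lengths.max())
    codons = np.full((n, max_len), -1, dtype=np.int64)
    codons[:, 0] = codon_to_index("AUG")
    for pos in range(1, max_len - 1):
        active = np.flatnonzero(pos <= lengths - 2)
        if active.size == 0:
            continue
        u = rng.random(active.size)
        prev = codons[active, pos - 1]
        prev_nnu = (prev % 4) == 3  # wobble U
        pick = np.where(
            prev_nnu,
            np.searchsorted(cdf_biased, u, side="right"),
            np.searchsorted(cdf_base, u, side="right"),
        )
        codons[active, pos] = pick
    stops = np.array([codon_to_index(s) for s in ("UAA", "UAG", "UGA")])
    codons[np.arange(n), lengths - 1] = rng.choice(stops, size=n)

    records: dict[str, str] = {}
    adjacency_pairs = 0
    for k in range(n):
        row = codons[k, : lengths[k]]
        records[f"gene{k:04d}"] = "".join(CODON_STRS[row])
        nnu = (row[:-1] % 4) == 3
        gstart = row[1:] >= 32
        gstart &= row[1:] < 48
        adjacency_pairs += int(np.sum(nnu & gstart))
    truth = SimTruth(config=config, adjacency_pairs=adjacency_pairs)
    return OrfSet(records), truth


def gen_profiles(
    orfs: OrfSet, config: SimConfig, truth: SimTruth | None = None
) -> tuple[FootprintCounts, SimTruth]:
    """Generate footprint 5'-end counts for one RFP class."""
    rng = np.random.default_rng([config.seed, 1])
    if truth is None:
        truth = SimTruth(config=config)
    mixture = config.resolved_mixture()
    offsets = config.resolved_offsets()
    missing = set(mixture) - set(offsets)
    if missing:
        raise ValueError(f"true offsets missing for read lengths {sorted(missing)}")
    lengths_arr = np.array(sorted(mixture))
    mix_w = np.array([mixture[l] for l in lengths_arr])
    fw = np.asarray(config.frame_weights)
    off_arr = np.array([offsets[l] for l in lengths_arr])

    effects = [
        e for e in config.dwell_effects
        if e.rfp_class is None or e.rfp_class == config.rfp_class
    ]
    eff_masks = [(codon_mask(e.asite), codon_mask(e.plus1), e.multiplier) for e in effects]

    gene_ids = orfs.gene_ids
    K = np.array([orfs.n_codons(g) for g in gene_ids])
    depth = np.exp(np.log(config.depth_median) + config.depth_sigma * rng.standard_normal(len(gene_ids)))

    dwell_parts = []
    for gi, g in enumerate(gene_ids):
        cod = orfs.codons(g)
        d = np.ones(cod.size)
        for am, pm, mult in eff_masks:
            hit = np.zeros(cod.size, dtype=bool)
            hit[:-1] = am[cod[:-1]] & pm[cod[1:]]
            d[hit] *= mult
        dwell_parts.append(d)
        truth.dwell[g] = d
        truth.depth[g] = float(depth[gi])
        truth.expected_reads[g] = float(depth[gi] * cod.size * 3)

    dwell_cat = np.concatenate(dwell_parts)
    gene_idx = np.repeat(np.arange(len(gene_ids)), K)
    within = np.concatenate([np.arange(k) for k in K])
    mean_dwell = np.array([d.mean() for d in dwell_parts])
    lam = depth[gene_idx] * 3.0 * dwell_cat / mean_dwell[gene_idx]
    if config.overdispersion > 0:
        shape = 1.0 / config.overdispersion
        lam = lam * rng.gamma(shape, 1.0 / shape, size=lam.size)
    grid = lam[:, None, None] * fw[None, :, None] * mix_w[None, None, :]
    counts = rng.poisson(grid)

    peak = 3 * within[:, None, None] + config.major_frame + _FRAME_DELTA[None, :, None]
    L = (3 * K)[gene_idx][:, None, None]
    counts = np.where((peak >= 0) & (peak < L), counts, 0)

    ci, fi, li = np.nonzero(counts)
    pos5 = peak[ci, fi, np.zeros_like(li)].ravel() - off_arr[li]
    df = pd.DataFrame(
        {
            "gene_id": np.array(gene_ids, dtype=object)[gene_idx[ci]],
            "pos5": pos5,
            "read_length": lengths_arr[li],
            "count": counts[ci, fi, li],
        }
    )
    return FootprintCounts(df), truth


def gen_expression(orfs: OrfSet, config: SimConfig) -> ExpressionMap:
    """Seeded lognormal expression values, one per gene."""
    rng = np.random.default_rng([config.seed, 2])
    values = np.exp(config.expression_sigma * rng.standard_normal(len(orfs)))
    return dict(zip(orfs.gene_ids, map(float, values)))


def write_dataset(outdir, config: SimConfig, rfp_classes=("28nt",)) -> dict:
    """Generate a full dataset and write it through the standard writers.

    Writes ``orfs.fasta``, one ``counts_<class>.tsv`` per requested class,
    ``expression.tsv`` and ``truth.json``; returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    orfs, truth = gen_orfs(config)
    paths = {"orfs": outdir / "orfs.fasta", "expression": outdir / "expression.tsv"}
    write_orf_fasta(orfs, paths["orfs"])
    write_expression_table(gen_expression(orfs, config), paths["expression"])
    summary = {
        "config": _config_dict(config),
        "adjacency_pairs": truth.adjacency_pairs,
        "rfp_classes": list(rfp_classes),
        "expected_reads": {},
    }
    for cls in rfp_classes:
        cfg = dataclasses.replace(config, rfp_class=cls)
        counts, cls_truth = gen_profiles(orfs, cfg)
        p = outdir / f"counts_{cls}.tsv"
        write_footprint_table(counts, p)
        paths[f"counts_{cls}"] = p
        summary["expected_reads"][cls] = {
            g: round(v, 3) for g, v in cls_truth.expected_reads.items()
        }
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return paths


def _config_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["dwell_effects"] = [dataclasses.asdict(e) for e in config.dwell_effects]
    return d
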