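"""Footprint-to-density pipeline: A-site offsetting, frame choice,
per-codon density aggregation, gene filtering and per-gene normalization.

Each footprint contributes its count at the A-site nucleotide position
``pos5 + offset(read_length)``.  The dataset-wide major frame ``m`` is the
frame (mod 3) carrying the most shifted counts; codon ``i``'s raw density
sums the shifted counts at the major-peak position ``3i + m`` and the two
flanking minor-peak positions.  Consecutive windows tile the ORF, so every
interior nucleotide position contributes to exactly one codon; positions
falling outside the ORF (or outside the first/last codon windows) are
dropped rather than spilling into UTRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import RFP_CLASSES, FootprintCounts, OrfSet

logger = logging.getLogger(__name__)

DEFAULT_OFFSET = 15  # canonical yeast A-site offset, both footprint classes
OFFSET_RANGE = range(10, 21)


@dataclass
class OffsetTable:
    """Read length -> A-site offset (5' end to first A-site nucleotide)."""

    offsets: dict[int, int]
    rfp_class: str
    source: str = "default"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        for length, off in self.offsets.items():
            if not (10 <= off <= 20):
                raise ValueError(f"offset {off} for length {length} outside [10, 20]")

    def __getitem__(self, read_length: int) -> int:
        return self.offsets[read_length]

    @classmethod
    def default(cls, rfp_class: str, offset: int = DEFAULT_OFFSET) -> "OffsetTable":
        return cls({l: offset for l in RFP_CLASSES[rfp_class]}, rfp_class, "default")


@dataclass
class GeneFilterReport:
    """Audit of the gene filters (length, then footprint density)."""

    n_input: int
    n_pass_length: int
    n_pass_density: int
    reasons: dict[str, str]
    retained: list[str]

    def __post_init__(self):
        if not (self.n_pass_density <= self.n_pass_length <= self.n_input):
            raise ValueError("inconsistent filter counts")


@dataclass
class CodonDensityMatrix:
    """Per-gene vectors of normalized per-codon densities for one RFP class.

    Each retained gene's vector is its raw per-codon density divided by the
    gene's own mean, so the per-gene mean is 1; vector length equals the
    gene's codon count (stop codon included).
    """

    rfp_class: str
    densities: dict[str, np.ndarray]
    raw_totals: dict[str, float]
    major_frame: int

    def __getitem__(self, gene: str) -> np.ndarray:
        return self.densities[gene]

    def __iter__(self):
        return iter(self.densities)

    def __len__(self):
        return len(self.densities)


def filter_genes(
    counts: FootprintCounts,
    orfs: OrfSet,
    rfp_class: str,
    min_len_nt: int = 198,
    min_density: float = 0.1,
) -> tuple[GeneFilterReport, list[str]]:
    """Retain genes with ORF length strictly > ``min_len_nt`` nt and raw
    class footprint density strictly > ``min_density`` per nt.

    The density is computed from raw footprint totals before offsetting.
    """
    totals = counts.gene_totals(rfp_class)
    reasons: dict[str, str] = {}
    retained: list[str] = []
    n_pass_length = 0
    for gene in orfs:
        L = orfs.length_nt(gene)
        if L <= min_len_nt:
            reasons[gene] = f"length {L} nt <= {min_len_nt}"
            continue
        n_pass_length += 1
        total = float(totals.get(gene, 0))
        if total / L <= min_density:
            reasons[gene] = f"density {total / L:.4g}/nt <= {min_density}"
            continue
        retained.append(gene)
    report = GeneFilterReport(
        n_input=len(orfs),
        n_pass_length=n_pass_length,
        n_pass_density=len(retained),
        reasons=reasons,
        retained=retained,
    )
    logger.info(
        "filter_genes[%s]: %d input, %d pass length, %d pass density",
        rfp_class, report.n_input, report.n_pass_length, report.n_pass_density,
    )
    return report, retained


def _shifted_positions(df: pd.DataFrame, orfs: OrfSet, offsets: OffsetTable):
    """A-site nt positions for each table row, with in-ORF validity mask."""
    lengths = df["read_length"].to_numpy()
    missing = set(np.unique(lengths)) - set(offsets.offsets)
    if missing:
        raise ValueError(f"read lengths missing from offset table: {sorted(missing)}")
    off = np.array([offsets.offsets[l] for l in np.unique(lengths)])
    off_map = dict(zip(np.unique(lengths), off))
    shift = np.vectorize(off_map.__getitem__, otypes=[np.int64])(lengths)
    pos = df["pos5"].to_numpy() + shift
    orf_len = np.array([orfs.length_nt(g) for g in df["gene_id"]])
    valid = (pos >= 0) & (pos < orf_len)
    return pos, valid


def codon_densities(
    counts: FootprintCounts,
    orfs: OrfSet,
    offsets: OffsetTable,
    rfp_class: str,
    genes: list[str] | None = None,
) -> tuple[dict[str, np.ndarray], int]:
    """Raw per-codon densities per gene, plus the chosen major frame.

    Returns vectors of length ``n_codons(gene)`` for every requested gene
    (genes with no counts get all-zero vectors); total shifted in-window
    counts are conserved into the codon sums.
    """
    if genes is None:
        genes = orfs.gene_ids
    gene_set = set(genes)
    df = counts.for_class(rfp_class)
    df = df[df["gene_id"].isin(gene_set)]
    out = {g: np.zeros(orfs.n_codons(g)) for g in genes}
    if len(df) == 0:
        return out, 0
    pos, valid = _shifted_positions(df, orfs, offsets)
    cnt = df["count"].to_numpy(dtype=float)
    frame_totals = np.bincount(pos[valid] % 3, weights=cnt[valid], minlength=3)
    major = int(np.argmax(frame_totals))
    logger.info(
        "codon_densities[%s]: major frame %d (frame totals %s)",
        rfp_class, major, frame_totals.astype(int).tolist(),
    )
    codon_idx = np.floor_divide(pos - major + 1, 3)
    n_codons = np.array([orfs.n_codons(g) for g in df["gene_id"]])
    keep = valid & (codon_idx >= 0) & (codon_idx < n_codons)
    sub = pd.DataFrame(
        {
            "gene_id": df["gene_id"].to_numpy()[keep],
            "codon": codon_idx[keep],
            "count": cnt[keep],
        }
    )
    for gene, grp in sub.groupby("gene_id", sort=False):
        vec = out[gene]
        np.add.at(vec, grp["codon"].to_numpy(dtype=np.int64), grp["count"].to_numpy())
    return out, major


def normalize_densities(
    raw: dict[str, np.ndarray], rfp_class: str, major_frame: int = 0
) -> CodonDensityMatrix:
    """Divide each gene's density vector by its own mean (gene mean -> 1)."""
    densities: dict[str, np.ndarray] = {}
    raw_totals: dict[str, float] = {}
    for gene, vec in raw.items():
        total = float(vec.sum())
        if total <= 0:
            raise ValueError(
                f"gene {gene!r} has zero footprint density; the gene filter"
                " should have removed it"
            )
        raw_totals[gene] = total
        densities[gene] = vec / vec.mean()
    return CodonDensityMatrix(rfp_class, densities, raw_totals, major_frame)


def calibrate_offsets(
    counts: FootprintCounts,
    orfs: OrfSet,
    rfp_class: str,
    default: int = DEFAULT_OFFSET,
    min_signal: float = 50.0,
) -> OffsetTable:
    """Estimate per-read-length A-site offsets from the data.

    For each read length the candidate offset in [10, 20] maximizing an
    ORF-anchored score is chosen: counts whose shifted A-site lands in-ORF
    on the major (frame-0) periodicity are rewarded and counts pushed
    outside the ORF are penalized.  The ORF boundaries break the mod-3
    degeneracy that a periodicity score alone would leave.  Lengths with
    insufficient or tied signal fall back to ``default`` with a warning.
    """
    df = counts.for_class(rfp_class)
    df = df[df["gene_id"].isin(set(orfs.gene_ids))]
    if len(df) == 0 or df["count"].sum() == 0:
        raise ValueError("no footprints available for offset calibration")
    offsets: dict[int, int] = {}
    warnings: list[str] = []
    orf_len_map = {g: orfs.length_nt(g) for g in orfs}
    for length in RFP_CLASSES[rfp_class]:
        sub = df[df["read_length"] == length]
        if len(sub) == 0:
            offsets[length] = default
            warnings.append(f"length {length}: no reads; default offset {default}")
            continue
        p5 = sub["pos5"].to_numpy()
        cnt = sub["count"].to_numpy(dtype=float)
        orf_len = np.array([orf_len_map[g] for g in sub["gene_id"]])
        scores = np.empty(len(OFFSET_RANGE))
        inframe = np.empty(len(OFFSET_RANGE))
        for k, o in enumerate(OFFSET_RANGE):
            pos = p5 + o
            inside = (pos >= 0) & (pos < orf_len)
            frame0 = inside & (pos % 3 == 0)
            inframe[k] = cnt[frame0].sum()
            scores[k] = inframe[k] - cnt[~inside].sum()
        best = int(np.argmax(scores))
        tied = np.sum(scores == scores[best]) > 1
        if inframe[best] < min_signal or tied:
            offsets[length] = default
            warnings.append(
                f"length {length}: insufficient or ambiguous signal; "
                f"default offset {default}"
            )
        else:
            offsets[length] = int(list(OFFSET_RANGE)[best])
    for w in warnings:
        logger.warning("calibrate_offsets[%s]: %s", rfp_class, w)
    return OffsetTable(offsets, rfp_class, "calibrated", warnings)


def read_offset_table(path, rfp_class: str) -> OffsetTable:
    """Read a TSV (read_length, offset) into an OffsetTable."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns)[:2] != ["read_length", "offset"]:
        raise ValueError(f"{path}: expected columns read_length, offset")
    table = dict(zip(df["read_length"].astype(int), df["offset"].astype(int)))
    return OffsetTable(table, rfp_class, "file")


def write_offset_table(offsets: OffsetTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_length\toffset\n")
        for length in sorted(offsets.offsets):
            fh.write(f"{length}\t{offsets.offsets[length]}\n")
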