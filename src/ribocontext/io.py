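"""File formats and canonical in-memory containers.

Coordinates are 0-based and half-open, relative to the first nucleotide of
the start codon; codon ``i`` covers nucleotides ``[3i, 3i+3)``.  Sequences
are canonicalized internally to the RNA alphabet (U), with T accepted on
input everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import seq_to_codon_indices

logger = logging.getLogger(__name__)

#: Footprint-length classes: 20-22 nt reads are pre-accommodation ("21nt")
#: footprints, 27-30 nt reads carry A- and P-site tRNAs ("28nt").
RFP_CLASSES: dict[str, tuple[int, ...]] = {
    "21nt": (20, 21, 22),
    "28nt": (27, 28, 29, 30),
}

_VALID = set("ACGU")


def canonicalize_sequence(seq: str) -> str | None:
    """Uppercase, T->U; return None if the record must be dropped
    (length not a positive multiple of 3, or ambiguous characters)."""
    s = seq.upper().replace("T", "U")
    if not s or len(s) % 3 or set(s) - _VALID:
        return None
    return s


class OrfSet:
    """Ordered collection of in-frame coding sequences, keyed by gene id.

    Every sequence has positive length, a multiple of 3, over {A,C,G,U}.
    """

    def __init__(self, records: Mapping[str, str]):
        canon: dict[str, str] = {}
        for gene, seq in records.items():
            c = canonicalize_sequence(seq)
            if c is None:
                raise ValueError(f"invalid ORF sequence for gene {gene!r}")
            canon[gene] = c
        if not canon:
            raise ValueError("OrfSet must contain at least one record")
        self.records: dict[str, str] = canon
        self._codon_cache: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[str]:
        return iter(self.records)

    def __contains__(self, gene: str) -> bool:
        return gene in self.records

    def __getitem__(self, gene: str) -> str:
        return self.records[gene]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.records)

    def length_nt(self, gene: str) -> int:
        return len(self.records[gene])

    def n_codons(self, gene: str) -> int:
        return len(self.records[gene]) // 3

    def codons(self, gene: str) -> np.ndarray:
        """Integer codon vector for one gene (cached)."""
        arr = self._codon_cache.get(gene)
        if arr is None:
            arr = seq_to_codon_indices(self.records[gene])
            arr.setflags(write=False)
            self._codon_cache[gene] = arr
        return arr

    def subset(self, genes) -> "OrfSet":
        return OrfSet({g: self.records[g] for g in genes})

    def total_codons(self) -> int:
        return sum(len(s) // 3 for s in self.records.values())


def read_orf_fasta(path) -> OrfSet:
    """Read ORF/CDS sequences from FASTA, dropping invalid records.

    Records whose length is not a positive multiple of 3 or that contain
    characters outside {A,C,G,T,U} are dropped, with a logged count.
    """
    records: dict[str, str] = {}
    n_dropped_len = n_dropped_ambig = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate gene id in FASTA: {rec.id!r}")
        seq = str(rec.seq).upper().replace("T", "U")
        if not seq or len(seq) % 3:
            n_dropped_len += 1
            continue
        if set(seq) - _VALID:
            n_dropped_ambig += 1
            continue
        records[rec.id] = seq
    if n_dropped_len or n_dropped_ambig:
        logger.warning(
            "read_orf_fasta(%s): dropped %d records (length not multiple of 3)"
            " and %d records (ambiguous bases)",
            path, n_dropped_len, n_dropped_ambig,
        )
    if not records:
        raise ValueError(f"no valid ORF records in {path}")
    return OrfSet(records)


def write_orf_fasta(orfs: OrfSet, path) -> None:
    """Write an OrfSet as DNA-alphabet FASTA (U -> T)."""
    recs = [
        SeqRecord(Seq(seq.replace("U", "T")), id=gene, description="")
        for gene, seq in orfs.records.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


@dataclass
class FootprintCounts:
    """Sparse per-gene, per-position, per-read-length footprint 5'-end counts.

    ``df`` has columns (gene_id, pos5, read_length, count); duplicate keys
    are summed on construction.  ``pos5`` is the 0-based offset of the read
    5' end relative to the first nucleotide of the start codon and may be
    negative (reads starting in the 5' UTR).
    """

    df: pd.DataFrame

    def __post_init__(self):
        required = ["gene_id", "pos5", "read_length", "count"]
        if list(self.df.columns)[:4] != required:
            raise ValueError(f"FootprintCounts requires columns {required}")
        if (self.df["count"] < 0).any():
            raise ValueError("negative footprint count")
        df = self.df
        if df.duplicated(["gene_id", "pos5", "read_length"]).any():
            df = (
                df.groupby(["gene_id", "pos5", "read_length"], sort=False, as_index=False)[
                    "count"
                ].sum()
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def total(self) -> int:
        return int(self.df["count"].sum())

    def for_class(self, rfp_class: str) -> pd.DataFrame:
        lengths = RFP_CLASSES[rfp_class]
        return self.df[self.df["read_length"].isin(lengths)]

    def gene_totals(self, rfp_class: str | None = None) -> pd.Series:
        df = self.df if rfp_class is None else self.for_class(rfp_class)
        return df.groupby("gene_id")["count"].sum()


def read_footprint_table(path) -> FootprintCounts:
    """Read the footprint TSV (header: gene_id, pos5, read_length, count).

    Duplicate (gene, pos, length) rows are summed.  Negative counts and
    malformed rows raise, naming the offending line number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = ["gene_id", "pos5", "read_length", "count"]
    if list(df.columns) != required:
        raise ValueError(
            f"{path}: expected header {required}, got {list(df.columns)}"
        )
    for col in ("pos5", "read_length", "count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # + header line
            raise ValueError(f"{path}: malformed {col} value on line {line}")
        df[col] = vals.astype(np.int64)
    neg = df["count"] < 0
    if neg.any():
        line = int(np.flatnonzero(neg.to_numpy())[0]) + 2
        raise ValueError(f"{path}: negative count on line {line}")
    return FootprintCounts(df)


def write_footprint_table(counts: FootprintCounts, path) -> None:
    counts.df.to_csv(path, sep="\t", index=False)


ExpressionMap = dict  # gene_id -> positive expression value


def read_expression_table(path) -> ExpressionMap:
    """Read a two-column TSV (gene_id, value) into an ExpressionMap."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2 or len(df) == 0:
        raise ValueError(f"{path}: expected non-empty TSV with gene_id, value")
    gene_col, value_col = df.columns[:2]
    vals = pd.to_numeric(df[value_col], errors="coerce")
    if vals.isna().any() or not np.isfinite(vals).all():
        line = int(np.flatnonzero((vals.isna() | ~np.isfinite(vals)).to_numpy())[0]) + 2
        raise ValueError(f"{path}: non-numeric or non-finite value on line {line}")
    return dict(zip(df[gene_col].astype(str), vals.astype(float)))


def write_expression_table(expr: ExpressionMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tvalue\n")
        for gene, value in expr.items():
            fh.write(f"{gene}\t{_fmt(value)}\n")


def _fmt(x) -> str:
    """Deterministic 6-significant-digit float formatting."""
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        return format(float(x), ".6g")
    return str(x)


def write_tsv_report(obj, path) -> None:
    """Write a Pwm, a ContextComparison collection, or a BootstrapResult
    as a deterministic TSV (fixed column order, floats at 6 significant
    digits; writing the same object twice is byte-identical)."""
    from .context import ContextComparison, comparisons_frame
    from .pwm import Pwm
    from .bootstrap import BootstrapResult

    if isinstance(obj, Pwm):
        rows = ["position\tA\tC\tG\tU"]
        for pos in range(3):
            cells = "\t".join(_fmt(w) for w in obj.weights[pos])
            rows.append(f"{pos + 1}\t{cells}")
        text = "\n".join(rows) + "\n"
    elif isinstance(obj, BootstrapResult):
        fields = [
            "statistic", "p_two_tailed", "n_boot", "seed",
            "boot_mean", "boot_sd", "threshold_low", "threshold_high", "method",
        ]
        vals = [
            obj.observed_stat, obj.p_two_tailed, obj.n_boot, obj.seed,
            obj.boot_mean, obj.boot_sd, obj.threshold_low, obj.threshold_high,
            obj.method,
        ]
        text = "\t".join(fields) + "\n" + "\t".join(_fmt(v) for v in vals) + "\n"
    elif isinstance(obj, (list, tuple)) and (
        len(obj) == 0 or isinstance(obj[0], ContextComparison)
    ):
        frame = comparisons_frame(obj)
        lines = ["\t".join(frame.columns)]
        for _, row in frame.iterrows():
            lines.append("\t".join(_fmt(v) for v in row))
        text = "\n".join(lines) + "\n"
    else:
        raise TypeError(f"no TSV report writer for {type(obj).__name__}")
    with open(path, "w", newline="\n") as fh:
        fh.write(text)


def read_pwm_report(path) -> np.ndarray:
    """Read back a PWM report written by :func:`write_tsv_report` (3x4 weights)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["position", "A", "C", "G", "U"]:
        raise ValueError(f"{path}: not a PWM report")
    return df[["A", "C", "G", "U"]].to_numpy(dtype=float)


def read_bootstrap_report(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return df.iloc[0].to_dict()


def read_comparisons(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
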