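"""Codon arithmetic and wobble-decoding classification.

Codons are represented either as 3-letter RNA strings (``"GCU"``) or as
integers in ``[0, 64)`` with base-4 digits over the alphabet A=0, C=1,
G=2, U=3 (most-significant digit = codon position 1).

The tRNA nucleotide-34 classification follows the wobble-decoding rule for
eukaryotes: an NNU/NNC codon pair is read by an inosine-34 (I34) anticodon
when the sibling NNA codon codes for the same amino acid (inosine pairs
with U, C and A), and by a guanosine-34 (G34) anticodon otherwise.  Glycine
is the known exception and is kept G34 even though GGA codes Gly.  CGA is
the single NNA codon decoded exclusively by an I34 anticodon and carries a
dedicated flag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGU"
NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

#: ASCII lookup table mapping nucleotide characters to indices (255 = invalid).
_ASCII_TO_IDX = np.full(256, 255, dtype=np.uint8)
for _n, _i in NUC_INDEX.items():
    _ASCII_TO_IDX[ord(_n)] = _i
_ASCII_TO_IDX[ord("T")] = NUC_INDEX["U"]  # U/T treated as identical

ALL_CODONS = tuple(
    a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES
)
CODON_STRS = np.array(ALL_CODONS)

_rna_table = CodonTable.unambiguous_rna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_rna_table.forward_table)
STOP_CODONS = frozenset(_rna_table.stop_codons)  # UAA, UAG, UGA
for _stop in STOP_CODONS:
    GENETIC_CODE[_stop] = "*"

SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)


def codon_to_index(codon: str) -> int:
    """Map a 3-letter codon (RNA or DNA alphabet) to its integer code."""
    if len(codon) != 3:
        raise ValueError(f"not a codon: {codon!r}")
    idx = 0
    for ch in codon.upper():
        v = _ASCII_TO_IDX[ord(ch)] if ord(ch) < 256 else 255
        if v == 255:
            raise ValueError(f"invalid nucleotide in codon {codon!r}")
        idx = idx * 4 + int(v)
    return idx


def index_to_codon(idx: int) -> str:
    return ALL_CODONS[idx]


STOP_INDICES = frozenset(codon_to_index(c) for c in STOP_CODONS)
SENSE_INDICES = tuple(i for i in range(64) if i not in STOP_INDICES)


def seq_to_nuc_indices(seq: str) -> np.ndarray:
    """Vector of nucleotide indices (0..3) for an ACGT/ACGU string."""
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = _ASCII_TO_IDX[raw]
    if (out == 255).any():
        raise ValueError("sequence contains characters outside {A,C,G,T,U}")
    return out.astype(np.int64)


def seq_to_codon_indices(seq: str) -> np.ndarray:
    """Integer codons for an in-frame sequence (length multiple of 3)."""
    if len(seq) % 3:
        raise ValueError("sequence length is not a multiple of 3")
    nt = seq_to_nuc_indices(seq)
    return 16 * nt[0::3] + 4 * nt[1::3] + nt[2::3]


def codon_indices_to_seq(codons: Iterable[int]) -> str:
    return "".join(CODON_STRS[np.asarray(list(codons), dtype=np.int64)])


#: ONE-HOT decomposition tensor: ONEHOT[codon, position, nucleotide] in {0,1}.
ONEHOT = np.zeros((64, 3, 4), dtype=np.float64)
for _ci, _codon in enumerate(ALL_CODONS):
    for _pos, _ch in enumerate(_codon):
        ONEHOT[_ci, _pos, NUC_INDEX[_ch]] = 1.0


@dataclass(frozen=True)
class CodonClassInfo:
    """Decoding classification of one codon.

    Attributes
    ----------
    codon : str
        3-letter RNA codon.
    amino_acid : str
        One-letter amino acid, ``"*"`` for stop codons.
    wobble : str
        Third (wobble) nucleotide.
    t34 : str
        Anticodon nucleotide-34 class: ``"G34"``, ``"I34"``, ``"other"``
        (sense NNA/NNG codons), or ``"none"`` (stop codons).
    i34_exclusive : bool
        True only for CGA, the sole NNA codon decoded exclusively by I34.
    """

    codon: str
    amino_acid: str
    wobble: str
    t34: str
    i34_exclusive: bool = False


def _build_decoding_table() -> dict[str, CodonClassInfo]:
    table: dict[str, CodonClassInfo] = {}
    for codon in ALL_CODONS:
        aa = GENETIC_CODE[codon]
        wobble = codon[2]
        if codon in STOP_CODONS:
            t34 = "none"
        elif wobble in "UC":
            sibling_a = codon[:2] + "A"
            same_box = GENETIC_CODE.get(sibling_a) == aa
            # Gly keeps a G34 anticodon despite GGA coding Gly.
            t34 = "I34" if (same_box and aa != "G") else "G34"
        else:
            t34 = "other"
        info = CodonClassInfo(codon, aa, wobble, t34)
        if codon == "CGA":
            info = replace(info, t34="I34", i34_exclusive=True)
        table[codon] = info
    return table


DECODING_TABLE: dict[str, CodonClassInfo] = _build_decoding_table()


def classify_codon(codon: str, mode: str = "eukaryote") -> CodonClassInfo:
    """Classify a codon by amino acid, wobble nucleotide and tRNA nt-34.

    ``mode="prokaryote"`` remaps every I34 assignment to G34 (inosine 34 is
    a eukaryote innovation); the CGA exclusivity flag is then cleared.
    """
    key = codon.upper().replace("T", "U")
    try:
        info = DECODING_TABLE[key]
    except KeyError:
        raise ValueError(f"invalid codon: {codon!r}") from None
    if mode == "prokaryote" and info.t34 == "I34":
        t34 = "G34" if info.wobble in "UC" else "other"
        return replace(info, t34=t34, i34_exclusive=False)
    if mode not in ("eukaryote", "prokaryote"):
        raise ValueError(f"unknown mode: {mode!r}")
    return info


def codon_mask(pattern: str | Callable[[str], bool]) -> np.ndarray:
    """Boolean mask over the 64 codons for a pattern like ``"NNU"``/``"GNN"``.

    ``N`` matches any nucleotide; other positions must match exactly.
    A callable predicate over codon strings is also accepted; the string
    ``"all"`` selects every codon.
    """
    mask = np.zeros(64, dtype=bool)
    if callable(pattern):
        for i, codon in enumerate(ALL_CODONS):
            mask[i] = bool(pattern(codon))
        return mask
    pat = pattern.upper().replace("T", "U")
    if pat == "ALL":
        mask[:] = True
        return mask
    if len(pat) != 3 or any(ch not in "ACGUN" for ch in pat):
        raise ValueError(f"invalid codon pattern: {pattern!r}")
    for i, codon in enumerate(ALL_CODONS):
        mask[i] = all(p == "N" or p == c for p, c in zip(pat, codon))
    return mask


#: Masks used throughout the density analysis.
SENSE_MASK = np.array([c not in STOP_CODONS for c in ALL_CODONS])
GNN_MASK = codon_mask("GNN")


def density_group(codon: str) -> str:
    """Codon-class label used to group context comparisons.

    NNU codons split by their tRNA nt-34 class; NNC/NNA/NNG codons group by
    wobble nucleotide alone.  Stop codons have no group.
    """
    info = classify_codon(codon)
    if info.amino_acid == "*":
        raise ValueError(f"stop codon {codon!r} has no density group")
    if info.wobble == "U":
        return f"NNU({info.t34})"
    return f"NN{info.wobble}"
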