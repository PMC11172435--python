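"""Nucleotide background frequencies and (conditional) position weight matrices.

A PWM here is the 3 x 4 matrix of per-codon-position nucleotide weights

    weight(pos, N) = log2( f_observed(pos, N) / f_expected(N) )

where ``f_expected`` is the background nucleotide frequency of the same ORF
set pooled over *all* positions regardless of codon structure.  Conditional
PWMs restrict the tally to codons picked out by a selector, e.g. "codons
3'-adjacent to an NNU codon".

Zero-frequency guard: where ``f_observed`` or ``f_expected`` is zero the
weight is reported as NaN and excluded from downstream comparisons; no
pseudocounts are applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .codons import NUC_INDEX, ONEHOT, codon_mask
from .io import OrfSet

SelectorFn = Callable[[str, np.ndarray], np.ndarray]
"""Selector: (gene_id, integer codon vector) -> boolean inclusion mask."""


@dataclass(frozen=True)
class NucFreqs:
    """Background nucleotide frequencies (sum to 1)."""

    f_A: float
    f_C: float
    f_G: float
    f_U: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f_A, self.f_C, self.f_G, self.f_U])

    @classmethod
    def from_array(cls, arr) -> "NucFreqs":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (4,) or (arr < 0).any():
            raise ValueError("NucFreqs requires 4 non-negative frequencies")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        return cls(*map(float, arr))


@dataclass
class Pwm:
    """Position weight matrix over a selected codon set.

    ``weights`` and ``f_obs`` are (3, 4) arrays in A, C, G, U column order;
    ``f_exp`` is the length-4 background; ``n_codons`` counts the codons that
    contributed.
    """

    weights: np.ndarray
    f_obs: np.ndarray
    f_exp: np.ndarray
    selector_description: str
    n_codons: int

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.f_obs = np.asarray(self.f_obs, dtype=float)
        self.f_exp = np.asarray(self.f_exp, dtype=float)
        if self.weights.shape != (3, 4) or self.f_obs.shape != (3, 4):
            raise ValueError("Pwm matrices must be 3 x 4")
        if self.n_codons <= 0:
            raise ValueError("Pwm requires n_codons > 0")
        if not np.allclose(self.f_obs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("observed frequencies must sum to 1 per position")

    def weight(self, position: int, nucleotide: str) -> float:
        """Weight for 1-based codon position and nucleotide letter."""
        return float(self.weights[position - 1, NUC_INDEX[nucleotide.upper().replace("T", "U")]])


def select_all(gene_id: str, codons: np.ndarray) -> np.ndarray:
    return np.ones(codons.size, dtype=bool)


def select_after(reference_mask: np.ndarray) -> SelectorFn:
    """Selector for codons whose 5' neighbour (same ORF) matches a codon mask."""

    def _sel(gene_id: str, codons: np.ndarray) -> np.ndarray:
        mask = np.zeros(codons.size, dtype=bool)
        if codons.size > 1:
            mask[1:] = reference_mask[codons[:-1]]
        return mask

    return _sel


def nucleotide_counts(orfs: OrfSet) -> np.ndarray:
    """Pooled nucleotide counts (A, C, G, U) over all sequences/positions."""
    total = np.zeros(4)
    for gene in orfs:
        c64 = np.bincount(orfs.codons(gene), minlength=64).astype(float)
        total += np.tensordot(c64, ONEHOT, axes=(0, 0)).sum(axis=0)
    return total


def background_frequencies(orfs: OrfSet) -> NucFreqs:
    """Background nucleotide frequencies of an ORF set, pooled over all
    sequences and positions regardless of codon structure."""
    counts = nucleotide_counts(orfs)
    return NucFreqs.from_array(counts / counts.sum())


def position_counts(orfs: OrfSet, selector: SelectorFn) -> tuple[np.ndarray, int]:
    """(3, 4) nucleotide counts at codon positions 1-3 over selected codons."""
    c64 = np.zeros(64)
    for gene in orfs:
        codons = orfs.codons(gene)
        mask = selector(gene, codons)
        if mask.any():
            c64 += np.bincount(codons[mask], minlength=64)
    n_sel = int(c64.sum())
    return np.tensordot(c64, ONEHOT, axes=(0, 0)), n_sel


def weights_from_counts(pos_counts: np.ndarray, f_exp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(weights, f_obs) with the zero-frequency NaN guard applied."""
    totals = pos_counts.sum(axis=1, keepdims=True)
    f_obs = pos_counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = f_obs / f_exp[None, :]
        weights = np.where((f_obs > 0) & (f_exp[None, :] > 0), np.log2(ratio), np.nan)
    return weights, f_obs


def positional_weight_matrix(
    orfs: OrfSet,
    selector: SelectorFn = select_all,
    description: str = "all codons",
) -> Pwm:
    """PWM over the codons picked by ``selector``; the background comes from
    :func:`background_frequencies` of the same ORF set."""
    pos_counts, n_sel = position_counts(orfs, selector)
    if n_sel == 0:
        raise ValueError("selector matched zero codons")
    f_exp = background_frequencies(orfs).as_array()
    weights, f_obs = weights_from_counts(pos_counts, f_exp)
    return Pwm(weights, f_obs, f_exp, description, n_sel)


def adjacency_pwm(orfs: OrfSet, reference_class="NNU") -> Pwm:
    """Conditional PWM of codons 3'-adjacent to a reference codon class.

    ``reference_class`` is a codon pattern (``"NNU"``), a predicate over
    codon strings, or a length-64 boolean mask.  Adjacency never crosses
    ORF boundaries.
    """
    if isinstance(reference_class, np.ndarray):
        mask = reference_class.astype(bool)
        desc = "codons after custom reference class"
    else:
        mask = codon_mask(reference_class)
        label = reference_class if isinstance(reference_class, str) else "predicate"
        desc = f"codons 3'-adjacent to {label}"
    if not mask.any():
        raise ValueError("reference class matches no codons")
    return positional_weight_matrix(orfs, select_after(mask), desc)
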