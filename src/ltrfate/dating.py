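"""Insertion dating of intact LTR retrotransposons.

The two LTRs of an element are identical at insertion and diverge at twice
the per-site substitution rate thereafter, so the Kimura two-parameter (K2P)
distance K between them converts to an insertion age

    T = K / (2 r)

with r the per-site per-year substitution rate (default 1.3e-8, the
repeat-DNA rate commonly used for grass LTR retrotransposons).

K2P separates transitions (A<->G, C<->T; proportion P of ungapped columns)
from transversions (proportion Q):

    K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Columns containing gaps or ambiguous bases are excluded.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align

#: default substitution rate, substitutions / site / year
DEFAULT_RATE = 1.3e-8

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


class SaturationError(ValueError):
    """Raised when the K2P distance is undefined (log of a non-positive)."""


@dataclass(frozen=True)
class DivergenceEstimate:
    """K2P sufficient statistics plus the derived distance and age.

    P, Q      transition / transversion proportions over ungapped columns
    K         K2P substitutions per site
    T         insertion age in years (``None`` until a rate is applied)
    sites_used  number of ungapped, unambiguous columns
    """

    P: float
    Q: float
    K: float
    sites_used: int
    T: float | None = None


def _aligner(match: float = 1.0, mismatch: float = -1.0,
             gap_open: float = -5.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    # Gap convention: a gap of length L costs |gap_open| + L * |gap_extend|.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def align_ltr_pair(ltr5: str, ltr3: str) -> tuple[str, str]:
    """Global affine-gap alignment of the two LTR copies.

    Scoring: match +1, mismatch -1, a gap of length L costs 5 + L.  Returns
    the two aligned rows (with ``-`` gap characters).  Deterministic: the
    first alignment in the aligner's canonical enumeration order is taken.
    """
    if not ltr5 or not ltr3:
        raise ValueError("cannot align an empty LTR sequence")
    alignment = _aligner().align(ltr5.upper(), ltr3.upper())[0]
    return str(alignment[0]), str(alignment[1])


def alignment_score(ltr5: str, ltr3: str) -> float:
    """Optimal global alignment score under the :func:`align_ltr_pair` scheme."""
    if not ltr5 or not ltr3:
        raise ValueError("cannot align an empty LTR sequence")
    return float(_aligner().score(ltr5.upper(), ltr3.upper()))


def k2p_distance(alignment: tuple[str, str]) -> DivergenceEstimate:
    """K2P distance from a pairwise alignment (gap/N columns excluded)."""
    row1, row2 = alignment
    if len(row1) != len(row2):
        raise ValueError("alignment rows differ in length")
    sites = transitions = transversions = 0
    for x, y in zip(row1.upper(), row2.upper()):
        if x not in _VALID or y not in _VALID:
            continue
        sites += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise ValueError("alignment has no ungapped, unambiguous columns")
    P = transitions / sites
    Q = transversions / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P distance undefined at P={P:.4f}, Q={Q:.4f} (saturated)")
    K = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return DivergenceEstimate(P=P, Q=Q, K=K, sites_used=sites)


def insertion_time(K: float, r: float = DEFAULT_RATE) -> float:
    """Insertion age in years, T = K / (2 r)."""
    if r <= 0:
        raise ValueError("substitution rate must be positive")
    if K < 0:
        raise ValueError("K2P distance cannot be negative")
    return K / (2.0 * r)


def date_element(ltr5: str, ltr3: str, r: float = DEFAULT_RATE) -> DivergenceEstimate:
    """Align two LTR copies, compute K2P distance and the insertion age."""
    est = k2p_distance(align_ltr_pair(ltr5, ltr3))
    return DivergenceEstimate(P=est.P, Q=est.Q, K=est.K,
                              sites_used=est.sites_used,
                              T=insertion_time(est.K, r))
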