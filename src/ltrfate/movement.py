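"""Scanners for DSB-repair and element-capture gene-movement footprints.

When a double-strand break is repaired with a foreign DNA template, or a
transposable element captures a gene fragment, characteristic sequence
signatures are left around the moved gene.  Five patterns are scanned:

* **A (TSD capture)** — an exact target-site duplication embracing a
  TE-plus-gene block: the TE created the break, the gene fragment filled it.
* **B (shared border)** — donor and acceptor gene copies flanked by an
  identical terminal motif on the same side.
* **C (Helitron capture)** — a gene fully contained within an annotated
  Helitron, the rolling-circle transposon known to capture genes.
* **D (tandem flank)** — a gene flanked by tandem-repeat arrays on both
  sides, suggesting movement by template slippage / unequal crossing-over.
* **E (retrocopy)** — an intronless duplicate of a multi-exon paralog,
  the signature of reverse-transcribed processed mRNA.

All motif evidence is exact-match: every reported evidence string occurs
verbatim at its reported coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode

Interval = tuple[int, int]


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    interval: Interval
    exons: tuple[Interval, ...] = ()

    @property
    def n_exons(self) -> int:
        return len(self.exons) if self.exons else 1

    @property
    def exon_bp(self) -> int:
        if self.exons:
            return sum(e - s for s, e in self.exons)
        return self.interval[1] - self.interval[0]


@dataclass(frozen=True)
class TEAnnotationLite:
    te_id: str
    interval: Interval
    class_label: str = "Unclassified"


@dataclass(frozen=True)
class TandemArray:
    """A tandem repeat array: ``copies`` repeats of a ``period``-bp unit."""

    interval: Interval
    period: int
    copies: int
    consensus_unit: str


@dataclass(frozen=True)
class MovementFootprint:
    pattern: str              # A_tsd_capture .. E_retrocopy
    interval: Interval
    evidence: dict[str, str] = field(default_factory=dict)
    score: int = 0            # bp of exact evidence


# ---------------------------------------------------------------------------
# Tandem arrays
# ---------------------------------------------------------------------------

def find_tandem_arrays(sequence: str, min_period: int = 1, max_period: int = 10,
                       min_copies: int = 4, max_mismatch_frac: float = 0.0,
                       min_length: int = 12) -> list[TandemArray]:
    """Maximal tandem arrays by period-k self-shift agreement.

    For each period ``k`` the boolean track ``s[i] == s[i+k]`` is scanned
    for runs whose agreement fraction is at least ``1 - max_mismatch_frac``
    (runs must begin and end on an agreement).  A run ``[i, j)`` implies the
    array ``[i, j+k)``.  Arrays shorter than ``min_length`` bp are dropped
    (short-period chance runs such as homopolymers are ubiquitous in random
    sequence); overlapping calls at different periods are resolved
    longest-first, smallest period among ties.
    """
    if not 1 <= min_period <= max_period:
        raise ValueError("need 1 <= min_period <= max_period")
    n = len(sequence)
    codes = encode(sequence)
    calls: list[TandemArray] = []
    for k in range(min_period, max_period + 1):
        if n < k * 2:
            continue
        agree = codes[:-k] == codes[k:]
        i = 0
        m = len(agree)
        while i < m:
            if not agree[i]:
                i += 1
                continue
            if max_mismatch_frac == 0.0:
                j = i
                while j < m and agree[j]:
                    j += 1
                best_j = j
            else:
                # greedy: extend over disagreements while the fraction holds
                j = i + 1
                good = 1
                best_j = j
                while j < m:
                    if agree[j]:
                        good += 1
                        if good / (j + 1 - i) >= 1.0 - max_mismatch_frac:
                            best_j = j + 1
                    j += 1
                    if good / (j - i) < 0.5:   # hopeless tail, stop early
                        break
            length = best_j - i + k
            if length / k >= min_copies and length >= min_length:
                calls.append(TandemArray(interval=(i, i + length), period=k,
                                         copies=int(length // k),
                                         consensus_unit=sequence[i:i + k]))
            i = best_j + 1
    # longest-first, smallest-period resolution of overlapping calls
    calls.sort(key=lambda a: (-(a.interval[1] - a.interval[0]), a.period,
                              a.interval[0]))
    kept: list[TandemArray] = []
    for call in calls:
        s, e = call.interval
        if any(s < o.interval[1] and o.interval[0] < e for o in kept):
            continue
        kept.append(call)
    kept.sort(key=lambda a: a.interval)
    return kept


# ---------------------------------------------------------------------------
# Pattern scanners
# ---------------------------------------------------------------------------

def _adjacent(a: Interval, b: Interval, max_gap: int) -> bool:
    return max(a[0], b[0]) - min(a[1], b[1]) <= max_gap and not _overlaps(a, b)


def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def scan_tsd_capture(sequence: str, te_annotations: list[TEAnnotationLite],
                     gene_annotations: list[GeneAnnotation],
                     min_tsd: int = 8, max_tsd: int = 25,
                     max_gap: int = 2000) -> list[MovementFootprint]:
    """Pattern A: an exact duplicated motif of >= ``min_tsd`` bp whose two
    copies flank a combined [TE + gene] block (TE adjacent to the gene
    within ``max_gap``).  The default ``min_tsd`` sits above ordinary 4-6 bp
    element TSDs so routine insertions do not trigger the pattern."""
    seq = sequence.upper()
    n = len(seq)
    found: list[MovementFootprint] = []
    for te in te_annotations:
        for gene in gene_annotations:
            if not _adjacent(te.interval, gene.interval, max_gap):
                continue
            block = (min(te.interval[0], gene.interval[0]),
                     max(te.interval[1], gene.interval[1]))
            s, e = block
            top = min(max_tsd, s, n - e)
            for length in range(top, min_tsd - 1, -1):
                if seq[s - length:s] == seq[e:e + length]:
                    found.append(MovementFootprint(
                        pattern="A_tsd_capture", interval=block,
                        evidence={"tsd": seq[s - length:s],
                                  "te_id": te.te_id, "gene_id": gene.gene_id},
                        score=length))
                    break
    found.sort(key=lambda f: f.interval)
    return found


def scan_shared_border(acceptor_sequence: str, acceptor_gene: Interval,
                       donor_sequence: str, donor_gene: Interval,
                       min_border: int = 6) -> MovementFootprint | None:
    """Pattern B: longest exact terminal motif anchored at the gene boundary
    on the same side of both the donor and the acceptor copy."""
    for seq, (s, e) in ((acceptor_sequence, acceptor_gene),
                        (donor_sequence, donor_gene)):
        if s < 1 or e > len(seq) - 1:
            raise ValueError("gene interval needs flanking sequence on both sides")
    acc = acceptor_sequence.upper()
    don = donor_sequence.upper()
    best: tuple[int, str, str] | None = None
    # right side: common prefix of the two right flanks
    ra, rd = acc[acceptor_gene[1]:], don[donor_gene[1]:]
    k = 0
    while k < min(len(ra), len(rd)) and ra[k] == rd[k]:
        k += 1
    if k >= min_border:
        best = (k, "right", ra[:k])
    # left side: common suffix of the two left flanks
    la, ld = acc[:acceptor_gene[0]], don[:donor_gene[0]]
    k = 0
    while k < min(len(la), len(ld)) and la[-1 - k] == ld[-1 - k]:
        k += 1
    if k >= min_border and (best is None or k > best[0]):
        best = (k, "left", la[len(la) - k:])
    if best is None:
        return None
    length, side, motif = best
    return MovementFootprint(pattern="B_shared_border", interval=acceptor_gene,
                             evidence={"border": motif, "side": side},
                             score=length)


def scan_helitron_capture(te_annotations: list[TEAnnotationLite],
                          gene_annotations: list[GeneAnnotation]
                          ) -> list[MovementFootprint]:
    """Pattern C: genes fully contained within Helitron-class elements."""
    found = []
    for te in te_annotations:
        if te.class_label != "Helitron":
            continue
        for gene in gene_annotations:
            s, e = gene.interval
            if te.interval[0] <= s and e <= te.interval[1] and \
                    (te.interval[0], te.interval[1]) != (s, e):
                found.append(MovementFootprint(
                    pattern="C_helitron_capture", interval=gene.interval,
                    evidence={"helitron_id": te.te_id, "gene_id": gene.gene_id},
                    score=e - s))
    found.sort(key=lambda f: f.interval)
    return found


def scan_tandem_flank(sequence: str, gene_annotations: list[GeneAnnotation],
                      arrays: list[TandemArray], window: int = 500,
                      boundary_slack: int = 3) -> list[MovementFootprint]:
    """Pattern D: genes with a tandem array within ``window`` bp on BOTH sides.

    An array may straddle the gene boundary by up to ``boundary_slack`` bp:
    a repeat run can extend a few bases into the gene by chance agreement.
    """
    found = []
    for gene in gene_annotations:
        gs, ge = gene.interval
        left = [a for a in arrays
                if a.interval[0] < gs and a.interval[1] <= gs + boundary_slack
                and gs - a.interval[1] <= window]
        right = [a for a in arrays
                 if a.interval[1] > ge and a.interval[0] >= ge - boundary_slack
                 and a.interval[0] - ge <= window]
        if left and right:
            la = max(left, key=lambda a: a.interval[1])
            ra = min(right, key=lambda a: a.interval[0])
            found.append(MovementFootprint(
                pattern="D_tandem_flank", interval=gene.interval,
                evidence={"gene_id": gene.gene_id,
                          "left_unit": la.consensus_unit,
                          "right_unit": ra.consensus_unit},
                score=(la.interval[1] - la.interval[0]) +
                      (ra.interval[1] - ra.interval[0])))
    found.sort(key=lambda f: f.interval)
    return found


def flag_retrocopy(gene_annotations: list[GeneAnnotation],
                   homology_pairs: list[tuple[str, str]],
                   length_tolerance: float = 0.10) -> list[MovementFootprint]:
    """Pattern E: paralog pairs where one copy is single-exon and its length
    matches the partner's summed exon length within ``length_tolerance``."""
    by_id = {g.gene_id: g for g in gene_annotations}
    found = []
    for id_a, id_b in homology_pairs:
        if id_a not in by_id or id_b not in by_id:
            continue
        a, b = by_id[id_a], by_id[id_b]
        for parent, copy in ((a, b), (b, a)):
            if parent.n_exons >= 2 and copy.n_exons == 1:
                copy_len = copy.exon_bp
                if abs(copy_len - parent.exon_bp) <= length_tolerance * parent.exon_bp:
                    found.append(MovementFootprint(
                        pattern="E_retrocopy", interval=copy.interval,
                        evidence={"retrocopy_id": copy.gene_id,
                                  "parent_id": parent.gene_id},
                        score=copy_len))
                break
    found.sort(key=lambda f: f.interval)
    return found
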