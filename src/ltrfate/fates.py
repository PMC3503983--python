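"""Fate classification of LTR-retrotransposon remnants and mechanism inference.

Every LTR-derived element in a region is assigned exactly one of nine fate
categories describing what survives of the original
[5'LTR][internal][3'LTR] + TSD structure.  The category determines the
removal mechanism: unequal homologous recombination (UR) between the two
LTRs of one element (intra) or between elements (inter) produces solo-LTRs,
while illegitimate recombination (IR) produces truncated and internally
deleted remnants.  A region-level balance of inserted versus inferred
removed bp summarizes whether retrotransposon turnover is expanding (E) or
contracting (C) the locus.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .annotate import AnnotatedElement, RepeatLibrary


class FateCategory(enum.Enum):
    """The nine element-fate categories, labelled as in the field's usage."""

    INTACT_LTR = "Intact LTR"
    SOLO_WITH_TSD = "Solo w/TSD"
    SOLO_WITHOUT_TSD = "Solo w/o TSD"
    INTACT_WITHOUT_TSD = "Intact LTR w/o TSD"
    TRUNCATED_SOLO = "Truncated Solo"
    THREE_PRIME_LTR_DELETED = "3' LTR deleted"
    FIVE_PRIME_LTR_DELETED = "5' LTR deleted"
    PARTIALLY_DELETED = "5' and/or 3' partially deleted"
    RECOMBINATION_COMPLEX = "Recombination complex"


class Mechanism(enum.Enum):
    UR_INTRA = "UR(Intra)"
    UR_INTER = "UR(Inter)"
    IR = "IR"
    UR_INTER_OR_UR_INTRA_AND_IR = "UR(Inter) or UR(Intra)&IR"
    NONE = "none"


#: fixed category -> removal-mechanism mapping
MECHANISM_OF: dict[FateCategory, Mechanism] = {
    FateCategory.INTACT_LTR: Mechanism.NONE,
    FateCategory.SOLO_WITH_TSD: Mechanism.UR_INTRA,
    FateCategory.SOLO_WITHOUT_TSD: Mechanism.UR_INTER,
    FateCategory.INTACT_WITHOUT_TSD: Mechanism.UR_INTRA,
    FateCategory.TRUNCATED_SOLO: Mechanism.UR_INTER_OR_UR_INTRA_AND_IR,
    FateCategory.THREE_PRIME_LTR_DELETED: Mechanism.IR,
    FateCategory.FIVE_PRIME_LTR_DELETED: Mechanism.IR,
    FateCategory.PARTIALLY_DELETED: Mechanism.IR,
    FateCategory.RECOMBINATION_COMPLEX: Mechanism.UR_INTER,
}


def mechanism_of(category: FateCategory) -> Mechanism:
    """Removal mechanism implied by a fate category (total pure function)."""
    return MECHANISM_OF[category]


class NotClassifiableError(ValueError):
    """Element carries no LTR-class evidence and cannot receive a fate."""


def _cov(sf, library: RepeatLibrary | None) -> float:
    """Consensus coverage of a sub-feature; structural intervals without a
    homology hit are measured against the library LTR consensus if possible,
    else treated as full."""
    if sf.coverage is not None:
        return sf.coverage
    if library is not None and sf.family and sf.family in library:
        ltr = library[sf.family].ltr
        if ltr:
            return min(1.0, (sf.interval[1] - sf.interval[0]) / len(ltr))
    return 1.0


def classify_element(element: AnnotatedElement,
                     library: RepeatLibrary | None = None, *,
                     full_ltr_cov: float = 0.8, internal_cov: float = 0.5,
                     solo_isolation: int = 500) -> FateCategory:
    """Assign one fate category to an annotated element.

    Decision cascade (first match wins):

    1. two full LTRs of one family plus >=``internal_cov`` of that family's
       internal region -> Intact LTR (with / without TSD);
    2. evidence from two different families -> Recombination complex;
    3. a single full-length LTR with no internal evidence nearby -> solo
       (with / without TSD);
    4. partial LTR evidence only -> Truncated Solo;
    5. internal region plus exactly one LTR -> 3' or 5' LTR deleted,
       depending on which copy is absent (strand-aware);
    6. anything else with both termini representable -> partially deleted.
    """
    ltr_feats = element.features_with_role("5'LTR", "3'LTR", "partial_LTR")
    internal_feats = element.features_with_role("internal", "partial_internal")
    if not ltr_feats:
        raise NotClassifiableError(
            f"element {element.element_id or '?'} has no LTR-class sub-features")

    full_ltrs = [sf for sf in ltr_feats if _cov(sf, library) >= full_ltr_cov]
    fam = element.family_name
    internal_fam_cov = sum(
        _cov(sf, library) for sf in internal_feats
        if sf.family in (fam, None))
    n_families = len(element.families_present)

    # 1. intact
    if len(full_ltrs) >= 2 and n_families <= 1 and internal_fam_cov >= internal_cov:
        return (FateCategory.INTACT_LTR if element.tsd is not None
                else FateCategory.INTACT_WITHOUT_TSD)

    # 2. chimera of two families sharing an LTR
    if n_families >= 2:
        return FateCategory.RECOMBINATION_COMPLEX

    # 3. solo-LTR
    if len(ltr_feats) == 1 and len(full_ltrs) == 1:
        ltr_iv = ltr_feats[0].interval
        near = [sf for sf in internal_feats
                if max(sf.interval[0] - ltr_iv[1], ltr_iv[0] - sf.interval[1]) <= solo_isolation]
        if not near:
            return (FateCategory.SOLO_WITH_TSD if element.tsd is not None
                    else FateCategory.SOLO_WITHOUT_TSD)

    # 4. truncated solo remnant
    if not internal_feats and not full_ltrs:
        return FateCategory.TRUNCATED_SOLO

    # 5. one LTR lost entirely
    if internal_feats and len(ltr_feats) == 1 and full_ltrs:
        ltr_iv = ltr_feats[0].interval
        first = all(ltr_iv[1] <= sf.interval[0] + 1 for sf in internal_feats)
        last = all(sf.interval[1] <= ltr_iv[0] + 1 for sf in internal_feats)
        if first or last:
            ltr_is_5prime = first if element.strand == "+" else last
            return (FateCategory.THREE_PRIME_LTR_DELETED if ltr_is_5prime
                    else FateCategory.FIVE_PRIME_LTR_DELETED)

    # 6. internally / terminally deleted
    return FateCategory.PARTIALLY_DELETED


_INTACT = {FateCategory.INTACT_LTR, FateCategory.INTACT_WITHOUT_TSD}


@dataclass
class FateCountTable:
    """Per-region fate counts plus the contraction/expansion balance."""

    region_id: str
    counts: dict[FateCategory, int] = field(default_factory=dict)
    bp_inserted: int = 0
    bp_removed_inferred: int = 0

    @property
    def tendency(self) -> str:
        """'E' (expansion) if surviving LTR-derived bp exceed the bp inferred
        removed from non-intact remnants, else 'C' (contraction)."""
        return "E" if self.bp_inserted > self.bp_removed_inferred else "C"

    @property
    def n_elements(self) -> int:
        return sum(self.counts.values())


def fate_count_table(region_id: str,
                     classified: list[tuple[AnnotatedElement, FateCategory]],
                     library: RepeatLibrary | None = None) -> FateCountTable:
    """Tabulate fates for one region and compute the tendency balance.

    ``bp_inserted`` is the total LTR-derived sequence still present;
    ``bp_removed_inferred`` sums, over non-intact remnants of known family,
    the difference between the library-reconstructed intact length and the
    observed remnant length.
    """
    if not classified:
        raise ValueError("cannot summarize an empty region")
    table = FateCountTable(region_id=region_id)
    for element, category in classified:
        table.counts[category] = table.counts.get(category, 0) + 1
        observed = sum(sf.interval[1] - sf.interval[0]
                       for sf in element.sub_features)
        table.bp_inserted += observed
        if category not in _INTACT and library is not None:
            full = (library[element.family_name].full_length
                    if element.family_name in library else None)
            if full is not None:
                table.bp_removed_inferred += max(0, full - observed)
    return table
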