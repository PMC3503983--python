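"""Region-level TE composition and chromatin profiling.

Produces the classic BAC-annotation summary: percent of the region masked
by each TE family/class (Class I retrotransposons vs Class II DNA
transposons), with intact-element subsets reported separately and never
added into the class totals; gene density in kb/gene; and a descriptive
heterochromatin indicator from the Gypsy:Copia balance plus gene density
(Gypsy-rich, gene-poor regions are heterochromatin-like, the converse
euchromatin-like).

All masking arithmetic is done at base-pair level: where TEs nest, each
base is attributed to the innermost (most recently inserted) element, so
family percentages are conserved (they can never sum past 100%).  Percent
rounding to two decimals happens only at the reporting layer.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import CLASS_I, CLASS_LABELS

Interval = tuple[int, int]

#: canonical Class II labels (DNA transposons)
CLASS_II = frozenset(set(CLASS_LABELS) - CLASS_I)


@dataclass(frozen=True)
class TEAnnotation:
    """Minimal TE annotation consumed by the composition table."""

    interval: Interval
    family: str
    class_label: str
    intact: bool = False


@dataclass
class CompositionTable:
    """Per-family masked bp and percent for one region."""

    region_id: str
    region_length: int
    family_bp: dict[tuple[str, str], int] = field(default_factory=dict)  # (class,family)->bp
    intact_bp: dict[str, int] = field(default_factory=dict)              # subset rows

    def percent(self, class_label: str, family: str) -> float:
        return 100.0 * self.family_bp.get((class_label, family), 0) / self.region_length

    def class_percents(self, class_labels) -> dict[str, float]:
        out: dict[str, float] = {}
        for (cls, fam), bp in self.family_bp.items():
            if cls in class_labels:
                out[cls] = out.get(cls, 0.0) + 100.0 * bp / self.region_length
        return out

    @property
    def class1_total_percent(self) -> float:
        """Class I total: sum of retrotransposon family percents (intact
        subsets are informational and excluded)."""
        return sum(self.class_percents(CLASS_I).values())

    @property
    def class2_total_percent(self) -> float:
        return sum(self.class_percents(CLASS_II).values())

    def to_frame(self) -> pd.DataFrame:
        """Report layout: one row per family grouped by class, intact
        subsets as separate rows, totals last; percents to 2 decimals."""
        rows = []
        for group, labels in (("Class I", sorted(CLASS_I)),
                              ("Class II", sorted(CLASS_II))):
            for cls in labels:
                for (c, fam), bp in sorted(self.family_bp.items()):
                    if c == cls:
                        rows.append((group, cls, fam, bp,
                                     round(100.0 * bp / self.region_length, 2)))
            key = "Intact Class I" if group == "Class I" else "Intact Class II"
            if key in self.intact_bp:
                bp = self.intact_bp[key]
                rows.append((group, "(intact subset)", key, bp,
                             round(100.0 * bp / self.region_length, 2)))
            total = (self.class1_total_percent if group == "Class I"
                     else self.class2_total_percent)
            rows.append((group, "Total", "", np.nan, round(total, 2)))
        return pd.DataFrame(rows, columns=["class_group", "class", "family",
                                           "masked_bp", "percent"])


def class_total_percent(component_percents) -> float:
    """Class total as the sum of its component family percentages, rounded
    to the two decimals of the reporting layer.  Intact-element subset rows
    are informational and must not be included by the caller."""
    return round(float(sum(component_percents)), 2)


def composition_table(annotations: list[TEAnnotation], region_length: int,
                      region_id: str = "region") -> CompositionTable:
    """bp-level composition with innermost attribution for nested TEs.

    Intervals are painted largest-first so that a nested (more recently
    inserted) element overwrites its host; every base is counted once.
    """
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    for ann in annotations:
        s, e = ann.interval
        if not 0 <= s <= e <= region_length:
            raise ValueError(f"interval {ann.interval} outside region")
    owner = np.full(region_length, -1, dtype=np.int32)
    order = sorted(range(len(annotations)),
                   key=lambda i: -(annotations[i].interval[1] - annotations[i].interval[0]))
    for i in order:
        s, e = annotations[i].interval
        owner[s:e] = i
    table = CompositionTable(region_id=region_id, region_length=region_length)
    idx, counts = np.unique(owner[owner >= 0], return_counts=True)
    for i, bp in zip(idx, counts):
        ann = annotations[int(i)]
        key = (ann.class_label, ann.family)
        table.family_bp[key] = table.family_bp.get(key, 0) + int(bp)
        if ann.intact:
            subset = ("Intact Class I" if ann.class_label in CLASS_I
                      else "Intact Class II")
            table.intact_bp[subset] = table.intact_bp.get(subset, 0) + int(bp)
    return table


def gene_density(region_length: int, n_genes: int) -> float | None:
    """Gene density in kb per gene model; ``None`` for a gene-free region."""
    if region_length < 0 or n_genes < 0:
        raise ValueError("inputs must be non-negative")
    if n_genes == 0:
        return None
    return region_length / 1000.0 / n_genes


@dataclass(frozen=True)
class RegionProfile:
    region_id: str
    gene_density_kb: float | None
    gypsy_percent: float
    copia_percent: float


def chromatin_indicator(profile: RegionProfile,
                        density_threshold: float = 20.0,
                        ratio_threshold: float = 2.0,
                        eps: float = 1e-9) -> str:
    """Descriptive chromatin label from Gypsy:Copia balance and gene density.

    heterochromatin-like: Gypsy/Copia >= ratio_threshold AND gene density
    >= density_threshold kb/gene (gene-poor); euchromatin-like when both
    are reversed; otherwise indeterminate.  Purely descriptive — no
    cytological claim.
    """
    ratio = profile.gypsy_percent / max(profile.copia_percent, eps)
    dens = profile.gene_density_kb
    if dens is None:
        dens = float("inf")
    if ratio >= ratio_threshold and dens >= density_threshold:
        return "heterochromatin-like"
    if ratio < 1.0 / ratio_threshold and dens < density_threshold:
        return "euchromatin-like"
    return "indeterminate"


def region_profile(table: CompositionTable, n_genes: int,
                   region_id: str | None = None) -> RegionProfile:
    return RegionProfile(
        region_id=region_id or table.region_id,
        gene_density_kb=gene_density(table.region_length, n_genes),
        gypsy_percent=sum(table.percent("Ty3/Gypsy", fam)
                          for (cls, fam) in table.family_bp if cls == "Ty3/Gypsy"),
        copia_percent=sum(table.percent("Ty1/Copia", fam)
                          for (cls, fam) in table.family_bp if cls == "Ty1/Copia"))
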