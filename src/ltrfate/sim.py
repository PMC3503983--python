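"""Synthetic genomic regions with planted, ground-truthed repeat biology.

The generator emulates BAC-scale grass genomic regions (0.1–2 Mb): a random
background of configurable GC content carrying genes (exon/intron
intervals), LTR retrotransposons of known family, insertion age and fate,
DNA transposons, tandem-repeat arrays, and planted gene-movement footprints.
Every planted feature is emitted as a :class:`TruthRecord`, so each
downstream stage (annotation, fate classification, dating, footprint
scanning) can be scored against ground truth.

Aging model: element-derived sequence (LTRs and internal region) evolves
under a continuous-time Kimura two-parameter substitution process with rate
``r`` (substitutions/site/year) and transition/transversion rate ratio
``kappa``; the two LTR copies of one element evolve independently, so their
expected divergence is governed by branch length ``2·r·age``.  Indels are
not simulated inside elements, which keeps the dating oracle exact.  Host
flanks and TSD copies do not evolve: TSD identity is the planted mechanism
signal.

Each planted element is a *maximal* repeat: the internal bases immediately
inside the two LTR junctions are resampled so that the LTR–LTR alignment
cannot extend past the planted boundary by a chance flank match.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import decode, encode
from .annotate import LibraryEntry, RepeatLibrary
from .fates import FateCategory

Interval = tuple[int, int]

FOOTPRINT_PATTERNS = ("A_tsd_capture", "B_shared_border", "C_helitron_capture",
                      "D_tandem_flank", "E_retrocopy")

#: internal stream offsets so that adding features never perturbs earlier ones
_STREAM_BACKGROUND = 0
_STREAM_FAMILY = 1_000_000
_STREAM_FEATURE = 2_000_000


# ---------------------------------------------------------------------------
# Specs and configuration
# ---------------------------------------------------------------------------

@dataclass
class PlantSpec:
    """One LTR retrotransposon to plant."""

    family_name: str
    ltr_length: int = 1000
    internal_length: int = 5000
    age_years: float = 1.0e6
    fate: FateCategory = FateCategory.INTACT_LTR
    tsd_length: int = 5
    position: int | str = "random"
    nest_in: str | None = None
    class_label: str = "Ty3/Gypsy"
    #: fraction of the LTR kept for Truncated Solo fates
    truncation_fraction: float = 0.4
    #: second family for Recombination complex chimeras
    partner_family: str | None = None

    def __post_init__(self):
        if self.age_years < 0:
            raise ValueError("age_years must be >= 0")
        if not 0 <= self.tsd_length <= 20:
            raise ValueError("tsd_length must be in [0, 20]")
        needs_tsd = self.fate in (FateCategory.INTACT_LTR, FateCategory.SOLO_WITH_TSD)
        if needs_tsd and self.tsd_length == 0:
            raise ValueError(f"fate {self.fate.value!r} requires tsd_length > 0")
        if self.fate is FateCategory.RECOMBINATION_COMPLEX and not self.partner_family:
            raise ValueError("Recombination complex requires partner_family")
        if not 0.05 <= self.truncation_fraction < 0.8:
            raise ValueError("truncation_fraction must lie in [0.05, 0.8)")


@dataclass
class GeneSpec:
    name: str
    n_exons: int = 3
    exon_length: int = 300
    intron_length: int = 150
    position: int | str = "random"


@dataclass
class DnaTeSpec:
    family_name: str
    length: int = 800
    class_label: str = "MITE/Tourist"
    tsd_length: int = 3
    age_years: float = 0.0
    position: int | str = "random"


@dataclass
class TandemSpec:
    period: int = 3
    copies: int = 8
    position: int | str = "random"


@dataclass
class FootprintSpec:
    pattern: str
    params: dict = field(default_factory=dict)
    position: int | str = "random"

    def __post_init__(self):
        if self.pattern not in FOOTPRINT_PATTERNS:
            raise ValueError(f"unknown footprint pattern {self.pattern!r}")


@dataclass
class SimConfig:
    """Full description of one synthetic region (deterministic per seed)."""

    region_length: int
    gc_fraction: float = 0.43
    rate: float = 1.3e-8          # substitutions / site / year
    kappa: float = 2.0            # transition/transversion rate ratio
    seed: int = 0
    region_id: str = "region_1"
    element_specs: list[PlantSpec] = field(default_factory=list)
    gene_specs: list[GeneSpec] = field(default_factory=list)
    dna_te_specs: list[DnaTeSpec] = field(default_factory=list)
    tandem_specs: list[TandemSpec] = field(default_factory=list)
    footprint_specs: list[FootprintSpec] = field(default_factory=list)
    margin: int = 1000            # min bp between planted features
    family_spacing: int = 20000   # min bp between same-family LTR elements

    def __post_init__(self):
        if self.region_length < 10_000:
            raise ValueError("region_length must be >= 10 kb")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must lie strictly in (0, 1)")
        if self.rate <= 0:
            raise ValueError("substitution rate must be positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


@dataclass
class TruthRecord:
    """Ground truth for one planted feature (0-based half-open intervals)."""

    feature_id: str
    kind: str                      # gene | ltr_element | dna_te | tandem_array | footprint
    interval: Interval
    family_name: str | None = None
    fate: FateCategory | None = None
    age_years: float | None = None
    tsd_sequence: str | None = None
    pattern: str | None = None
    nested_in: str | None = None
    donor_id: str | None = None
    sub_intervals: dict[str, Interval] = field(default_factory=dict)

    def to_line(self) -> str:
        subs = ";".join(f"{k}:{s}-{e}" for k, (s, e) in sorted(self.sub_intervals.items()))
        fields = [
            f"feature_id={self.feature_id}", f"kind={self.kind}",
            f"start={self.interval[0]}", f"end={self.interval[1]}",
            f"family={self.family_name or '.'}",
            f"fate={self.fate.name if self.fate else '.'}",
            f"age_years={self.age_years if self.age_years is not None else '.'}",
            f"tsd={self.tsd_sequence or '.'}",
            f"pattern={self.pattern or '.'}",
            f"nested_in={self.nested_in or '.'}",
            f"donor_id={self.donor_id or '.'}",
            f"sub_intervals={subs or '.'}",
        ]
        return "\t".join(fields)

    @classmethod
    def from_line(cls, line: str) -> "TruthRecord":
        kv = dict(tok.split("=", 1) for tok in line.rstrip("\n").split("\t"))
        subs: dict[str, Interval] = {}
        if kv["sub_intervals"] != ".":
            for item in kv["sub_intervals"].split(";"):
                role, span = item.rsplit(":", 1)
                s, e = span.split("-")
                subs[role] = (int(s), int(e))
        return cls(
            feature_id=kv["feature_id"], kind=kv["kind"],
            interval=(int(kv["start"]), int(kv["end"])),
            family_name=None if kv["family"] == "." else kv["family"],
            fate=None if kv["fate"] == "." else FateCategory[kv["fate"]],
            age_years=None if kv["age_years"] == "." else float(kv["age_years"]),
            tsd_sequence=None if kv["tsd"] == "." else kv["tsd"],
            pattern=None if kv["pattern"] == "." else kv["pattern"],
            nested_in=None if kv["nested_in"] == "." else kv["nested_in"],
            donor_id=None if kv["donor_id"] == "." else kv["donor_id"],
            sub_intervals=subs,
        )


# ---------------------------------------------------------------------------
# Elementary processes
# ---------------------------------------------------------------------------

def make_background(length: int, gc_fraction: float, seed) -> str:
    """Random background sequence with the requested expected GC content."""
    if length <= 0:
        raise ValueError("background length must be positive")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must lie strictly in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at]).astype(np.uint8)
    return decode(codes)


def k2p_substitution_probs(d: float, kappa: float) -> tuple[float, float]:
    """(transition, total transversion) probabilities after branch length ``d``
    expected substitutions/site under K2P with ts/tv rate ratio ``kappa``."""
    beta = d / (kappa + 2.0)
    alpha = kappa * beta
    p_ts = 0.25 + 0.25 * math.exp(-4.0 * beta) - 0.5 * math.exp(-2.0 * (alpha + beta))
    p_tv = 0.5 - 0.5 * math.exp(-4.0 * beta)
    return p_ts, p_tv


def evolve(codes: np.ndarray, d: float, kappa: float,
           rng: np.random.Generator) -> np.ndarray:
    """Evolve a code array for ``d`` expected substitutions/site under K2P."""
    if d < 0:
        raise ValueError("branch length must be >= 0")
    if d == 0:
        return codes.copy()
    p_ts, p_tv = k2p_substitution_probs(d, kappa)
    u = rng.random(len(codes))
    pick = rng.random(len(codes))
    out = codes.copy()
    ts = u < p_ts
    tv = (~ts) & (u < p_ts + p_tv)
    out[ts] ^= 2                                  # A<->G, C<->T
    out[tv] ^= np.where(pick[tv] < 0.5, 1, 3).astype(np.uint8)
    return out


def _random_codes(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    g = gc / 2.0
    return rng.choice(4, size=length, p=[at, g, g, at]).astype(np.uint8)


# ---------------------------------------------------------------------------
# Payload construction
# ---------------------------------------------------------------------------

def _distinct_base(rng: np.random.Generator, *avoid: int) -> int:
    choices = [b for b in range(4) if b not in avoid]
    return int(choices[rng.integers(len(choices))])


@dataclass
class _Payload:
    codes: np.ndarray
    truth: TruthRecord                   # interval/sub_intervals payload-relative
    extra_truths: list[TruthRecord] = field(default_factory=list)


def _pin_maximality(codes: np.ndarray, subs: dict[str, Interval],
                    rng: np.random.Generator,
                    flank_before: int | None = None,
                    flank_after: int | None = None) -> None:
    """Resample the internal bases at the two LTR junctions so the LTR-LTR
    alignment cannot extend past the planted boundary by a chance match.

    The aligned columns just outside the LTR pair are (first internal base,
    first base right of the 3'LTR) and (last base left of the 5'LTR, last
    internal base); each pair is forced to mismatch.  Bases outside the
    payload must be supplied via ``flank_before``/``flank_after`` once the
    insertion point is known.
    """
    if "5'LTR" not in subs or "3'LTR" not in subs or "internal" not in subs:
        return
    int_s, int_e = subs["internal"]
    l5_s = subs["5'LTR"][0]
    l3_e = subs["3'LTR"][1]
    right_outside = int(codes[l3_e]) if l3_e < len(codes) else flank_after
    if right_outside is not None and codes[int_s] == right_outside:
        codes[int_s] = _distinct_base(rng, right_outside)
    left_outside = int(codes[l5_s - 1]) if l5_s > 0 else flank_before
    if left_outside is not None and codes[int_e - 1] == left_outside:
        codes[int_e - 1] = _distinct_base(rng, left_outside)


def _build_element_payload(spec: PlantSpec, consensi: dict[str, LibraryEntry],
                           config: SimConfig, rng: np.random.Generator) -> _Payload:
    """Assemble the planted-fate payload for one LTR retrotransposon."""
    entry = consensi[spec.family_name]
    ltr_cons = encode(entry.ltr)
    int_cons = encode(entry.internal)
    d = config.rate * spec.age_years
    fate = spec.fate

    ltr5 = evolve(ltr_cons, d, config.kappa, rng)
    ltr3 = evolve(ltr_cons, d, config.kappa, rng)
    internal = evolve(int_cons, d, config.kappa, rng)
    tsd = _random_codes(rng, spec.tsd_length, config.gc_fraction) \
        if spec.tsd_length else np.empty(0, dtype=np.uint8)

    subs: dict[str, Interval] = {}
    parts: list[np.ndarray] = []
    pos = 0

    def add(role: str | None, arr: np.ndarray):
        nonlocal pos
        if role is not None:
            subs[role] = (pos, pos + len(arr))
        parts.append(arr)
        pos += len(arr)

    if fate in (FateCategory.INTACT_LTR, FateCategory.INTACT_WITHOUT_TSD):
        if fate is FateCategory.INTACT_LTR:
            add("tsd_left", tsd)
        add("5'LTR", ltr5)
        add("internal", internal)
        add("3'LTR", ltr3)
        if fate is FateCategory.INTACT_LTR:
            add("tsd_right", tsd)
    elif fate is FateCategory.SOLO_WITH_TSD:
        add("tsd_left", tsd)
        add("5'LTR", ltr5)
        add("tsd_right", tsd)
    elif fate is FateCategory.SOLO_WITHOUT_TSD:
        add("5'LTR", ltr5)
    elif fate is FateCategory.TRUNCATED_SOLO:
        keep = max(1, int(round(spec.truncation_fraction * len(ltr5))))
        piece = ltr5[:keep] if rng.random() < 0.5 else ltr5[-keep:]
        add("partial_LTR", piece)
    elif fate is FateCategory.THREE_PRIME_LTR_DELETED:
        add("5'LTR", ltr5)
        add("internal", internal)
    elif fate is FateCategory.FIVE_PRIME_LTR_DELETED:
        add("internal", internal)
        add("3'LTR", ltr3)
    elif fate is FateCategory.PARTIALLY_DELETED:
        # one IR deletion spanning most of the internal region and the 5'
        # third of the 3'LTR, leaving both element termini representable,
        # with a 2-10 bp microhomology copied across the junction
        keep_int = max(1, int(round(0.2 * len(internal))))
        cut_ltr = int(round(0.3 * len(ltr3)))
        int_piece = internal[:keep_int].copy()
        ltr_piece = ltr3[cut_ltr:].copy()
        mh = int(rng.integers(2, 11))
        mh = min(mh, len(int_piece), len(ltr_piece))
        int_piece[-mh:] = ltr_piece[:mh]
        add("5'LTR", ltr5)
        add("partial_internal", int_piece)
        add("partial_LTR", ltr_piece)
    elif fate is FateCategory.RECOMBINATION_COMPLEX:
        partner = consensi[spec.partner_family]
        int_y = evolve(encode(partner.internal), d, config.kappa, rng)
        ltr3_y = evolve(encode(partner.ltr), d, config.kappa, rng)
        half_x = internal[:len(internal) // 2]
        half_y = int_y[len(int_y) // 2:]
        add("5'LTR", ltr5)
        add("partial_internal", half_x)
        add("partial_internal_partner", half_y)
        add("3'LTR_partner", ltr3_y)
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unhandled fate {fate!r}")

    codes = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
    _pin_maximality(codes, subs, rng)
    # the element proper excludes the TSD copies
    inner = [iv for role, iv in subs.items() if not role.startswith("tsd")]
    start = min(iv[0] for iv in inner)
    end = max(iv[1] for iv in inner)
    truth = TruthRecord(
        feature_id="", kind="ltr_element", interval=(start, end),
        family_name=spec.family_name, fate=fate, age_years=spec.age_years,
        tsd_sequence=decode(tsd) if (len(tsd) and fate in
                                     (FateCategory.INTACT_LTR,
                                      FateCategory.SOLO_WITH_TSD)) else None,
        sub_intervals=subs)
    return _Payload(codes=codes, truth=truth)


def _build_gene_payload(spec: GeneSpec, config: SimConfig,
                        rng: np.random.Generator) -> _Payload:
    subs: dict[str, Interval] = {}
    parts: list[np.ndarray] = []
    pos = 0
    for i in range(spec.n_exons):
        exon = _random_codes(rng, spec.exon_length, min(0.6, config.gc_fraction + 0.1))
        subs[f"exon_{i + 1}"] = (pos, pos + len(exon))
        parts.append(exon)
        pos += len(exon)
        if i < spec.n_exons - 1:
            intron = _random_codes(rng, spec.intron_length, config.gc_fraction)
            parts.append(intron)
            pos += len(intron)
    codes = np.concatenate(parts)
    truth = TruthRecord(feature_id="", kind="gene", interval=(0, len(codes)),
                        family_name=spec.name, sub_intervals=subs)
    return _Payload(codes=codes, truth=truth)


def _build_dna_te_payload(spec: DnaTeSpec, consensi: dict[str, LibraryEntry],
                          config: SimConfig, rng: np.random.Generator) -> _Payload:
    entry = consensi[spec.family_name]
    body = evolve(encode(entry.consensus), config.rate * spec.age_years,
                  config.kappa, rng)
    tsd = _random_codes(rng, spec.tsd_length, config.gc_fraction) \
        if spec.tsd_length else np.empty(0, dtype=np.uint8)
    codes = np.concatenate([tsd, body, tsd])
    n = len(tsd)
    subs = {"body": (n, n + len(body))}
    if n:
        subs["tsd_left"] = (0, n)
        subs["tsd_right"] = (n + len(body), n + len(body) + n)
    truth = TruthRecord(feature_id="", kind="dna_te",
                        interval=(n, n + len(body)),
                        family_name=spec.family_name,
                        age_years=spec.age_years,
                        tsd_sequence=decode(tsd) if n else None,
                        sub_intervals=subs)
    return _Payload(codes=codes, truth=truth)


def _build_tandem_payload(spec: TandemSpec, config: SimConfig,
                          rng: np.random.Generator) -> _Payload:
    if spec.period < 1 or spec.copies < 2:
        raise ValueError("tandem arrays need period >= 1 and copies >= 2")
    unit = _random_codes(rng, spec.period, config.gc_fraction)
    codes = np.tile(unit, spec.copies)
    truth = TruthRecord(feature_id="", kind="tandem_array",
                        interval=(0, len(codes)),
                        family_name=f"period{spec.period}",
                        sub_intervals={"unit": (0, spec.period)})
    return _Payload(codes=codes, truth=truth)


def _build_footprint_payloads(spec: FootprintSpec, config: SimConfig,
                              rng: np.random.Generator) -> list[_Payload]:
    """Payload(s) for one gene-movement footprint pattern.

    Some patterns plant two blocks (donor + acceptor); the footprint
    TruthRecord always belongs to the first payload.
    """
    p = dict(spec.params)
    gc = config.gc_fraction
    pattern = spec.pattern
    if pattern == "A_tsd_capture":
        tsd_len = int(p.get("tsd_length", 10))
        te_len = int(p.get("te_length", 500))
        gene_len = int(p.get("gene_length", 400))
        tsd = _random_codes(rng, tsd_len, gc)
        te = _random_codes(rng, te_len, gc)
        gene = _random_codes(rng, gene_len, min(0.6, gc + 0.1))
        codes = np.concatenate([tsd, te, gene, tsd])
        n = tsd_len
        fp = TruthRecord(feature_id="", kind="footprint",
                         interval=(n, n + te_len + gene_len),
                         pattern=pattern, tsd_sequence=decode(tsd),
                         sub_intervals={"tsd_left": (0, n),
                                        "te": (n, n + te_len),
                                        "gene": (n + te_len, n + te_len + gene_len),
                                        "tsd_right": (n + te_len + gene_len,
                                                      n + te_len + gene_len + n)})
        te_truth = TruthRecord(feature_id="", kind="dna_te",
                               interval=(n, n + te_len),
                               family_name=p.get("te_family", "capture_TE"))
        gene_truth = TruthRecord(feature_id="", kind="gene",
                                 interval=(n + te_len, n + te_len + gene_len),
                                 family_name=p.get("gene_name", "captured_gene"),
                                 sub_intervals={"exon_1": (n + te_len,
                                                           n + te_len + gene_len)})
        return [_Payload(codes=codes, truth=fp, extra_truths=[te_truth, gene_truth])]
    if pattern == "B_shared_border":
        border_len = int(p.get("border_length", 6))
        gene_len = int(p.get("gene_length", 400))
        gene = _random_codes(rng, gene_len, min(0.6, gc + 0.1))
        border = _random_codes(rng, border_len, gc)
        codes = np.concatenate([gene, border])
        acceptor_fp = TruthRecord(
            feature_id="", kind="footprint", interval=(0, gene_len),
            pattern=pattern, tsd_sequence=decode(border),
            sub_intervals={"gene": (0, gene_len),
                           "border": (gene_len, gene_len + border_len)})
        acceptor_gene = TruthRecord(feature_id="", kind="gene",
                                    interval=(0, gene_len),
                                    family_name=p.get("gene_name", "moved_gene"),
                                    sub_intervals={"exon_1": (0, gene_len)})
        donor_gene = TruthRecord(feature_id="", kind="gene",
                                 interval=(0, gene_len),
                                 family_name=p.get("gene_name", "moved_gene") + "_donor",
                                 sub_intervals={"exon_1": (0, gene_len)})
        return [
            _Payload(codes=codes, truth=acceptor_fp, extra_truths=[acceptor_gene]),
            _Payload(codes=codes.copy(), truth=donor_gene),
        ]
    if pattern == "C_helitron_capture":
        flank = int(p.get("helitron_flank", 600))
        gene_len = int(p.get("gene_length", 400))
        left = _random_codes(rng, flank, gc)
        gene = _random_codes(rng, gene_len, min(0.6, gc + 0.1))
        right = _random_codes(rng, flank, gc)
        codes = np.concatenate([left, gene, right])
        total = len(codes)
        fp = TruthRecord(feature_id="", kind="footprint", interval=(0, total),
                         pattern=pattern,
                         sub_intervals={"helitron": (0, total),
                                        "gene": (flank, flank + gene_len)})
        hel = TruthRecord(feature_id="", kind="dna_te", interval=(0, total),
                          family_name=p.get("te_family", "Helitron_capture"))
        gene_truth = TruthRecord(feature_id="", kind="gene",
                                 interval=(flank, flank + gene_len),
                                 family_name=p.get("gene_name", "captured_gene"),
                                 sub_intervals={"exon_1": (flank, flank + gene_len)})
        return [_Payload(codes=codes, truth=fp, extra_truths=[hel, gene_truth])]
    if pattern == "D_tandem_flank":
        period = int(p.get("period", 3))
        copies = int(p.get("copies", 8))
        gene_len = int(p.get("gene_length", 400))
        unit = _random_codes(rng, period, gc)
        arr = np.tile(unit, copies)
        gene = _random_codes(rng, gene_len, min(0.6, gc + 0.1))
        codes = np.concatenate([arr, gene, arr])
        alen = len(arr)
        fp = TruthRecord(feature_id="", kind="footprint",
                         interval=(alen, alen + gene_len), pattern=pattern,
                         sub_intervals={"array_left": (0, alen),
                                        "gene": (alen, alen + gene_len),
                                        "array_right": (alen + gene_len,
                                                        alen + gene_len + alen)})
        gene_truth = TruthRecord(feature_id="", kind="gene",
                                 interval=(alen, alen + gene_len),
                                 family_name=p.get("gene_name", "flanked_gene"),
                                 sub_intervals={"exon_1": (alen, alen + gene_len)})
        arr_l = TruthRecord(feature_id="", kind="tandem_array", interval=(0, alen),
                            family_name=f"period{period}",
                            sub_intervals={"unit": (0, period)})
        arr_r = TruthRecord(feature_id="", kind="tandem_array",
                            interval=(alen + gene_len, alen + gene_len + alen),
                            family_name=f"period{period}",
                            sub_intervals={"unit": (alen + gene_len,
                                                    alen + gene_len + period)})
        return [_Payload(codes=codes, truth=fp,
                         extra_truths=[gene_truth, arr_l, arr_r])]
    if pattern == "E_retrocopy":
        n_exons = int(p.get("n_exons", 3))
        exon_len = int(p.get("exon_length", 300))
        intron_len = int(p.get("intron_length", 150))
        if n_exons < 2:
            raise ValueError("retrocopy pattern needs a multi-exon source gene")
        gspec = GeneSpec(name=p.get("gene_name", "retro_parent"),
                         n_exons=n_exons, exon_length=exon_len,
                         intron_length=intron_len)
        parent = _build_gene_payload(gspec, config, rng)
        exons = [parent.codes[s:e]
                 for _, (s, e) in sorted(parent.truth.sub_intervals.items())]
        copy_codes = np.concatenate(exons)
        fp = TruthRecord(feature_id="", kind="footprint",
                         interval=(0, len(copy_codes)), pattern=pattern,
                         sub_intervals={"gene": (0, len(copy_codes))})
        copy_gene = TruthRecord(feature_id="", kind="gene",
                                interval=(0, len(copy_codes)),
                                family_name=gspec.name + "_retro",
                                sub_intervals={"exon_1": (0, len(copy_codes))})
        return [_Payload(codes=copy_codes, truth=fp, extra_truths=[copy_gene]),
                parent]
    raise ValueError(f"unknown footprint pattern {pattern!r}")


# ---------------------------------------------------------------------------
# Region assembly
# ---------------------------------------------------------------------------

def _shift_interval(iv: Interval, pos: int, length: int) -> Interval:
    s, e = iv
    if s >= pos:
        return (s + length, e + length)
    if e > pos:
        return (s, e + length)
    return iv


def _apply_insertion(truths: list[TruthRecord], pos: int, length: int) -> None:
    for t in truths:
        t.interval = _shift_interval(t.interval, pos, length)
        t.sub_intervals = {k: _shift_interval(iv, pos, length)
                           for k, iv in t.sub_intervals.items()}


@dataclass
class SimResult:
    region_id: str
    sequence: str
    truths: list[TruthRecord]
    library: RepeatLibrary
    config: SimConfig

    def truths_of_kind(self, *kinds: str) -> list[TruthRecord]:
        return [t for t in self.truths if t.kind in kinds]


class Simulator:
    """Deterministic region builder; one master seed, per-feature substreams."""

    def __init__(self, config: SimConfig):
        self.config = config

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.config.seed) & 0x7FFFFFFF, stream])

    def _consensi(self) -> dict[str, LibraryEntry]:
        cfg = self.config
        consensi: dict[str, LibraryEntry] = {}
        order: list[tuple[str, str, int, int]] = []
        for spec in cfg.element_specs:
            for fam, cls in ((spec.family_name, spec.class_label),
                             (spec.partner_family, spec.class_label)):
                if fam and all(o[0] != fam for o in order):
                    order.append((fam, cls, spec.ltr_length, spec.internal_length))
        for spec in cfg.dna_te_specs:
            if all(o[0] != spec.family_name for o in order):
                order.append((spec.family_name, spec.class_label, 0, spec.length))
        for idx, (fam, cls, ltr_len, body_len) in enumerate(order):
            rng = self._rng(_STREAM_FAMILY + idx)
            if ltr_len:
                consensi[fam] = LibraryEntry(
                    family=fam, class_label=cls,
                    ltr=decode(_random_codes(rng, ltr_len, cfg.gc_fraction)),
                    internal=decode(_random_codes(rng, body_len, cfg.gc_fraction)))
            else:
                consensi[fam] = LibraryEntry(
                    family=fam, class_label=cls,
                    consensus=decode(_random_codes(rng, body_len, cfg.gc_fraction)))
        return consensi

    def run(self) -> SimResult:
        cfg = self.config
        consensi = self._consensi()
        seq = encode(make_background(cfg.region_length, cfg.gc_fraction,
                                     self._rng(_STREAM_BACKGROUND)))
        truths: list[TruthRecord] = []
        counters = {"gene": 0, "ltr_element": 0, "dna_te": 0,
                    "tandem_array": 0, "footprint": 0}
        prefix = {"gene": "g", "ltr_element": "e", "dna_te": "d",
                  "tandem_array": "t", "footprint": "f"}

        def next_id(kind: str) -> str:
            counters[kind] += 1
            return f"{prefix[kind]}_{counters[kind]:04d}"

        def place(rng: np.random.Generator, payload_len: int,
                  spec_pos, families: tuple[str, ...] = (),
                  host: TruthRecord | None = None) -> int:
            if isinstance(spec_pos, int):
                return spec_pos
            if host is not None:
                s, e = host.sub_intervals.get("internal", host.interval)
                pad = min(50, (e - s) // 4)
                return int(rng.integers(s + pad, e - pad))
            occupied = [t.interval for t in truths]
            if families:
                # keep same-family LTR copies (including chimera partner
                # LTRs) farther apart than the structural search span
                occupied += [
                    (t.interval[0] - cfg.family_spacing, t.interval[1] + cfg.family_spacing)
                    for fam, t in ltr_placed if fam in families]
            low = cfg.margin
            high = len(seq) - cfg.margin - payload_len
            if high <= low:
                raise RuntimeError("region too small for requested features")
            for _ in range(2000):
                pos = int(rng.integers(low, high))
                if all(pos + payload_len + cfg.margin <= s or pos >= e + cfg.margin
                       for s, e in occupied):
                    return pos
            raise RuntimeError("could not find a free position; region too crowded")

        def insert(payload: _Payload, pos: int, kind: str,
                   nested_in: str | None = None) -> TruthRecord:
            nonlocal seq
            _apply_insertion(truths, pos, len(payload.codes))
            seq = np.concatenate([seq[:pos], payload.codes, seq[pos:]])
            group = [payload.truth] + payload.extra_truths
            for t in group:
                t.interval = (t.interval[0] + pos, t.interval[1] + pos)
                t.sub_intervals = {k: (s + pos, e + pos)
                                   for k, (s, e) in t.sub_intervals.items()}
                t.feature_id = next_id(t.kind)
            payload.truth.nested_in = nested_in
            truths.extend(group)
            return payload.truth

        stream = _STREAM_FEATURE
        for gspec in cfg.gene_specs:
            rng = self._rng(stream); stream += 1
            payload = _build_gene_payload(gspec, cfg, rng)
            insert(payload, place(rng, len(payload.codes), gspec.position), "gene")

        planted_elements: dict[str, TruthRecord] = {}
        ltr_placed: list[tuple[str, TruthRecord]] = []
        # hosts first so guests can nest inside them
        ordered = sorted(cfg.element_specs, key=lambda s: s.nest_in is not None)
        for espec in ordered:
            rng = self._rng(stream); stream += 1
            host = None
            if espec.nest_in is not None:
                host = planted_elements.get(espec.nest_in)
                if host is None:
                    raise ValueError(f"nest_in target {espec.nest_in!r} not planted")
            payload = _build_element_payload(espec, consensi, cfg, rng)
            fams = (espec.family_name,) if not espec.partner_family else \
                (espec.family_name, espec.partner_family)
            pos = place(rng, len(payload.codes), espec.position,
                        families=fams, host=host)
            # pin repeat maximality against the host flanks now that the
            # insertion point is known (no-op for TSD-flanked payloads)
            _pin_maximality(payload.codes, payload.truth.sub_intervals, rng,
                            flank_before=int(seq[pos - 1]),
                            flank_after=int(seq[pos]))
            truth = insert(payload, pos, "ltr_element",
                           nested_in=host.feature_id if host else None)
            ltr_placed.append((espec.family_name, truth))
            if espec.partner_family:
                ltr_placed.append((espec.partner_family, truth))
            planted_elements[truth.feature_id] = truth
            if espec.nest_in is None:
                # allow nest_in references by family name as well
                planted_elements.setdefault(espec.family_name, truth)

        for dspec in cfg.dna_te_specs:
            rng = self._rng(stream); stream += 1
            payload = _build_dna_te_payload(dspec, consensi, cfg, rng)
            insert(payload, place(rng, len(payload.codes), dspec.position), "dna_te")

        for tspec in cfg.tandem_specs:
            rng = self._rng(stream); stream += 1
            payload = _build_tandem_payload(tspec, cfg, rng)
            insert(payload, place(rng, len(payload.codes), tspec.position),
                   "tandem_array")

        for fspec in cfg.footprint_specs:
            rng = self._rng(stream); stream += 1
            payloads = _build_footprint_payloads(fspec, cfg, rng)
            primary = insert(payloads[0],
                             place(rng, len(payloads[0].codes), fspec.position),
                             payloads[0].truth.kind)
            for extra in payloads[1:]:
                t = insert(extra, place(rng, len(extra.codes), "random"),
                           extra.truth.kind)
                if primary.kind == "footprint":
                    primary.donor_id = t.feature_id

        library = RepeatLibrary({fam: e for fam, e in consensi.items()})
        return SimResult(region_id=cfg.region_id, sequence=decode(seq),
                         truths=truths, library=library, config=cfg)


def simulate(config: SimConfig) -> SimResult:
    """Build one synthetic region from its configuration."""
    return Simulator(config).run()


def plant_element(sequence: str, spec: PlantSpec, config: SimConfig,
                  consensi: dict[str, LibraryEntry] | None = None,
                  rng: np.random.Generator | None = None,
                  position: int | None = None) -> tuple[str, TruthRecord]:
    """Plant a single LTR element into ``sequence``; returns the new sequence
    and the (absolute-coordinate) truth record.  Convenience wrapper around
    the machinery :class:`Simulator` uses."""
    rng = rng or np.random.default_rng(config.seed)
    if consensi is None:
        consensi = Simulator(replace(config, element_specs=[spec])). _consensi()
    codes = encode(sequence)
    if position is None:
        position = len(codes) // 2
    if not 1 <= position <= len(codes) - 1:
        raise ValueError("position must leave at least 1 bp of flank")
    payload = _build_element_payload(spec, consensi, config, rng)
    _pin_maximality(payload.codes, payload.truth.sub_intervals, rng,
                    flank_before=int(codes[position - 1]),
                    flank_after=int(codes[position]))
    out = np.concatenate([codes[:position], payload.codes, codes[position:]])
    t = payload.truth
    t.feature_id = "e_0001"
    t.interval = (t.interval[0] + position, t.interval[1] + position)
    t.sub_intervals = {k: (s + position, e + position)
                       for k, (s, e) in t.sub_intervals.items()}
    return decode(out), t


def plant_footprint(sequence: str, pattern: str, params: dict,
                    config: SimConfig | None = None,
                    rng: np.random.Generator | None = None,
                    position: int | None = None
                    ) -> tuple[str, list[TruthRecord]]:
    """Plant one gene-movement footprint; returns the new sequence and all
    truth records created (the footprint record first).  Patterns that plant
    a donor block place it a fixed offset after the primary block."""
    config = config or SimConfig(region_length=max(10_000, len(sequence)))
    rng = rng or np.random.default_rng(config.seed)
    spec = FootprintSpec(pattern=pattern, params=params)
    payloads = _build_footprint_payloads(spec, config, rng)
    codes = encode(sequence)
    if position is None:
        position = len(codes) // 3
    out_truths: list[TruthRecord] = []
    counter = 0

    def insert_one(codes, payload, pos):
        nonlocal counter
        _apply_insertion(out_truths, pos, len(payload.codes))
        group = [payload.truth] + payload.extra_truths
        for t in group:
            counter += 1
            t.feature_id = f"fp_{counter:04d}"
            t.interval = (t.interval[0] + pos, t.interval[1] + pos)
            t.sub_intervals = {k: (s + pos, e + pos)
                               for k, (s, e) in t.sub_intervals.items()}
        out_truths.extend(group)
        return np.concatenate([codes[:pos], payload.codes, codes[pos:]])

    codes = insert_one(codes, payloads[0], position)
    if len(payloads) > 1:
        donor_pos = min(len(codes) - 1,
                        position + len(payloads[0].codes) + 2000)
        codes = insert_one(codes, payloads[1], donor_pos)
        if out_truths[0].kind == "footprint":
            out_truths[0].donor_id = payloads[1].truth.feature_id
    return decode(codes), out_truths
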