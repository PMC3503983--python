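"""Structural annotation of LTR retrotransposons from raw sequence.

Three evidence sources are combined:

* **LTR pair search** — exact k-mer seeding of the sequence against itself
  (forward strand: the two LTRs of one element are co-oriented), ungapped
  X-drop extension along each seeded diagonal, and boundary trimming to a
  terminal run of exact matches.  Finds the [5'LTR ... 3'LTR] skeleton of
  intact elements.
* **Library matching** — seeded ungapped local alignment of each family
  consensus (LTR, internal, or whole-element for DNA TEs) against both
  strands; recovers solo-LTRs, truncated remnants and internal regions.
* **TSD detection** — exact duplicated host motif abutting the element
  boundaries; presence/absence of the target-site duplication later
  discriminates the removal mechanism.

Both alignment stages are ungapped by design: the accompanying simulator
evolves elements by substitution only, and on real data the annotator is a
screen whose hits a curator refines.  Coordinates are 0-based half-open.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import (decode, encode, extend_left, extend_right, kmer_index,
                   pack_kmers, revcomp, segment_identity, trim_to_match_run)

Interval = tuple[int, int]

#: TE class labels recognized in library metadata.  "Unclassified-RNA" is an
#: explicit Class I residue row (retrotransposon mass of unknown family);
#: "Unclassified" is the Class II catch-all.
CLASS_LABELS = ("Ty1/Copia", "Ty3/Gypsy", "LINE", "SINE", "Unclassified-RNA",
                "MITE/Tourist", "MITE/Stowaway", "hAT", "En-Spm", "MuDR",
                "Helitron", "Unclassified")

#: class labels that belong to Class I (retrotransposons)
CLASS_I = frozenset({"Ty1/Copia", "Ty3/Gypsy", "LINE", "SINE",
                     "Unclassified-RNA"})


@dataclass(frozen=True)
class LibraryEntry:
    """Consensus sequences for one repeat family."""

    family: str
    class_label: str
    ltr: str | None = None        # LTR consensus (LTR retrotransposons)
    internal: str | None = None   # internal-region consensus
    consensus: str | None = None  # whole-element consensus (DNA / non-LTR TEs)

    @property
    def full_length(self) -> int | None:
        """Reconstructed intact length: 2 LTRs + internal region."""
        if self.ltr is not None and self.internal is not None:
            return 2 * len(self.ltr) + len(self.internal)
        if self.consensus is not None:
            return len(self.consensus)
        return None


class RepeatLibrary:
    """Family-name -> :class:`LibraryEntry` mapping with FASTA round-trip.

    The FASTA dialect stores metadata as ``key=value`` tokens on the
    description line: ``>FAM_LTR family=FAM role=LTR class=Ty3/Gypsy``.
    Roles are ``LTR``, ``internal`` and ``full``.
    """

    def __init__(self, entries: dict[str, LibraryEntry] | None = None):
        self.entries: dict[str, LibraryEntry] = dict(entries or {})
        for name, entry in self.entries.items():
            if name != entry.family:
                raise ValueError(f"library key {name!r} != family {entry.family!r}")
            if not (entry.ltr or entry.internal or entry.consensus):
                raise ValueError(f"family {name!r} has no consensus sequence")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, family: str) -> LibraryEntry:
        return self.entries[family]

    def __contains__(self, family: str) -> bool:
        return family in self.entries

    def families(self) -> list[str]:
        return sorted(self.entries)

    def to_fasta(self, path) -> None:
        from .io import write_fasta
        records = []
        for name in self.families():
            e = self.entries[name]
            for role, seq in (("LTR", e.ltr), ("internal", e.internal),
                              ("full", e.consensus)):
                if seq is not None:
                    records.append((f"{name}_{role}",
                                    f"family={name} role={role} class={e.class_label}",
                                    seq))
        write_fasta(path, records)

    @classmethod
    def from_fasta(cls, path) -> "RepeatLibrary":
        from Bio import SeqIO
        partial: dict[str, dict] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            meta = dict(tok.split("=", 1) for tok in rec.description.split()
                        if "=" in tok)
            family = meta.get("family", rec.id)
            role = meta.get("role", "full")
            entry = partial.setdefault(family, {"class": meta.get("class", "Unclassified")})
            key = {"LTR": "ltr", "internal": "internal", "full": "consensus"}.get(role)
            if key is None:
                raise ValueError(f"unknown consensus role {role!r} for {family!r}")
            entry[key] = str(rec.seq).upper()
        entries = {
            fam: LibraryEntry(family=fam, class_label=d["class"],
                              ltr=d.get("ltr"), internal=d.get("internal"),
                              consensus=d.get("consensus"))
            for fam, d in partial.items()
        }
        return cls(entries)


@dataclass(frozen=True)
class LTRPairCandidate:
    """A candidate pair of co-oriented LTR copies found by self-comparison."""

    left: Interval
    right: Interval
    identity: float

    @property
    def span(self) -> int:
        """Outer distance covered by the putative element."""
        return self.right[1] - self.left[0]

    @property
    def outer(self) -> Interval:
        return (self.left[0], self.right[1])


@dataclass(frozen=True)
class TSD:
    """An exact target-site duplication flanking an element."""

    left_copy: Interval
    right_copy: Interval
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LibraryHit:
    """One ungapped local alignment of a family consensus to the region."""

    family: str
    role: str                 # LTR | internal | full
    class_label: str
    interval: Interval        # region coordinates, forward
    consensus_span: Interval  # consensus coordinates, forward
    consensus_length: int
    identity: float
    strand: str               # '+' or '-'

    @property
    def coverage(self) -> float:
        """Fraction of the consensus covered by the alignment."""
        return (self.consensus_span[1] - self.consensus_span[0]) / self.consensus_length

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass(frozen=True)
class SubFeature:
    role: str                 # 5'LTR | 3'LTR | partial_LTR | internal | partial_internal | body
    interval: Interval
    family: str | None = None
    identity: float | None = None
    coverage: float | None = None


@dataclass
class AnnotatedElement:
    """A detected repeat element assembled from structural + homology evidence."""

    element_id: str
    family_name: str          # family or "unknown"
    class_label: str
    sub_features: list[SubFeature]
    tsd: TSD | None = None
    strand: str = "+"
    structural_pair: bool = False
    families_present: frozenset[str] = field(default_factory=frozenset)

    @property
    def interval(self) -> Interval:
        return (min(sf.interval[0] for sf in self.sub_features),
                max(sf.interval[1] for sf in self.sub_features))

    @property
    def length(self) -> int:
        s, e = self.interval
        return e - s

    def features_with_role(self, *roles: str) -> list[SubFeature]:
        return [sf for sf in self.sub_features if sf.role in roles]


# ---------------------------------------------------------------------------
# LTR pair search
# ---------------------------------------------------------------------------

def find_ltr_pairs(sequence: str, min_ltr: int = 100, max_ltr: int = 3000,
                   min_span: int = 1000, max_span: int = 18000,
                   min_identity: float = 0.80, seed_k: int = 20,
                   xdrop: int = 25, boundary_run: int = 8,
                   max_kmer_occ: int = 50) -> list[LTRPairCandidate]:
    """Candidate LTR pairs by exact-seeded self-comparison (forward strand).

    Seeds are exact shared ``seed_k``-mers; each seeded diagonal is extended
    ungapped with X-drop and the extent trimmed so both ends terminate in
    ``boundary_run`` consecutive matches.  Candidates must satisfy the
    length, span and identity bounds; overlapping candidates are resolved
    longest-outer-span-first; k-mers occurring more than ``max_kmer_occ``
    times (low-complexity sequence) are not used as seeds.
    """
    if min_ltr < seed_k:
        raise ValueError("min_ltr must be >= seed_k")
    if min_span <= 2 * min_ltr:
        raise ValueError("min_span must exceed 2*min_ltr")
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    if not sequence:
        return []
    a = encode(sequence)
    index = kmer_index(a, seed_k)
    covered: dict[int, list[Interval]] = {}
    raw: dict[tuple[Interval, Interval], float] = {}
    for positions in index.values():
        if len(positions) < 2 or len(positions) > max_kmer_occ:
            continue
        for ii in range(len(positions) - 1):
            for jj in range(ii + 1, len(positions)):
                i, j = positions[ii], positions[jj]
                d = j - i
                if d < min_ltr or d > max_span:
                    continue
                spans = covered.setdefault(d, [])
                if any(s <= i < e for s, e in spans):
                    continue
                right_ext = extend_right(a, a, i, j, xdrop)
                left_ext = extend_left(a, a, i, j, xdrop)
                s, e = i - left_ext, i + right_ext
                spans.append((s, e))
                s, e = trim_to_match_run(a, a, s, e, d, boundary_run)
                length = e - s
                if length < min_ltr or length > max_ltr:
                    continue
                if e > s + d:  # copies overlap
                    continue
                span = e + d - s
                if span < min_span or span > max_span:
                    continue
                ident = segment_identity(a, a, s, e, d)
                if ident < min_identity:
                    continue
                key = ((s, e), (s + d, e + d))
                raw[key] = max(raw.get(key, 0.0), ident)
    candidates = [LTRPairCandidate(left=k[0], right=k[1], identity=v)
                  for k, v in raw.items()]
    # longest-outer-span-first resolution of overlapping candidates
    candidates.sort(key=lambda c: (-c.span, c.left[0], -c.identity))
    kept: list[LTRPairCandidate] = []
    for cand in candidates:
        clash = False
        for other in kept:
            for iv1 in (cand.left, cand.right):
                for iv2 in (other.left, other.right):
                    if iv1[0] < iv2[1] and iv2[0] < iv1[1]:
                        clash = True
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda c: (c.left[0], -c.identity))
    return kept


# ---------------------------------------------------------------------------
# Library matching
# ---------------------------------------------------------------------------

def _scan_consensus(region: np.ndarray, region_idx: dict, cons: np.ndarray,
                    seed_k: int, xdrop: int, boundary_run: int,
                    merge_gap: int) -> list[tuple[int, int, int]]:
    """Ungapped seeded hits of one consensus orientation against the region.

    Returns merged segments as ``(cons_start, cons_end, diag)`` with
    ``diag = region_start - cons_start``.
    """
    packed = pack_kmers(cons, seed_k)
    covered: dict[int, list[Interval]] = {}
    segments: dict[int, list[Interval]] = {}
    for ci in range(len(packed)):
        key = int(packed[ci])
        if key < 0 or key not in region_idx:
            continue
        for rj in region_idx[key]:
            d = rj - ci
            spans = covered.setdefault(d, [])
            if any(s <= ci < e for s, e in spans):
                continue
            right_ext = extend_right(cons, region, ci, rj, xdrop)
            left_ext = extend_left(cons, region, ci, rj, xdrop)
            s, e = ci - left_ext, ci + right_ext
            spans.append((s, e))
            s, e = trim_to_match_run(cons, region, s, e, d, boundary_run)
            if e > s:
                segments.setdefault(d, []).append((s, e))
    merged: list[tuple[int, int, int]] = []
    for d, segs in segments.items():
        segs.sort()
        cur_s, cur_e = segs[0]
        for s, e in segs[1:]:
            if s - cur_e <= merge_gap:
                cur_e = max(cur_e, e)
            else:
                merged.append((cur_s, cur_e, d))
                cur_s, cur_e = s, e
        merged.append((cur_s, cur_e, d))
    return merged


def match_library(sequence: str, library: RepeatLibrary,
                  min_identity: float = 0.80, min_cov: float = 0.10,
                  seed_k: int = 12, xdrop: int = 30, boundary_run: int = 4,
                  min_len: int = 40, merge_gap: int = 50) -> list[LibraryHit]:
    """Local ungapped alignments of every family consensus against both strands.

    Hits below ``min_identity``, shorter than ``min_len`` bp, or covering
    less than ``min_cov`` of their consensus are dropped; overlapping hits
    are resolved best-identity-first.
    """
    if len(library) == 0:
        raise ValueError("repeat library is empty")
    if not sequence:
        return []
    region = encode(sequence)
    region_idx = kmer_index(region, seed_k)
    hits: list[LibraryHit] = []
    for family in library.families():
        entry = library[family]
        for role, seq in (("LTR", entry.ltr), ("internal", entry.internal),
                          ("full", entry.consensus)):
            if seq is None or len(seq) < seed_k:
                continue
            cons_fwd = encode(seq)
            n = len(cons_fwd)
            for strand in "+-":
                cons = cons_fwd if strand == "+" else revcomp(cons_fwd)
                for cs, ce, d in _scan_consensus(region, region_idx, cons,
                                                 seed_k, xdrop, boundary_run,
                                                 merge_gap):
                    length = ce - cs
                    if length < max(min_len, int(np.ceil(min_cov * n))):
                        continue
                    ident = segment_identity(cons, region, cs, ce, d)
                    if ident < min_identity:
                        continue
                    span = (cs, ce) if strand == "+" else (n - ce, n - cs)
                    hits.append(LibraryHit(
                        family=family, role=role,
                        class_label=entry.class_label,
                        interval=(cs + d, ce + d), consensus_span=span,
                        consensus_length=n, identity=ident, strand=strand))
    # best-identity-first overlap resolution
    hits.sort(key=lambda h: (-h.identity, -h.length, h.interval[0], h.family, h.role))
    kept: list[LibraryHit] = []
    for hit in hits:
        s, e = hit.interval
        overlap = 0
        for other in kept:
            os_, oe = other.interval
            overlap = max(overlap, min(e, oe) - max(s, os_))
        if overlap > 0.5 * hit.length:
            continue
        kept.append(hit)
    kept.sort(key=lambda h: h.interval)
    return kept


# ---------------------------------------------------------------------------
# TSD detection
# ---------------------------------------------------------------------------

def detect_tsd(sequence: str, element_interval: Interval, min_len: int = 4,
               max_len: int = 20, window: int = 2) -> TSD | None:
    """Longest exact duplicated motif abutting the element boundaries.

    The left copy must end within ``window`` bp left of the element start
    and the right copy start within ``window`` bp right of the element end.
    Ties are broken by closeness to the boundary, then leftmost.  Returns
    ``None`` if the longest such motif is shorter than ``min_len`` (motifs
    longer than ``max_len`` are not searched).
    """
    start, end = element_interval
    if not 0 <= start < end <= len(sequence):
        raise ValueError("element interval outside sequence")
    if start < window + min_len or len(sequence) - end < window + min_len:
        raise ValueError("insufficient flank for TSD search")
    seq = sequence.upper()
    top = min(max_len, start - window, len(sequence) - end - window)
    for length in range(top, min_len - 1, -1):
        best: tuple[int, int, int] | None = None
        for le in range(start, start - window - 1, -1):       # left copy end
            for rs in range(end, end + window + 1):           # right copy start
                if seq[le - length:le] == seq[rs:rs + length]:
                    dist = (start - le) + (rs - end)
                    key = (dist, le - length, rs)
                    if best is None or key < best:
                        best = key
        if best is not None:
            _, ls, rs = best
            return TSD(left_copy=(ls, ls + length),
                       right_copy=(rs, rs + length),
                       sequence=seq[ls:ls + length])
    return None


# ---------------------------------------------------------------------------
# Element assembly
# ---------------------------------------------------------------------------

def _overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _extrapolate_hit(hit: LibraryHit, seq_len: int | None,
                     cap: int = 25) -> LibraryHit:
    """Extend a hit to the full consensus extent when only a few terminal
    consensus bases are unmatched (boundary-run trimming), leaving genuinely
    truncated remnants alone.  Exact under substitution-only evolution (no
    indels), so the refined interval recovers the element's true boundary.
    """
    (cs, ce), n = hit.consensus_span, hit.consensus_length
    s, e = hit.interval
    # consensus bases missing on the region-left / region-right side
    left_miss = cs if hit.strand == "+" else n - ce
    right_miss = n - ce if hit.strand == "+" else cs
    if 0 < left_miss <= cap and s - left_miss >= 0:
        s -= left_miss
        if hit.strand == "+":
            cs = 0
        else:
            ce = n
    if 0 < right_miss <= cap and (seq_len is None or e + right_miss <= seq_len):
        e += right_miss
        if hit.strand == "+":
            ce = n
        else:
            cs = 0
    if (s, e) == hit.interval:
        return hit
    return replace(hit, interval=(s, e), consensus_span=(cs, ce))


def _majority_family(feats: list[SubFeature]) -> tuple[str, frozenset[str]]:
    votes: dict[str, int] = {}
    for sf in feats:
        if sf.family:
            votes[sf.family] = votes.get(sf.family, 0) + (sf.interval[1] - sf.interval[0])
    present = frozenset(votes)
    if not votes:
        return "unknown", present
    return max(sorted(votes), key=lambda f: votes[f]), present


def assemble_elements(pairs: list[LTRPairCandidate], hits: list[LibraryHit],
                      sequence: str | None = None,
                      library: RepeatLibrary | None = None,
                      full_ltr_cov: float = 0.8, cluster_gap: int = 300,
                      tsd_min: int = 5, tsd_max: int = 20,
                      tsd_window: int = 2) -> list[AnnotatedElement]:
    """Merge structural LTR pairs and library hits into annotated elements.

    Each library hit is attached to the innermost structural pair containing
    it (nested guests keep their own hits); hits overlapping a pair's LTR
    intervals label that pair's family.  Leftover hits are clustered by
    proximity into homology-only elements (solos, truncated remnants,
    DNA/non-LTR TEs).  Structural evidence takes precedence over homology
    for coordinates.  If ``sequence`` is given, a TSD search is run around
    every element.
    """
    seq_len = len(sequence) if sequence is not None else None
    hits = [_extrapolate_hit(h, seq_len) if h.role in ("LTR", "internal") else h
            for h in hits]
    skeletons = sorted(pairs, key=lambda p: (p.outer[0], p.span))
    skel_feats: list[list[SubFeature]] = [[] for _ in skeletons]
    skel_ltr_info: list[dict[str, SubFeature]] = [dict() for _ in skeletons]
    leftovers: list[LibraryHit] = []

    def innermost_skeleton(iv: Interval) -> int | None:
        center = (iv[0] + iv[1]) // 2
        best, best_span = None, None
        for idx, p in enumerate(skeletons):
            o = p.outer
            if o[0] <= center < o[1]:
                if best_span is None or p.span < best_span:
                    best, best_span = idx, p.span
        return best

    for hit in hits:
        idx = innermost_skeleton(hit.interval)
        if idx is None:
            leftovers.append(hit)
            continue
        pair = skeletons[idx]
        placed = False
        for side, ltr_iv in (("5'LTR", pair.left), ("3'LTR", pair.right)):
            if hit.role == "LTR" and _overlap(hit.interval, ltr_iv) >= 0.5 * hit.length:
                prev = skel_ltr_info[idx].get(side)
                if prev is None or (hit.coverage or 0) > (prev.coverage or 0):
                    # homology hit refines the structural boundary
                    skel_ltr_info[idx][side] = SubFeature(
                        role=side, interval=hit.interval, family=hit.family,
                        identity=hit.identity, coverage=hit.coverage)
                placed = True
        if placed:
            continue
        gap = (pair.left[1], pair.right[0])
        if _overlap(hit.interval, gap) >= 0.5 * hit.length:
            if hit.role == "internal":
                role = "internal" if hit.coverage >= 0.5 else "partial_internal"
            else:
                role = "body"
            skel_feats[idx].append(SubFeature(
                role=role, interval=hit.interval, family=hit.family,
                identity=hit.identity, coverage=hit.coverage))
        else:
            leftovers.append(hit)

    elements: list[AnnotatedElement] = []
    for idx, pair in enumerate(skeletons):
        feats = [skel_ltr_info[idx].get("5'LTR") or SubFeature("5'LTR", pair.left),
                 *sorted(skel_feats[idx], key=lambda sf: sf.interval),
                 skel_ltr_info[idx].get("3'LTR") or SubFeature("3'LTR", pair.right)]
        family, present = _majority_family(feats)
        class_label = (library[family].class_label
                       if library is not None and family in library else "Unclassified")
        elements.append(AnnotatedElement(
            element_id="", family_name=family, class_label=class_label,
            sub_features=feats, structural_pair=True, families_present=present))

    # cluster leftover hits by proximity
    leftovers.sort(key=lambda h: h.interval)
    clusters: list[list[LibraryHit]] = []
    for hit in leftovers:
        if clusters and hit.interval[0] - clusters[-1][-1].interval[1] <= cluster_gap:
            clusters[-1].append(hit)
        else:
            clusters.append([hit])
    for cluster in clusters:
        feats = []
        ltr_hits = [h for h in cluster if h.role == "LTR"]
        internal_hits = [h for h in cluster if h.role == "internal"]
        for hit in cluster:
            if hit.role == "LTR":
                if hit.coverage >= full_ltr_cov:
                    before_internal = (not internal_hits or
                                       hit.interval[1] <= min(h.interval[0] for h in internal_hits))
                    if len(ltr_hits) >= 2 and hit is ltr_hits[-1]:
                        role = "3'LTR"
                    elif before_internal:
                        role = "5'LTR"
                    else:
                        role = "3'LTR"
                else:
                    role = "partial_LTR"
            elif hit.role == "internal":
                role = "internal" if hit.coverage >= 0.5 else "partial_internal"
            else:
                role = "body"
            feats.append(SubFeature(role=role, interval=hit.interval,
                                    family=hit.family, identity=hit.identity,
                                    coverage=hit.coverage))
        feats.sort(key=lambda sf: sf.interval)
        family, present = _majority_family(feats)
        class_label = (library[family].class_label
                       if library is not None and family in library else "Unclassified")
        strand = cluster[0].strand
        elements.append(AnnotatedElement(
            element_id="", family_name=family, class_label=class_label,
            sub_features=feats, strand=strand, families_present=present))

    elements.sort(key=lambda el: el.interval)
    numbered: list[AnnotatedElement] = []
    for i, el in enumerate(elements, start=1):
        el.element_id = f"elem_{i:04d}"
        if sequence is not None:
            try:
                el.tsd = detect_tsd(sequence, el.interval, min_len=tsd_min,
                                    max_len=tsd_max, window=tsd_window)
            except ValueError:
                el.tsd = None
        numbered.append(el)
    return numbered


def annotate_region(sequence: str, library: RepeatLibrary,
                    pair_params: dict | None = None,
                    match_params: dict | None = None,
                    assemble_params: dict | None = None) -> list[AnnotatedElement]:
    """Run the full annotation stack on one region."""
    pairs = find_ltr_pairs(sequence, **(pair_params or {}))
    hits = match_library(sequence, library, **(match_params or {}))
    return assemble_elements(pairs, hits, sequence=sequence, library=library,
                             **(assemble_params or {}))
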