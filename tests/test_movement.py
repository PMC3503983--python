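"""Movement-footprint scanner tests: tandem arrays (with brute-force
oracle), the five pattern scanners, and evidence-verbatim invariants."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ltrfate import movement, sim
from ltrfate.movement import (GeneAnnotation, TEAnnotationLite,
                              find_tandem_arrays, flag_retrocopy,
                              scan_helitron_capture, scan_shared_border,
                              scan_tandem_flank, scan_tsd_capture)


def brute_force_arrays(seq, min_period, max_period, min_copies, min_length):
    """Exact-mode oracle: for every (start, period), the maximal run of
    consecutive self-shift agreements."""
    out = []
    n = len(seq)
    for k in range(min_period, max_period + 1):
        i = 0
        while i + k < n:
            if seq[i] != seq[i + k]:
                i += 1
                continue
            j = i
            while j + k < n and seq[j] == seq[j + k]:
                j += 1
            length = j - i + k
            if length / k >= min_copies and length >= min_length:
                out.append((i, i + length, k))
            i = j + 1
    return set(out)


class TestFindTandemArrays:
    def test_dinucleotide_repeat(self):
        arrays = find_tandem_arrays("ATATATATAT", min_copies=4, min_length=0)
        assert len(arrays) == 1
        a = arrays[0]
        assert a.period == 2 and a.copies == 5 and a.interval == (0, 10)

    def test_planted_array_recovered(self):
        seq, truths = sim.plant_footprint(sim.make_background(20000, 0.43, 8),
                                          "D_tandem_flank",
                                          {"period": 3, "copies": 8})
        arr_truths = [t for t in truths if t.kind == "tandem_array"]
        arrays = find_tandem_arrays(seq)
        for t in arr_truths:
            close = [a for a in arrays
                     if abs(a.interval[0] - t.interval[0]) <= a.period
                     and abs(a.interval[1] - t.interval[1]) <= a.period]
            assert close, f"array at {t.interval} not recovered"

    def test_null_scan_clean(self):
        seq = sim.make_background(10000, 0.43, 99)
        arrays = find_tandem_arrays(seq, min_period=1, max_period=6,
                                    min_copies=5)
        assert arrays == []

    def test_invalid_period_bounds(self):
        with pytest.raises(ValueError):
            find_tandem_arrays("ACGT", min_period=3, max_period=2)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 9999))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # random sequence with an implanted short repeat
        bg = "".join(rng.choice(list("ACGT"), 400))
        unit = "".join(rng.choice(list("ACGT"), int(rng.integers(1, 5))))
        rep = unit * int(rng.integers(4, 9))
        pos = int(rng.integers(0, 380))
        seq = bg[:pos] + rep + bg[pos:]
        got = {(a.interval[0], a.interval[1], a.period)
               for a in find_tandem_arrays(seq, 1, 6, 4, 0.0, min_length=0)}
        want = brute_force_arrays(seq, 1, 6, 4, 0)
        # the scanner applies longest-first overlap resolution; every kept
        # call must be a brute-force maximal run, and every brute-force run
        # must be covered by a kept call
        assert got <= want
        for s, e, k in want:
            assert any(a[0] < e and s < a[1] for a in got)


class TestScanTsdCapture:
    def test_planted_pattern_recovered(self, footprint_result):
        res = footprint_result
        genes = [GeneAnnotation(t.feature_id, t.interval)
                 for t in res.truths_of_kind("gene")]
        tes = [TEAnnotationLite(t.feature_id, t.interval)
               for t in res.truths_of_kind("dna_te")]
        calls = scan_tsd_capture(res.sequence, tes, genes)
        planted = [t for t in res.truths_of_kind("footprint")
                   if t.pattern == "A_tsd_capture"]
        assert len(planted) == 2
        for t in planted:
            hit = [c for c in calls if c.interval == t.interval]
            assert hit and hit[0].evidence["tsd"] == t.tsd_sequence
            assert hit[0].score == len(t.tsd_sequence)

    def test_ordinary_element_tsd_not_called(self):
        """A routine 5 bp element TSD with no adjacent gene must not
        produce a capture call."""
        cfg = sim.SimConfig(region_length=20000, seed=13, element_specs=[
            sim.PlantSpec(family_name="F")])
        res = sim.simulate(cfg)
        t = res.truths_of_kind("ltr_element")[0]
        tes = [TEAnnotationLite("te1", t.interval)]
        assert scan_tsd_capture(res.sequence, tes, []) == []

    def test_no_tes_empty(self):
        genes = [GeneAnnotation("g", (100, 400))]
        assert scan_tsd_capture("ACGT" * 500, [], genes) == []


class TestScanSharedBorder:
    def test_planted_border_recovered(self, footprint_result):
        res = footprint_result
        planted = [t for t in res.truths_of_kind("footprint")
                   if t.pattern == "B_shared_border"]
        assert len(planted) == 2
        for fp in planted:
            donor = next(t for t in res.truths if t.feature_id == fp.donor_id)
            call = scan_shared_border(res.sequence, fp.interval,
                                      res.sequence, donor.interval)
            assert call is not None
            # the call may extend past the planted 6-mer by chance agreement
            assert call.evidence["border"].startswith(fp.tsd_sequence)
            assert call.score >= 6

    def test_random_flanks_give_none(self):
        rng = np.random.default_rng(17)
        misses = 0
        for _ in range(20):
            acc = "".join(rng.choice(list("ACGT"), 300))
            don = "".join(rng.choice(list("ACGT"), 300))
            if scan_shared_border(acc, (100, 200), don, (100, 200)) is None:
                misses += 1
        assert misses >= 19  # chance >=6 bp identical border is ~2*4^-6

    def test_identical_flanks_full_match(self):
        seq = "ACGTACGTAC" * 30
        call = scan_shared_border(seq, (100, 200), seq, (100, 200))
        assert call is not None and call.score == 100

    def test_missing_flank_rejected(self):
        with pytest.raises(ValueError):
            scan_shared_border("ACGT", (0, 4), "ACGT", (1, 3))


class TestScanHelitronCapture:
    TES = [TEAnnotationLite("hel", (1000, 5000), "Helitron"),
           TEAnnotationLite("mite", (8000, 8800), "MITE/Tourist")]

    def test_contained_gene_flagged(self):
        genes = [GeneAnnotation("g", (2000, 3000))]
        calls = scan_helitron_capture(self.TES, genes)
        assert len(calls) == 1
        assert calls[0].evidence == {"helitron_id": "hel", "gene_id": "g"}

    def test_overlapping_but_not_contained(self):
        genes = [GeneAnnotation("g", (4500, 5500))]
        assert scan_helitron_capture(self.TES, genes) == []

    def test_no_helitrons_empty(self):
        genes = [GeneAnnotation("g", (8100, 8500))]
        assert scan_helitron_capture([self.TES[1]], genes) == []


class TestScanTandemFlank:
    def test_planted_pattern_recovered(self, footprint_result):
        res = footprint_result
        genes = [GeneAnnotation(t.feature_id, t.interval)
                 for t in res.truths_of_kind("gene")]
        arrays = find_tandem_arrays(res.sequence)
        calls = scan_tandem_flank(res.sequence, genes, arrays)
        planted = [t for t in res.truths_of_kind("footprint")
                   if t.pattern == "D_tandem_flank"]
        called = {c.evidence["gene_id"] for c in calls}
        for fp in planted:
            gid = next(t.feature_id for t in res.truths_of_kind("gene")
                       if t.interval == fp.interval)
            assert gid in called

    def test_one_sided_array_not_called(self):
        seq = "ACG" * 10 + "T" * 400 + "GATTACA" * 20
        genes = [GeneAnnotation("g", (30, 430))]
        arrays = [movement.TandemArray((0, 30), 3, 10, "ACG")]
        assert scan_tandem_flank(seq, genes, arrays) == []

    def test_window_zero_requires_abutment(self):
        arrays = [movement.TandemArray((0, 30), 3, 10, "ACG"),
                  movement.TandemArray((440, 470), 3, 10, "TCA")]
        genes = [GeneAnnotation("g", (30, 430))]
        assert scan_tandem_flank("N" * 500, genes, arrays, window=0) == []
        genes = [GeneAnnotation("g", (30, 440))]
        assert len(scan_tandem_flank("N" * 500, genes, arrays, window=0)) == 1


class TestFlagRetrocopy:
    GENES = [GeneAnnotation("parent", (0, 1000),
                            exons=((0, 300), (450, 750), (900, 1000))),
             GeneAnnotation("retro", (2000, 2700), exons=((2000, 2700),)),
             GeneAnnotation("multi", (4000, 5000),
                            exons=((4000, 4300), (4600, 5000))),
             GeneAnnotation("single", (6000, 6100), exons=((6000, 6100),))]

    def test_retrocopy_pair_flagged(self):
        calls = flag_retrocopy(self.GENES, [("parent", "retro")])
        assert len(calls) == 1
        assert calls[0].evidence == {"retrocopy_id": "retro",
                                     "parent_id": "parent"}

    def test_two_multi_exon_paralogs_not_flagged(self):
        assert flag_retrocopy(self.GENES, [("parent", "multi")]) == []

    def test_single_exon_pair_not_flagged(self):
        assert flag_retrocopy(self.GENES, [("retro", "single")]) == []

    def test_length_mismatch_not_flagged(self):
        assert flag_retrocopy(self.GENES, [("parent", "single")]) == []

    def test_planted_retrocopies(self, footprint_result):
        res = footprint_result
        genes = [GeneAnnotation(t.feature_id, t.interval,
                                exons=tuple(iv for k, iv in
                                            sorted(t.sub_intervals.items())
                                            if k.startswith("exon")))
                 for t in res.truths_of_kind("gene")]
        pairs = []
        for fp in res.truths_of_kind("footprint"):
            if fp.pattern != "E_retrocopy":
                continue
            copy_id = next(t.feature_id for t in res.truths_of_kind("gene")
                           if t.interval == fp.interval)
            pairs.append((copy_id, fp.donor_id))
        calls = flag_retrocopy(genes, pairs)
        assert len(calls) == len(pairs) == 2


class TestEvidenceVerbatim:
    def test_reported_motifs_occur_at_coordinates(self, footprint_result):
        """Every reported TSD motif re-extracted from the sequence at the
        footprint boundaries equals the evidence string."""
        res = footprint_result
        genes = [GeneAnnotation(t.feature_id, t.interval)
                 for t in res.truths_of_kind("gene")]
        tes = [TEAnnotationLite(t.feature_id, t.interval)
               for t in res.truths_of_kind("dna_te")]
        for call in scan_tsd_capture(res.sequence, tes, genes):
            motif = call.evidence["tsd"]
            s, e = call.interval
            assert res.sequence[s - len(motif):s] == motif
            assert res.sequence[e:e + len(motif)] == motif
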