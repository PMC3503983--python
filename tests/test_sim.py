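"""Generator tests: determinism, mutation calibration, fate geometry,
truth round-trips."""
import math

import numpy as np
import pytest

from ltrfate import io, sim
from ltrfate._seq import encode
from ltrfate.fates import FateCategory as FC


def expected_divergence(d, kappa):
    """Closed-form expected raw mismatch fraction between two copies that
    each evolved a branch of d substitutions/site (total branch 2d)."""
    beta = 2 * d / (kappa + 2.0)
    alpha = kappa * beta
    p_ts = 0.25 + 0.25 * math.exp(-4 * beta) - 0.5 * math.exp(-2 * (alpha + beta))
    p_tv = 0.5 - 0.5 * math.exp(-4 * beta)
    return p_ts + p_tv


class TestBackground:
    def test_deterministic_per_seed(self):
        assert sim.make_background(1000, 0.5, 42) == sim.make_background(1000, 0.5, 42)
        assert sim.make_background(1000, 0.5, 42) != sim.make_background(1000, 0.5, 43)

    def test_gc_calibration(self):
        seq = sim.make_background(100000, 0.43, 7)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.43) < 0.02
        assert len(seq) == 100000

    def test_degenerate_length_rejected(self):
        with pytest.raises(ValueError):
            sim.make_background(0, 0.5, 1)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"region_length": 5000},
        {"region_length": 20000, "gc_fraction": 0.0},
        {"region_length": 20000, "rate": 0.0},
        {"region_length": 20000, "kappa": -1.0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sim.SimConfig(**kwargs)

    def test_solo_with_tsd_requires_tsd(self):
        with pytest.raises(ValueError):
            sim.PlantSpec(family_name="F", fate=FC.SOLO_WITH_TSD, tsd_length=0)

    def test_missing_nest_target_rejected(self):
        cfg = sim.SimConfig(region_length=30000, seed=1, element_specs=[
            sim.PlantSpec(family_name="G", nest_in="NOPE")])
        with pytest.raises(ValueError, match="nest_in"):
            sim.simulate(cfg)


class TestDeterminism:
    def test_identical_config_identical_output(self, nine_fate_result):
        again = sim.simulate(nine_fate_result.config)
        assert again.sequence == nine_fate_result.sequence
        assert [t.to_line() for t in again.truths] == \
            [t.to_line() for t in nine_fate_result.truths]


class TestMutationModel:
    def test_age_zero_ltrs_identical(self, intact_age0_result):
        t = intact_age0_result.truths_of_kind("ltr_element")[0]
        seq = intact_age0_result.sequence
        s5, e5 = t.sub_intervals["5'LTR"]
        s3, e3 = t.sub_intervals["3'LTR"]
        assert seq[s5:e5] == seq[s3:e3]

    def test_divergence_calibration(self):
        """Mean observed LTR-LTR mismatch over 50 elements within 3 SE of
        the closed-form two-rate expectation."""
        age, kappa, ltr_len, n = 1.0e6, 2.0, 1000, 50
        fracs = []
        for i in range(n):
            cfg = sim.SimConfig(region_length=12000, seed=2000 + i,
                                kappa=kappa, element_specs=[
                                    sim.PlantSpec(family_name="F", age_years=age,
                                                  ltr_length=ltr_len)])
            res = sim.simulate(cfg)
            t = res.truths_of_kind("ltr_element")[0]
            a = encode(res.sequence[slice(*t.sub_intervals["5'LTR"])])
            b = encode(res.sequence[slice(*t.sub_intervals["3'LTR"])])
            fracs.append(float(np.mean(a != b)))
        p = expected_divergence(cfg.rate * age, kappa)
        se = math.sqrt(p * (1 - p) / (ltr_len * n))
        assert abs(np.mean(fracs) - p) < 3 * se

    def test_single_element_mismatch_scale(self):
        """age 1e6 at r=1.3e-8: expected pairwise mismatch ~0.026, within
        binomial noise for a 1000 bp LTR."""
        cfg = sim.SimConfig(region_length=12000, seed=9, element_specs=[
            sim.PlantSpec(family_name="F", age_years=1e6)])
        res = sim.simulate(cfg)
        t = res.truths_of_kind("ltr_element")[0]
        a = encode(res.sequence[slice(*t.sub_intervals["5'LTR"])])
        b = encode(res.sequence[slice(*t.sub_intervals["3'LTR"])])
        frac = float(np.mean(a != b))
        p = expected_divergence(1.3e-8 * 1e6, 2.0)
        assert abs(frac - p) < 4 * math.sqrt(p * (1 - p) / 1000)


FATE_IDS = [f.name for f in FC]


@pytest.fixture(scope="module")
def by_fate(nine_fate_result):
    out = {}
    for t in nine_fate_result.truths_of_kind("ltr_element"):
        out.setdefault(t.fate, []).append(t)
    return out


class TestFateGeometry:
    @pytest.mark.parametrize("fate", list(FC), ids=FATE_IDS)
    def test_emitted_intervals_satisfy_fate(self, fate, by_fate, nine_fate_result):
        seq = nine_fate_result.sequence
        for t in by_fate[fate]:
            subs = t.sub_intervals
            roles = set(subs)
            if fate is FC.INTACT_LTR:
                assert {"5'LTR", "internal", "3'LTR", "tsd_left", "tsd_right"} <= roles
                assert seq[slice(*subs["tsd_left"])] == seq[slice(*subs["tsd_right"])]
                assert seq[slice(*subs["tsd_left"])] == t.tsd_sequence
            elif fate is FC.SOLO_WITH_TSD:
                # exactly one LTR-length interval, identical flanking k-mers
                assert "internal" not in roles and "3'LTR" not in roles
                assert t.interval[1] - t.interval[0] == \
                    subs["5'LTR"][1] - subs["5'LTR"][0]
                assert seq[slice(*subs["tsd_left"])] == seq[slice(*subs["tsd_right"])]
            elif fate is FC.SOLO_WITHOUT_TSD:
                assert roles == {"5'LTR"} and t.tsd_sequence is None
            elif fate is FC.INTACT_WITHOUT_TSD:
                assert {"5'LTR", "internal", "3'LTR"} <= roles
                assert "tsd_left" not in roles and t.tsd_sequence is None
            elif fate is FC.TRUNCATED_SOLO:
                assert roles == {"partial_LTR"}
                length = subs["partial_LTR"][1] - subs["partial_LTR"][0]
                assert length < 0.8 * 1000
            elif fate is FC.THREE_PRIME_LTR_DELETED:
                assert roles == {"5'LTR", "internal"}
            elif fate is FC.FIVE_PRIME_LTR_DELETED:
                assert roles == {"internal", "3'LTR"}
            elif fate is FC.PARTIALLY_DELETED:
                assert {"5'LTR", "partial_internal", "partial_LTR"} <= roles
            elif fate is FC.RECOMBINATION_COMPLEX:
                assert {"5'LTR", "3'LTR_partner"} <= roles

    def test_intervals_inside_region(self, nine_fate_result):
        n = len(nine_fate_result.sequence)
        for t in nine_fate_result.truths:
            assert 0 <= t.interval[0] < t.interval[1] <= n
            for s, e in t.sub_intervals.values():
                assert 0 <= s < e <= n

    def test_ltr_elements_only_overlap_when_nested(self, nine_fate_result):
        els = nine_fate_result.truths_of_kind("ltr_element")
        for i, a in enumerate(els):
            for b in els[i + 1:]:
                overlaps = a.interval[0] < b.interval[1] and \
                    b.interval[0] < a.interval[1]
                nested = b.nested_in == a.feature_id or a.nested_in == b.feature_id
                assert not overlaps or nested


class TestNesting:
    def test_guest_inside_host_interval(self):
        cfg = sim.SimConfig(region_length=40000, seed=11, element_specs=[
            sim.PlantSpec(family_name="HOST", internal_length=9000),
            sim.PlantSpec(family_name="GUEST", internal_length=3000,
                          nest_in="HOST", class_label="Ty1/Copia")])
        res = sim.simulate(cfg)
        host, guest = res.truths_of_kind("ltr_element")
        assert guest.nested_in == host.feature_id
        assert host.interval[0] < guest.interval[0]
        assert guest.interval[1] < host.interval[1]


class TestFootprintConstruction:
    def test_pattern_a_has_flanking_10mers(self):
        """The TSD-capture block carries two identical 10-mers at its outer
        boundaries (the defining 10 bp target-site duplication)."""
        seq, truths = sim.plant_footprint(sim.make_background(20000, 0.43, 3),
                                          "A_tsd_capture", {"tsd_length": 10})
        fp = truths[0]
        s, e = fp.interval
        assert len(fp.tsd_sequence) == 10
        assert seq[s - 10:s] == seq[e:e + 10] == fp.tsd_sequence

    def test_pattern_d_arrays_flank_gene(self):
        seq, truths = sim.plant_footprint(sim.make_background(20000, 0.43, 4),
                                          "D_tandem_flank",
                                          {"period": 3, "copies": 8})
        fp = truths[0]
        s, e = fp.interval
        left = fp.sub_intervals["array_left"]
        right = fp.sub_intervals["array_right"]
        assert left[1] == s and right[0] == e
        unit = seq[left[0]:left[0] + 3]
        assert seq[slice(*left)] == unit * 8

    def test_retrocopy_length_is_summed_exons(self):
        seq, truths = sim.plant_footprint(sim.make_background(20000, 0.43, 5),
                                          "E_retrocopy",
                                          {"n_exons": 3, "exon_length": 250})
        fp = truths[0]
        assert fp.interval[1] - fp.interval[0] == 3 * 250

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError, match="pattern"):
            sim.plant_footprint("A" * 20000, "Z_bogus", {})


class TestTruthEmission:
    def test_round_trip_reproduces_records(self, nine_fate_result, tmp_path):
        paths = io.emit_truth(nine_fate_result, tmp_path)
        back = io.load_truth_sidecar(paths["truth"])
        assert [t.to_line() for t in back] == \
            [t.to_line() for t in nine_fate_result.truths]

    def test_feature_count_conservation(self, nine_fate_result, tmp_path):
        paths = io.emit_truth(nine_fate_result, tmp_path)
        top_level = [f for f in io.read_gff3(paths["gff3"])
                     if f.featuretype != "part"]
        assert len(top_level) == len(nine_fate_result.truths)

    def test_empty_truth_list_still_valid(self, tmp_path):
        cfg = sim.SimConfig(region_length=10000, seed=1)
        res = sim.simulate(cfg)
        paths = io.emit_truth(res, tmp_path)
        assert io.read_fasta(paths["fasta"])[res.region_id] == res.sequence
        assert io.read_gff3(paths["gff3"]) == []
        assert io.load_truth_sidecar(paths["truth"]) == []
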