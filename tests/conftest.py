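"""Shared fixtures: small simulated regions used across test modules."""
import pytest

from ltrfate import sim
from ltrfate.fates import FateCategory as FC

#: family roster reused by multi-element fixtures
FAMILIES = [("F1", "Ty3/Gypsy"), ("F2", "Ty1/Copia"), ("F3", "Ty3/Gypsy"),
            ("F4", "Ty1/Copia"), ("F5", "Ty3/Gypsy"), ("F6", "Ty1/Copia")]


def nine_fate_specs(region_index: int, per_fate: int = 2,
                    ages=(0.3e6, 1.0e6, 1.8e6)):
    """Element specs covering all nine fates, cycling families and ages."""
    specs = []
    k = 0
    for fate in FC:
        for j in range(per_fate):
            fam, cls = FAMILIES[k % len(FAMILIES)]
            partner = (FAMILIES[(k + 1) % len(FAMILIES)][0]
                       if fate is FC.RECOMBINATION_COMPLEX else None)
            tsd = 0 if fate is FC.SOLO_WITHOUT_TSD else 5
            specs.append(sim.PlantSpec(
                family_name=fam, class_label=cls,
                age_years=ages[(region_index + j + k) % len(ages)],
                fate=fate, tsd_length=tsd, partner_family=partner))
            k += 1
    return specs


@pytest.fixture(scope="session")
def intact_age0_result():
    """One zero-age intact element: both LTR copies identical strings."""
    cfg = sim.SimConfig(region_length=20000, seed=42, element_specs=[
        sim.PlantSpec(family_name="FAM_A", ltr_length=500, internal_length=5000,
                      age_years=0.0, fate=FC.INTACT_LTR)])
    return sim.simulate(cfg)


@pytest.fixture(scope="session")
def nine_fate_result():
    """18 elements (2 per fate) in one 450 kb region at <=5% LTR divergence."""
    cfg = sim.SimConfig(region_length=450000, seed=77, region_id="nine",
                        element_specs=nine_fate_specs(0))
    return sim.simulate(cfg)


@pytest.fixture(scope="session")
def footprint_result():
    """Two planted footprints of each pattern plus background genes."""
    specs = [sim.FootprintSpec(pattern=p)
             for p in sim.FOOTPRINT_PATTERNS for _ in range(2)]
    cfg = sim.SimConfig(region_length=150000, seed=55, region_id="fp",
                        footprint_specs=specs,
                        gene_specs=[sim.GeneSpec(name=f"bg{i}") for i in range(3)])
    return sim.simulate(cfg)
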