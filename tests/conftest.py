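"""Shared fixtures: species suites are expensive, so they run once per session."""

import pytest

import cannonbone as cb
from cannonbone.experiments import run_suite
from cannonbone.morphology import MorphotypeSpec, SectionProfile
from cannonbone.scaling import ScalingSpec


@pytest.fixture(scope="session")
def material():
    return cb.Material()


@pytest.fixture(scope="session")
def scaling():
    return ScalingSpec.from_reference(cb.species_fixture("jaculus"))


@pytest.fixture(scope="session")
def suite_tables(material, scaling):
    """Both default experiment suites with per-species simulation results."""
    specs = list(cb.fixture_library().values())
    cfg = cb.SimulationConfig()
    out = {}
    for condition in ("unscaled", "scaled"):
        out[condition] = run_suite(
            specs, scaling, condition, material=material, config=cfg,
            return_results=True,
        )
    return out


def uniform_tube_spec(
    length=25.0, r_outer=1.0, thickness=0.5, name="tube"
) -> MorphotypeSpec:
    """Single uniform hollow tube, the workhorse for closed-form oracles."""
    return MorphotypeSpec(
        name=name,
        fusion="fused",
        length=length,
        profiles=(SectionProfile.uniform(r_outer, thickness),),
        limb_measurements=(length,),
        body_mass=10.0,
    )


@pytest.fixture
def tube_spec():
    return uniform_tube_spec()
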