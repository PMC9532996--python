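"""The two comparative experiment suites across the five morphotypes.

Unscaled: true anatomy, displacement scaled to body size by the limb
geometric mean.  Scaled: anatomy normalized to the reference length and
cortical thickness, fixed 3 mm displacement.  Prints both tables, the
body-size regression of peak GRF, and the hypothesis evaluation.

Takes a couple of minutes (ten explicit-dynamics simulations).
"""

from cannonbone import (
    Material,
    ScalingSpec,
    SimulationConfig,
    evaluate_hypotheses,
    fit_body_size_model,
    fixture_library,
    species_fixture,
)
from cannonbone.experiments import run_suite

material = Material()
config = SimulationConfig()
scaling = ScalingSpec.from_reference(species_fixture("jaculus"))
specs = list(fixture_library().values())

tables = {}
for condition in ("unscaled", "scaled"):
    tables[condition] = run_suite(
        specs, scaling, condition, material=material, config=config
    )
    print(f"--- {condition} suite ---")
    print(tables[condition][
        ["species", "fusion", "peak_vm_mpa", "peak_grf_n", "displacement_mm"]
    ].to_string(index=False, float_format=lambda x: f"{x:.3f}"))
    print()

fit = fit_body_size_model(tables["unscaled"], response="peak_grf_n")
print(f"unscaled peak GRF vs log10 body mass: {fit}")
print("(forces rise with body size when loading is scaled to the animal)")
print()
print(evaluate_hypotheses(tables["unscaled"], tables["scaled"]))
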