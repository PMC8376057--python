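"""End-to-end run on a synthetic landscape with known ground truth.

The recovery scenario lays out 20 survey squares (618 m side) holding six
habitat types in equal shares and places 40 bird units whose locations
follow known selection weights.  Running the full pipeline — plot
compositions, per-square availability, Manly/Chesson indices, BCa
bootstrap — should recover the electivities implied by those weights.
"""

import warnings

import pandas as pd

from habsel import (
    BootstrapSpec,
    bootstrap_all_habitats,
    build_availability,
    electivity_table,
    generate_landscape,
    place_units,
    recovery_scenario,
    scenario_ground_truth,
)

warnings.simplefilter("ignore")
pd.set_option("display.width", 120)

scenario = recovery_scenario(seed=11)
truth = scenario_ground_truth(scenario).epsilon["spring"]

maps = generate_landscape(scenario, 2017)
observations = place_units(scenario, maps, "spring", 2017)
availability = build_availability(maps, mode="per_square",
                                  source="square_map")
table = electivity_table(observations, maps, availability,
                         level="individual", radius=20.0)
summary = bootstrap_all_habitats(table, BootstrapSpec(seed=11))

report = summary.set_index("habitat")[
    ["mean_epsilon", "ci_low", "ci_high", "n_units", "significance"]]
report.insert(0, "true_epsilon", truth)
print(report.round(3))

# mean_epsilon tracks true_epsilon within a few hundredths; habitats with
# |true eps| >= 0.4 come out significant with the matching sign, and the
# near-neutral types straddle zero (not significant).
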