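"""Delta-corrected climate projection and habitat range change.

Takes a fitted ensemble, builds a deliberately biased pair of
climate-model layers for a warm scenario, removes the bias with the
delta method (observed baseline + model anomaly), projects suitability,
binarizes at the ensemble's max-TSS threshold, and prints the habitat
loss/gain/net percentages and areas.
"""

import numpy as np

from loligosdm import (
    GridSpec, NicheSpec, ScenarioDelta, binarize, build_ensemble, delta_correct_stack,
    evaluate, fit, generate_env_stack, generate_scenario_layers, habitat_area,
    project, range_change, simulate_survey, split,
)
from loligosdm.scenarios import ScenarioSpec, scenario_shift
from loligosdm.synthetic import GaussianResponse

COVS = ["sst", "sbt", "sss", "sbs"]

stack = generate_env_stack(GridSpec(cell_size=0.25), season="autumn", seed=1)
niche = NicheSpec(responses={"sbt": GaussianResponse(20.0, 2.0)})
survey = simulate_survey(stack, niche, n_stations=500, seed=2)
survey["presence"] = (survey["count"] > 0).astype(int)
occ = survey[["presence", *COVS]]
train, test = split(occ, seed=3)
models = {a: fit(a, train, COVS, seed=4) for a in ("GLM", "RF", "GBM")}
ens = build_ensemble(models, [evaluate(m, test) for m in models.values()],
                     test, auc_min=0.8)

scenario = ScenarioSpec("SSP5-8.5", "2090s")
delta = ScenarioDelta(
    shift=scenario_shift(scenario, COVS),          # the true change
    gcm_bias={"sst": 0.8, "sbt": 0.8, "sss": -0.3, "sbs": -0.3},
    noise_sd=0.1,
)
gcm_base, gcm_future, _truth = generate_scenario_layers(stack, delta, seed=5)
corrected = delta_correct_stack(stack, gcm_base, gcm_future)

current_map = project(ens, stack, scenario="baseline")
future_map = project(ens, corrected, scenario=scenario.label)
cur = binarize(current_map, ens.threshold)
fut = binarize(future_map, ens.threshold)
rep = range_change(cur, fut, scenario=scenario.label)

print(f"scenario {scenario.label}: "
      f"shift {scenario_shift(scenario, COVS)}")
print(f"current habitat: {rep.current_total} cells, "
      f"{habitat_area(cur):,.0f} km^2")
print(f"loss {rep.loss_pct:.2f}%  gain {rep.gain_pct:.2f}%  "
      f"net {rep.net_pct:.2f}%")
print(f"future habitat area: {rep.future_area_km2:,.0f} km^2")
print(f"novel-environment cells flagged: {future_map.novel_mask.sum()}")
# Loss% is signed negative and gain% is relative to the current range, so
# net = gain + loss; warming expands habitat here because the autumn
# baseline sits mostly below the species' 20 C optimum.
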