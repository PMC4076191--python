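"""Contrast habitat selection between the current landscape and an
encroachment scenario.

Simulates the same population on the baseline landscape and on one where the
centre 70% of each quadrat became mixed/deciduous forest, fits one pooled
RSF per run (availability = whole extent), and rank-tests the per-class
coefficient distributions between scenarios.
"""

import numpy as np

import ssfwalk as sw
from ssfwalk.landscape import ScenarioSpec, apply_encroachment
from ssfwalk.simulator import SimulationConfig, simulate
from ssfwalk.validation import scenario_contrast

study = sw.make_study(seed=5, nrows=120, ncols=120, n_individuals=1, n_steps=10)
grid_a = study["grid0"]
grid_b = apply_encroachment(grid_a, ScenarioSpec(quadrat_area_km2=9.0))

runs_a, runs_b = [], []
for rep in range(3):
    for runs, grid in ((runs_a, grid_a), (runs_b, grid_b)):
        cfg = SimulationConfig(n_individuals=3, n_iterations=80,
                               seed=100 + rep, selection_method="best90")
        _, log = simulate(grid.copy(), study["features"], study["model"],
                          study["distros"], cfg)
        runs.append(log)

out = scenario_contrast(runs_a, runs_b, grid_a, grid_b,
                        rng=np.random.default_rng(9))
print("per-class selection contrast (Wilcoxon-Mann-Whitney across runs):")
print(out["beta_tests"].round(3).to_string(index=False))
print(f"\nhome-range areas: baseline median "
      f"{np.median(out['mcp_a']):.2f} km^2, encroached median "
      f"{np.median(out['mcp_b']):.2f} km^2, "
      f"rank-test p = {out['mcp_test']['p']:.3f}")
print("-> significant per-class rows mark a functional response: selection "
      "changes when availability changes, without refitting the SSF.")
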