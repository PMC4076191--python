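"""Replay tracks through the latent-state submodels and fit the SSF.

Builds a synthetic study with a known "true" step-selection function,
replays the simulated tracks to manufacture the covariate table (energy
balance and memory direction are latent: only the replay engine can produce
them), then fits the three nested candidate models, ranks them by QIC, and
cross-validates the winner.
"""

import numpy as np

import ssfwalk as sw
import ssfwalk.replay as rp
from ssfwalk.ssf import build_independence_partition, kfold_cv, model_select, vif

study = sw.make_study(seed=7, nrows=120, ncols=120, n_individuals=3, n_steps=100)
table = rp.replay_tracks(study["tracks"], study["grid0"].copy(),
                         study["features"], study["distros"],
                         rng=np.random.default_rng(11), season_window=False)
print(f"covariate table: {table['stratum'].nunique()} strata x 21 rows "
      f"(1 observed + 20 random each)")

partition = build_independence_partition(table)
selection = model_select(table, partition)
print("\nQIC model selection (lower is better):")
print(selection[["K", "QIC", "dQIC", "weight"]].round(2).to_string())
print("-> the environment model (all 10 terms) generated these data and "
      "should carry all the QIC weight.")

best = selection.attrs["models"]["environment"]
truth = [sw.TRUE_BETA[t] for t in best.terms]
summary = best.summary().round(3)
summary["truth"] = truth
print("\nfitted coefficients vs truth (robust SEs via the sandwich):")
print(summary.to_string())

print("\nvariance inflation factors (multicollinearity screen):")
print(vif(table).round(2).to_string())
print("-> main effects and their uncentred energy-balance interactions "
      "share variance, so those pairs sit above the usual < 3 guideline.")

cv = kfold_cv(table, "environment", reps=20, rng=np.random.default_rng(5))
print(f"\nrank-bin cross-validation: observed r_s = {cv.mean_rs:.3f} "
      f"(95% CI {cv.ci[0]:.2f}..{cv.ci[1]:.2f}), "
      f"null r_s = {cv.null_mean:.3f}")
print("-> a model that ranks observed steps above their matched random "
      "steps gives r_s near 1; chance gives r_s near 0.")
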