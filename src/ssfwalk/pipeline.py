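"""End-to-end orchestration: synthetic study setup and the full pipeline.

``make_study`` builds a self-contained synthetic study: a patchy landscape,
an empirical-style step pool, a known "true" SSF, and tracks generated by
the simulator under score-proportional selection — the exact generative
counterpart of the conditional-logit likelihood, so refitting the replayed
tracks should recover the truth.  ``run_pipeline`` chains
synth -> replay -> fit/select/cv -> simulate -> validate and writes stamped
artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import landscape as ls
from . import replay as rp
from . import simulator as sim
from . import ssf as ssfmod
from . import trajectories as tj
from . import validation as vl
from .config import config_hash, load_config, substream

log = logging.getLogger(__name__)

#: Reference "true" environment-model coefficients for synthetic studies, on
#: this package's covariate scales (cover in %, altitude in m, energy-balance
#: interactions in MJ).  Chosen once to give informative but non-separated
#: selection: memory attraction, preference for a high gain/loss ratio and
#: altitude, avoidance of canopy cover, roads and regenerating cuts.
TRUE_BETA = {
    "cos_mem": 0.5, "g_over_l": 1.0, "cover": -0.02, "altitude": 0.005,
    "edge": 0.01, "road": -1.0, "recent_cut": 0.3, "regen_cut": -1.0,
    "gl_de": 0.02, "cover_de": -0.001,
}


def true_model(beta: dict | None = None) -> ssfmod.SSFModel:
    b = dict(TRUE_BETA)
    if beta:
        b.update(beta)
    terms = ssfmod.FORMULAS["environment"]
    return ssfmod.SSFModel.from_beta("environment", [b[t] for t in terms], terms)


def make_study(seed: int = 0, nrows: int = 150, ncols: int = 150,
               n_individuals: int = 4, n_steps: int = 120,
               beta: dict | None = None, cut_patches: int = 6,
               selection_method: str = "proportional"):
    """Synthetic study: landscape, step pool, truth model, simulated tracks.

    Returns a dict with grid (pristine copy in 'grid0'), features, distros,
    model (the truth), tracks, and the step log.
    """
    rng_land = substream(seed, "landscape")
    grid, features = ls.synth_landscape(int(rng_land.integers(2 ** 31)),
                                        nrows, ncols, cut_patches=cut_patches)
    rng_tracks = substream(seed, "tracks")
    distros = tj.synthetic_step_pool(rng_tracks)
    model = true_model(beta)
    cfg = sim.SimulationConfig(
        n_individuals=n_individuals, n_iterations=n_steps,
        selection_method=selection_method,
        seed=int(rng_tracks.integers(2 ** 31)),
    )
    grid_run = grid.copy()
    tracks, step_log = sim.simulate(grid_run, features, model, distros, cfg)
    return {"grid0": grid, "grid": grid_run, "features": features,
            "distros": distros, "model": model, "tracks": tracks,
            "step_log": step_log, "sim_config": cfg}


class StageError(RuntimeError):
    def __init__(self, stage, err):
        super().__init__(f"pipeline stage '{stage}' failed: {err}")
        self.stage = stage


def run_pipeline(cfg: dict | str | None = None, seed: int = 0,
                 outdir: str | Path = "pipeline_out",
                 nrows: int = 150, ncols: int = 150,
                 n_individuals: int = 4, n_steps: int = 250,
                 cv_reps: int = 20, scenario: bool = False) -> dict:
    """Run the full demo pipeline on a synthetic study and write artifacts.

    Stages: synth landscape -> generate tracks -> replay to covariate table
    -> fit / model-select / cross-validate -> simulate with the fitted model
    -> emergent-pattern validation (RSF correlation, home-range index)
    [-> encroachment scenario contrast].  Every CSV/JSON is stamped with the
    config hash and seed; rerunning with the same inputs reproduces them.
    """
    cfg = load_config(cfg)
    stamp = {"seed": int(seed), "config": config_hash(cfg)}
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"stamp": stamp}
    timer = time.perf_counter

    def stage(name):
        log.info("stage %s", name)
        return timer()

    try:
        t = stage("synth")
        study = make_study(seed, nrows=nrows, ncols=ncols,
                           n_individuals=n_individuals, n_steps=n_steps)
        ls.save_landscape(study["grid0"], out / "cover.asc", out / "dem.asc")
        tj.write_tracks_csv(study["tracks"], out / "tracks.csv")
        log.info("synth done in %.1fs", timer() - t)
    except Exception as err:
        raise StageError("synth", err) from err

    try:
        t = stage("replay")
        grid = study["grid0"].copy()
        rng = substream(seed, "replay")
        table = rp.replay_tracks(study["tracks"], grid, study["features"],
                                 study["distros"], rng=rng, season_window=False)
        rp.write_covariate_table(table, out / "covariates.csv",
                                 seed=stamp["seed"], cfg_hash=stamp["config"])
        log.info("replay done in %.1fs (%d strata)", timer() - t,
                 table["stratum"].nunique())
    except Exception as err:
        raise StageError("replay", err) from err

    try:
        t = stage("fit")
        partition = ssfmod.build_independence_partition(table)
        selection = ssfmod.model_select(table, partition)
        selection.to_csv(out / "model_selection.csv")
        best = selection.attrs["models"]["environment"]
        results["model_selection"] = selection
        results["fit"] = best
        best.summary().to_csv(out / "ssf_coefficients.csv")
        vifs = ssfmod.vif(table)
        vifs.to_csv(out / "vif.csv", header=["vif"])
        rng_cv = substream(seed, "fit-cv")
        cv = ssfmod.kfold_cv(table, "environment", reps=cv_reps, rng=rng_cv)
        results["cv"] = cv
        log.info("fit done in %.1fs", timer() - t)
    except Exception as err:
        raise StageError("fit", err) from err

    try:
        t = stage("simulate")
        rng_sim = substream(seed, "simulate")
        cfg_sim = sim.SimulationConfig(
            n_individuals=n_individuals, n_iterations=n_steps,
            selection_method=cfg["simulation"]["selection_method"],
            best90_exploit=cfg["simulation"]["best90_exploit"],
            seed=int(rng_sim.integers(2 ** 31)),
        )
        grid_sim = study["grid0"].copy()
        sim_tracks, sim_log = sim.simulate(grid_sim, study["features"], best,
                                           study["distros"], cfg_sim)
        tj.write_tracks_csv(sim_tracks, out / "sim_tracks.csv")
        sim_log.to_csv(out / "sim_step_log.csv", index=False)
        log.info("simulate done in %.1fs", timer() - t)
    except Exception as err:
        raise StageError("simulate", err) from err

    try:
        t = stage("validate")
        rng_val = substream(seed, "validate")
        ref_cls = cfg["validation"]["reference_class"]
        real_rsfs, idx_rows = [], []
        for tr_real, tr_sim in zip(study["tracks"], sim_tracks):
            hr_real = vl.mcp95(tr_real.xy)
            hr_sim = vl.mcp95(tr_sim.xy)
            if hr_real.degenerate or hr_sim.degenerate:
                continue
            c = vl.homerange_index(hr_sim.area_km2, hr_real.area_km2)
            real = vl.rsf_fit(tr_real.xy, hr_real.polygon, study["grid0"],
                              rng=rng_val, reference_class=ref_cls)
            simm = vl.rsf_fit(tr_sim.xy, hr_real.polygon, study["grid0"],
                              rng=rng_val, reference_class=ref_cls)
            comp = vl.compare_beta_vectors(real, [simm])
            idx_rows.append({"individual": tr_real.individual_id,
                             "homerange_index": c,
                             "R": comp["R"].iloc[0], "r_s": comp["r_s"].iloc[0]})
            real_rsfs.append(real)
        validation = pd.DataFrame(idx_rows)
        validation.to_csv(out / "validation.csv", index=False)
        results["validation"] = validation
        log.info("validate done in %.1fs", timer() - t)
    except Exception as err:
        raise StageError("validate", err) from err

    if scenario:
        try:
            t = stage("scenario")
            spec = ls.ScenarioSpec(
                quadrat_area_km2=cfg["landscape"]["quadrat_area_km2"],
                converted_fraction=cfg["landscape"]["converted_fraction"],
                target_class=cfg["landscape"]["target_class"],
                protected_classes=tuple(cfg["landscape"]["protected_classes"]),
            )
            grid_b = ls.apply_encroachment(study["grid0"], spec)
            rng_sc = substream(seed, "validate")
            runs_a, runs_b = [], []
            for r in range(2):
                for runs, g in ((runs_a, study["grid0"]), (runs_b, grid_b)):
                    c = sim.SimulationConfig(
                        n_individuals=n_individuals, n_iterations=n_steps,
                        selection_method="best90",
                        seed=int(rng_sc.integers(2 ** 31)))
                    _, slog = sim.simulate(g.copy(), study["features"], best,
                                           study["distros"], c)
                    runs.append(slog)
            contrast = vl.scenario_contrast(runs_a, runs_b, study["grid0"],
                                            grid_b, rng=rng_sc)
            contrast["beta_tests"].to_csv(out / "scenario_beta_tests.csv",
                                          index=False)
            results["scenario"] = contrast
            log.info("scenario done in %.1fs", timer() - t)
        except Exception as err:
            raise StageError("scenario", err) from err

    with open(out / "run_metadata.json", "w") as fh:
        json.dump({**stamp, "stages": "ok"}, fh, indent=2)
    return results
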