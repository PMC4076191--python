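"""Surrogate-data engine: replay observed tracks through the latent-state
submodels to build the step-selection covariate table.

For every observed step the animal's internal state (72 h energy ledger,
memory clusters) is known only because the recorded track is re-run through
the energetics and memory submodels.  Each observed step is paired with 20
random candidate steps sharing its start point; covariates are computed for
all 21, then the observed step alone advances the state (feeding depletes the
end cell's lichen, the ledger and memory update, the heading turns).  Random
steps never mutate state.

The same covariate computation drives the forward simulator, which is what
couples estimation and simulation: a simulated track replayed through this
module reproduces the covariates the simulator logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import state as st
from .landscape import FeatureLayers, LandscapeGrid, distance_angle_to_feature
from .state import AgentState, EnergeticsParams
from .trajectories import EmpiricalDistros, StepGeometry, Track, decompose_steps

log = logging.getLogger(__name__)

#: Covariates of the full (environment) model, in canonical order.
COVARIATE_COLUMNS = [
    "cos_mem", "g_over_l", "cover", "altitude", "edge",
    "road", "recent_cut", "regen_cut", "gl_de", "cover_de",
]

#: The 72 h energy balance enters the interaction terms in MJ so the design
#: matrix stays well-conditioned (a pure choice of units).
DE_SCALE = 1e-3

DISTURBANCE_KINDS = ("road", "recent_cut", "regenerating_cut")
_DIST_COLS = {"road": "road", "recent_cut": "recent_cut", "regenerating_cut": "regen_cut"}


@dataclass
class ReplayParams:
    energetics: EnergeticsParams = field(default_factory=EnergeticsParams)
    n_random: int = 20
    memory_capacity: int = 15
    patch_radius: float = st.PATCH_RADIUS
    m_consec: int = 2
    max_redraws: int = 100


def covariates_for_step(state: AgentState, candidate: StepGeometry,
                        grid: LandscapeGrid, features: FeatureLayers | None,
                        year: int | None = None,
                        params: ReplayParams | None = None) -> dict:
    """Covariate row for one candidate (or observed) step.

    End-of-step cover, edge and altitude come from the end cell; the energy
    gain is the hypothetical Michaelis-Menten gain at the end cell's current
    biomass (no depletion); the loss uses the step length and the altitude
    difference; the memory and disturbance direction terms use the step's
    start point and bearing; interactions use the energy balance at decision
    time, which is stratum-constant.
    """
    p = params or ReplayParams()
    ex, ey = candidate.end
    if not grid.contains(ex, ey):
        raise ValueError("candidate end outside grid")
    er, ec = grid.point_to_cell(ex, ey)
    sr, sc = grid.point_to_cell(*candidate.start)
    V = grid.lichen_at(er, ec)
    X = st.intake(V)
    G, _ = st.gain(X, p.energetics.body_mass, p.energetics.step_hours)
    L = st.loss(candidate, grid.altitude[sr, sc], grid.altitude[er, ec], p.energetics)
    de = state.delta_e
    de_mj = de * DE_SCALE
    row = {
        "cos_mem": st.cos_theta_mem(candidate.start, candidate.bearing, state.patch_array),
        "g_over_l": G / L,
        "cover": float(grid.cover[er, ec]),
        "altitude": float(grid.altitude[er, ec]),
        "edge": float(grid.edge[er, ec]),
    }
    for kind in DISTURBANCE_KINDS:
        if features is None:
            term = 0.0
        else:
            D, cth = distance_angle_to_feature(candidate.start, candidate.bearing,
                                               features, kind, year=year, grid=grid)
            f = st.f_disturbance(D, kind)
            term = cth * f
        row[_DIST_COLS[kind]] = term
    row["gl_de"] = row["g_over_l"] * de_mj
    row["cover_de"] = row["cover"] * de_mj
    row["delta_e"] = de
    row["sl"] = candidate.sl
    row["ta"] = np.nan if candidate.ta is None else candidate.ta
    row["x0"], row["y0"] = candidate.start
    row["x1"], row["y1"] = candidate.end
    return row


def advance_with_step(state: AgentState, step: StepGeometry, grid: LandscapeGrid,
                      params: ReplayParams | None = None) -> tuple[float, float, float]:
    """Apply one performed step: feed (gain + depletion), ledger, memory, heading.

    Returns ``(G_actual, L, grams_ingested)``.  Feeding happens only at the
    end cell; the intake demanded by the functional response is capped by the
    cell's remaining lichen mass, so grams removed from the grid always equal
    grams ingested.
    """
    p = params or ReplayParams()
    er, ec = grid.point_to_cell(*step.end)
    sr, sc = grid.point_to_cell(*step.start)
    V = grid.lichen_at(er, ec)
    X = st.intake(V)
    _, grams_wanted = st.gain(X, p.energetics.body_mass, p.energetics.step_hours)
    grams = grid.deplete_mass(er, ec, grams_wanted)
    G = st.ENERGY_PER_GRAM * grams
    L = st.loss(step, grid.altitude[sr, sc], grid.altitude[er, ec], p.energetics)
    st.update_ledger(state, G, L)
    st.update_memory(state, step.end)
    state.heading = step.bearing
    state.location = step.end
    return G, L, grams


def _fresh_state(individual_id: str, location, params: ReplayParams) -> AgentState:
    return AgentState(
        id=str(individual_id), location=tuple(location),
        body_mass=params.energetics.body_mass,
        memory_capacity=params.memory_capacity,
        patch_radius=params.patch_radius, m_consec=params.m_consec,
    )


def _draw_valid_candidates(start, heading, distros, n, grid, rng, max_redraws):
    """n candidate steps whose end points lie inside the grid (rejection)."""
    from .trajectories import draw_random_steps
    out = []
    attempts = 0
    while len(out) < n:
        if attempts >= max_redraws * n:
            return None
        cand = draw_random_steps(start, heading, distros, 1, rng)[0]
        attempts += 1
        if grid.contains(*cand.end):
            out.append(cand)
    return out


def replay_track(track: Track, grid: LandscapeGrid, features: FeatureLayers | None,
                 distros: EmpiricalDistros, params: ReplayParams | None = None,
                 rng: np.random.Generator | None = None,
                 season_window: bool = True) -> pd.DataFrame:
    """Replay one observed track; emit its strata of 1 observed + n random rows.

    Steps without a defined turning angle (series starts, post-gap steps)
    advance the state but emit no stratum, since candidate steps require a
    current heading.  Strata whose observed end leaves the grid are skipped
    with a warning and the chain restarts.
    """
    p = params or ReplayParams()
    rng = rng if rng is not None else np.random.default_rng(0)
    steps = decompose_steps(track, season_window=season_window)
    state = _fresh_state(track.individual_id, steps[0].start, p)
    rows: list[dict] = []
    stratum = 0
    grams_total = 0.0  # includes warm-up steps that emit no stratum
    for step in steps:
        if not grid.contains(*step.end):
            log.warning("track %s exits grid at t=%s; stratum skipped",
                        track.individual_id, step.t_end)
            continue
        obs_row = None
        if step.ta is not None:
            cands = _draw_valid_candidates(step.start, state.heading, distros,
                                           p.n_random, grid, rng, p.max_redraws)
            if cands is None:
                log.warning("track %s: candidate redraw cap hit; stratum skipped",
                            track.individual_id)
            else:
                stratum += 1
                obs_row = covariates_for_step(state, step, grid, features, params=p)
                obs_row.update(stratum=stratum, individual=track.individual_id,
                               t_end=step.t_end, case=1)
                rows.append(obs_row)
                for cand in cands:
                    r = covariates_for_step(state, cand, grid, features, params=p)
                    r.update(stratum=stratum, individual=track.individual_id,
                             t_end=step.t_end, case=0)
                    rows.append(r)
        G, L, grams = advance_with_step(state, step, grid, p)
        grams_total += grams
        if obs_row is not None:
            obs_row["grams_ingested"] = grams
    df = pd.DataFrame(rows)
    if len(df):
        if "grams_ingested" not in df.columns:
            df["grams_ingested"] = 0.0
        df["grams_ingested"] = df["grams_ingested"].fillna(0.0)
        front = ["stratum", "individual", "t_end", "case"]
        df = df[front + [c for c in df.columns if c not in front]]
    df.attrs["grams_total"] = grams_total
    return df


def replay_tracks(tracks, grid, features, distros, params=None, rng=None,
                  season_window: bool = True) -> pd.DataFrame:
    """Replay several individuals independently into one covariate table."""
    parts = []
    offset = 0
    for tr in tracks:
        df = replay_track(tr, grid, features, distros, params=params, rng=rng,
                          season_window=season_window)
        if len(df):
            df["stratum"] = df["stratum"] + offset
            offset = int(df["stratum"].max())
            parts.append(df)
    if not parts:
        return pd.DataFrame()
    return pd.concat(parts, ignore_index=True)


def write_covariate_table(df: pd.DataFrame, path, seed=None, cfg_hash=None) -> None:
    """Tidy CSV with a provenance comment header."""
    with open(path, "w") as fh:
        fh.write(f"# ssfwalk covariate table; seed={seed}; config={cfg_hash}\n")
        df.to_csv(fh, index=False)


def read_covariate_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", parse_dates=["t_end"])
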