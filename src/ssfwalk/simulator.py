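"""Forward individual-based simulation: SSF-scored biased correlated random walk.

Each iteration, each animal (in fixed id order) draws 21 candidate steps from
the empirical step-length/turning-angle distributions, scores them with the
fitted SSF (w = exp(beta.x)), selects one by the configured rule, moves,
feeds (depleting the end cell's lichen), and updates its energy ledger,
memory clusters, and heading.  Because animals act in series, lichen
depletion is order-dependent; the order and all draws are fixed by the seed.

Selection rules:

* ``best``      - always the highest-scoring candidate (seeded-shuffle tie-break)
* ``best90``    - the best with probability 0.9, else uniform over all candidates
* ``roulette``  - probability proportional to the logistic w/(1+w), normalized
* ``crw``       - uniform over candidates (the null correlated random walk)
* ``proportional`` - probability proportional to the raw score w; this is the
  exact generative counterpart of the conditional-logit likelihood and is the
  rule used for parameter-recovery calibration
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .landscape import FeatureLayers, LandscapeGrid
from .replay import COVARIATE_COLUMNS, ReplayParams, advance_with_step, covariates_for_step
from .ssf import SSFModel
from .state import AgentState
from .trajectories import EmpiricalDistros, StepGeometry, Track, draw_random_steps

log = logging.getLogger(__name__)

SELECTION_METHODS = ("best", "best90", "roulette", "crw", "proportional")

# Linear predictors are clipped before exponentiation; the logistic transform
# saturates there anyway, so selection probabilities are unaffected in practice.
_ETA_CLIP = 500.0


def winter_iterations(steps_per_day: int = 6) -> int:
    """Number of 4 h iterations in one winter season (Dec 28 - Apr 15)."""
    days = (_dt.date(2001, 4, 15) - _dt.date(2000, 12, 28)).days
    return days * steps_per_day


@dataclass
class SimulationConfig:
    n_individuals: int = 5
    n_iterations: int = field(default_factory=winter_iterations)
    n_candidates: int = 21
    selection_method: str = "best90"
    best90_exploit: float = 0.9
    seed: int = 0
    start_positions: list | None = None     # [(x, y), ...] or None
    start_class: int | None = 11            # random init over this class if no coords
    confinement: list | None = None         # per-individual shapely polygons
    start_time: str = "2008-12-28T00:00:00"
    step_hours: float = 4.0
    max_redraws: int = 100
    log_covariates: bool = True   # crw runs may skip scoring (rule ignores it)

    def __post_init__(self):
        if self.n_candidates < 2:
            raise ValueError("n_candidates must be >= 2")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.selection_method not in SELECTION_METHODS:
            raise ValueError(f"unknown selection method {self.selection_method!r}")


def score_candidates(state: AgentState, candidates, model: SSFModel,
                     grid: LandscapeGrid, features: FeatureLayers | None,
                     year: int | None = None,
                     params: ReplayParams | None = None
                     ) -> tuple[np.ndarray, pd.DataFrame]:
    """SSF scores w_i = exp(beta.x_i) for each candidate step.

    Returns (scores, covariate rows) so the caller can log what was scored.
    """
    rows = [covariates_for_step(state, c, grid, features, year=year, params=params)
            for c in candidates]
    X = np.array([[r[t] for t in model.terms] for r in rows], dtype=float)
    eta = np.clip(X @ model.beta, -_ETA_CLIP, _ETA_CLIP)
    return np.exp(eta), pd.DataFrame(rows)


def select_step(scores: np.ndarray, method: str, rng: np.random.Generator,
                exploit: float = 0.9) -> int:
    """Choose a candidate index from its scores under a selection rule."""
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n == 0:
        raise ValueError("empty scores")
    if method == "best":
        order = rng.permutation(n)  # seeded shuffle breaks ties
        return int(order[np.argmax(scores[order])])
    if method == "best90":
        if rng.random() < exploit:
            order = rng.permutation(n)
            return int(order[np.argmax(scores[order])])
        return int(rng.integers(n))
    if method == "roulette":
        p = scores / (1.0 + scores)
        tot = p.sum()
        p = np.full(n, 1.0 / n) if tot <= 0 else p / tot
        return int(rng.choice(n, p=p))
    if method == "proportional":
        tot = scores.sum()
        p = np.full(n, 1.0 / n) if tot <= 0 else scores / tot
        return int(rng.choice(n, p=p))
    if method == "crw":
        return int(rng.integers(n))
    raise ValueError(f"unknown selection method {method!r}")


def confine(draw_one, polygon: Polygon, rng: np.random.Generator,
            cap: int = 1000) -> StepGeometry:
    """Redraw a candidate until its end point falls inside the polygon.

    ``draw_one()`` must return a fresh StepGeometry each call.  If the cap is
    reached the shortest candidate seen is retained (and a warning logged),
    so an impossible confinement cannot hang the simulation.
    """
    if polygon.is_empty or polygon.area == 0:
        raise ValueError("degenerate confinement polygon")
    best = None
    for _ in range(cap):
        cand = draw_one()
        if polygon.contains(Point(*cand.end)):
            return cand
        if best is None or cand.sl < best.sl:
            best = cand
    log.warning("confinement redraw cap reached; shortest candidate retained")
    return best


def _initial_states(grid: LandscapeGrid, config: SimulationConfig,
                    rng: np.random.Generator, params: ReplayParams) -> list[AgentState]:
    states = []
    for i in range(config.n_individuals):
        if config.start_positions is not None:
            xy = tuple(config.start_positions[i])
        else:
            cand = np.argwhere(grid.cover_type == config.start_class) \
                if config.start_class is not None else None
            if cand is None or len(cand) == 0:
                cand = np.argwhere(np.ones_like(grid.cover_type, dtype=bool))
            r, c = cand[rng.integers(len(cand))]
            xy = grid.cell_center(int(r), int(c))
        state = AgentState(id=f"sim{i:03d}", location=xy,
                           heading=float(rng.uniform(-math.pi, math.pi)),
                           body_mass=params.energetics.body_mass,
                           memory_capacity=params.memory_capacity,
                           patch_radius=params.patch_radius,
                           m_consec=params.m_consec)
        states.append(state)
    return states


def simulate(grid: LandscapeGrid, features: FeatureLayers | None, model: SSFModel,
             distros: EmpiricalDistros, config: SimulationConfig,
             params: ReplayParams | None = None
             ) -> tuple[list[Track], pd.DataFrame]:
    """Run the IBM; returns per-individual tracks and a chosen-step log.

    The step log holds, per individual and iteration, the covariates and
    score of the selected step plus the realized energy bookkeeping; it is
    the simulation-side counterpart of the replay covariate table.
    """
    p = params or ReplayParams()
    rng = np.random.default_rng(config.seed)
    states = _initial_states(grid, config, rng, p)
    t0 = np.datetime64(config.start_time)
    dt = np.timedelta64(int(config.step_hours * 3600), "s")
    positions = {s.id: [s.location] for s in states}
    rows = []
    for it in range(config.n_iterations):
        t_end = t0 + (it + 1) * dt
        for idx, state in enumerate(states):
            poly = config.confinement[idx] if config.confinement else None

            def draw_one(state=state, poly=poly):
                for _ in range(config.max_redraws):
                    c = draw_random_steps(state.location, state.heading, distros, 1, rng)[0]
                    if grid.contains(*c.end):
                        return c
                return None

            cands = []
            trapped = False
            for _ in range(config.n_candidates):
                if poly is not None:
                    try:
                        c = confine(lambda: draw_one() or StepGeometry(
                            state.location, state.location, 0.0, state.heading, 0.0),
                            poly, rng)
                    except ValueError:
                        raise
                else:
                    c = draw_one()
                if c is None:
                    trapped = True
                    break
                cands.append(c)
            if trapped:
                log.warning("individual %s trapped at iteration %d; stays put",
                            state.id, it)
                positions[state.id].append(state.location)
                continue
            if config.selection_method == "crw" and not config.log_covariates:
                scores = np.ones(len(cands))
                cov = None
            else:
                scores, cov = score_candidates(state, cands, model, grid,
                                               features, params=p)
            choice = select_step(scores, config.selection_method, rng,
                                 exploit=config.best90_exploit)
            step = cands[choice]
            delta_e_before = state.delta_e
            G, L, grams = advance_with_step(state, step, grid, p)
            rec = {} if cov is None else cov.iloc[choice].to_dict()
            rec.update(individual=state.id, iteration=it, t_end=t_end,
                       score=scores[choice], G_actual=G, L=L,
                       grams_ingested=grams, delta_e_before=delta_e_before,
                       x0=step.start[0], y0=step.start[1],
                       x1=step.end[0], y1=step.end[1], sl=step.sl)
            rows.append(rec)
            positions[state.id].append(step.end)
    tracks = []
    for s in states:
        pts = np.array(positions[s.id])
        times = t0 + np.arange(len(pts)) * dt
        tracks.append(Track(s.id, times, pts))
    return tracks, pd.DataFrame(rows)
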