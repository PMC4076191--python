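"""Generative-mechanism submodels: intake energetics, spatial memory,
and the disturbance-distance kernel.

These are the latent-state models replayed alongside observed tracks to
manufacture the covariates (energy balance, memory direction) that GPS data
alone cannot provide.

Energetics: short-term lichen intake follows a Michaelis-Menten functional
response X = a V / (b + V) with a = 61.3 g/day/kg and b = 40 g/m^2; intake is
converted to energy at 7.79 kJ/g.  Expenditure per 4 h step is basal
metabolism plus linear costs of distance travelled and altitude climbed.  The
energy balance dE is the running sum of gains minus losses over the last 18
steps (72 h).

Memory: the animal remembers a bounded FIFO list of location clusters (patch
centroids with visit counts).  Being within 1600 m of a centroid sets the
in-patch flag and folds the new location into the centroid's running mean;
two consecutive off-patch locations within 1600 m of each other found a new
cluster, evicting the oldest at capacity.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .trajectories import StepGeometry, wrap_angle

# Printed model constants
A_MAX_INTAKE = 61.3      # g/day per kg body mass
B_HALF_SAT = 40.0        # g/m^2
ENERGY_PER_GRAM = 7.79   # kJ/g
PATCH_RADIUS = 1600.0    # m
LEDGER_STEPS = 18        # 72 h at 4 h steps

# Zero-crossing distances of the disturbance kernel (m)
DISTURBANCE_D0 = {"road": 1500.0, "recent_cut": 1600.0, "regenerating_cut": 1300.0}


def intake(V: float, a: float = A_MAX_INTAKE, b: float = B_HALF_SAT) -> float:
    """Michaelis-Menten intake rate X (g/day/kg) at cell biomass V (g/m^2)."""
    if np.any(np.asarray(V) < 0):
        raise ValueError("biomass V must be >= 0")
    return a * V / (b + V)


def gain(X: float, body_mass: float = 100.0, step_hours: float = 4.0,
         energy_per_gram: float = ENERGY_PER_GRAM) -> tuple[float, float]:
    """Energy gain for one step.

    Returns ``(G, grams)``: the grams of forage a ``body_mass``-kg animal
    ingests in ``step_hours`` at daily rate X, and the corresponding energy
    G = 7.79 kJ/g x grams.  Depletion of the landscape cell is the caller's
    responsibility (feed mode), so hypothetical candidate steps can reuse
    this function without touching the grid.
    """
    if X < 0:
        raise ValueError("intake rate must be >= 0")
    grams = X * body_mass * step_hours / 24.0
    return energy_per_gram * grams, grams


@dataclass
class EnergeticsParams:
    body_mass: float = 100.0
    step_hours: float = 4.0
    bmr_per_step: float = 1540.0   # kJ per step
    c_dist: float = 0.26           # kJ/m travelled
    c_climb: float = 2.5           # kJ/m climbed

    def __post_init__(self):
        if self.bmr_per_step <= 0:
            raise ValueError("bmr_per_step must be positive")


def loss(step: StepGeometry, altitude_start: float, altitude_end: float,
         params: EnergeticsParams | None = None) -> float:
    """Energy expenditure L (kJ) for one step: BMR + distance + climb terms.

    Descent is free: only positive altitude differences cost energy.
    """
    p = params or EnergeticsParams()
    if step.sl < 0:
        raise ValueError("step length must be >= 0")
    return p.bmr_per_step + p.c_dist * step.sl + p.c_climb * max(0.0, altitude_end - altitude_start)


@dataclass
class MemoryCluster:
    centroid: tuple[float, float]
    n_locations: int
    creation_order: int

    def absorb(self, location) -> None:
        n = self.n_locations
        cx = (n * self.centroid[0] + location[0]) / (n + 1)
        cy = (n * self.centroid[1] + location[1]) / (n + 1)
        self.centroid = (cx, cy)
        self.n_locations = n + 1


@dataclass
class AgentState:
    """Per-animal state carried through replay and simulation."""

    id: str
    location: tuple[float, float]
    heading: float = 0.0
    body_mass: float = 100.0
    ledger: deque = field(default_factory=lambda: deque(maxlen=LEDGER_STEPS))
    patch_array: list = field(default_factory=list)   # MemoryCluster, oldest first
    in_patch: bool = False
    memory_capacity: int = 15
    patch_radius: float = PATCH_RADIUS
    m_consec: int = 2
    _pending: list = field(default_factory=list)      # recent off-patch locations
    _next_order: int = 0

    @property
    def delta_e(self) -> float:
        """Energy balance over the last <= 18 steps (kJ); partial during warm-up."""
        return float(sum(self.ledger))


def update_ledger(state: AgentState, G: float, L: float) -> float:
    """Push one step's net energy G - L; evict beyond 18 entries; return sum."""
    state.ledger.append(G - L)
    return state.delta_e


def update_memory(state: AgentState, new_location) -> AgentState:
    """Fold a new location into the memory clusters (in place).

    Within ``patch_radius`` of the nearest centroid: update that centroid's
    running mean, bump its visit count, refresh it as most recent, set
    in_patch.  Otherwise, if ``m_consec`` consecutive off-patch locations lie
    within ``patch_radius`` of each other, found a new cluster at their mean
    (evicting the oldest cluster at capacity); else just clear in_patch.
    """
    x, y = float(new_location[0]), float(new_location[1])
    best, best_d = None, math.inf
    for cl in state.patch_array:
        d = math.hypot(x - cl.centroid[0], y - cl.centroid[1])
        if d < best_d:
            best, best_d = cl, d
    if best is not None and best_d < state.patch_radius:
        best.absorb((x, y))
        state.patch_array.remove(best)
        state.patch_array.append(best)  # refresh recency
        state.in_patch = True
        state._pending.clear()
        return state

    state.in_patch = False
    state._pending.append((x, y))
    if len(state._pending) > state.m_consec:
        state._pending = state._pending[-state.m_consec:]
    if len(state._pending) == state.m_consec:
        pts = state._pending
        close = all(
            math.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1]) < state.patch_radius
            for i in range(len(pts)) for j in range(i + 1, len(pts))
        )
        if close:
            cx = sum(p[0] for p in pts) / len(pts)
            cy = sum(p[1] for p in pts) / len(pts)
            cl = MemoryCluster((cx, cy), len(pts), state._next_order)
            state._next_order += 1
            state.patch_array.append(cl)
            if len(state.patch_array) > state.memory_capacity:
                # evict oldest by creation order
                oldest = min(state.patch_array, key=lambda c: c.creation_order)
                state.patch_array.remove(oldest)
            state.in_patch = True
            state._pending.clear()
    return state


def cos_theta_mem(start, bearing: float, patch_array) -> float:
    """Cosine of the minimum angle between a step bearing and any remembered
    patch centroid direction; 0 with empty memory (no directional pull).

    Centroids coincident with the start point have no defined direction and
    are skipped.
    """
    best = None
    for cl in patch_array:
        dx = cl.centroid[0] - start[0]
        dy = cl.centroid[1] - start[1]
        if dx == 0.0 and dy == 0.0:
            continue
        ang = abs(wrap_angle(math.atan2(dy, dx) - bearing))
        if best is None or ang < best:
            best = ang
    return 0.0 if best is None else math.cos(best)


def f_disturbance(D: float, kind: str) -> float:
    """Linear proximity kernel f(D) = max(0, 1 - D/D0), in [0, 1].

    D0 is the distance at which a feature's influence on step direction
    vanishes: 1500 m (roads), 1600 m (recent cuts), 1300 m (regenerating
    cuts).
    """
    if kind not in DISTURBANCE_D0:
        raise KeyError(f"unknown disturbance kind {kind!r}")
    if D < 0:
        raise ValueError("distance must be >= 0")
    if math.isinf(D):
        return 0.0
    return max(0.0, 1.0 - D / DISTURBANCE_D0[kind])
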