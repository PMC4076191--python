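"""GPS tracks, step decomposition, and empirical step distributions.

A track is an ordered series of 4 h fixes per animal.  Paths are broken into
straight-line steps between successive fixes; the step length (SL) and turning
angle (TA, angle from the previous step to the current one) pooled over all
animals in the winter window form the empirical distributions from which
candidate (random) steps are drawn.

Bearing convention is mathematical: radians counter-clockwise from +x.  TA is
normalized to (-pi, pi] and is undefined for the first step of a series and
for the step after a gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NOMINAL_INTERVAL_H = 4.0
GAP_TOLERANCE = 0.10  # fraction of the nominal interval
WINTER_START = (12, 28)  # Dec 28, inclusive
WINTER_END = (4, 15)     # Apr 15, inclusive


def wrap_angle(a: float) -> float:
    """Normalize an angle to (-pi, pi]."""
    a = (a + math.pi) % (2.0 * math.pi) - math.pi
    return math.pi if a == -math.pi else a


def in_winter(ts) -> bool:
    """True if a timestamp falls in the year-spanning winter window."""
    ts = pd.Timestamp(ts)
    md = (ts.month, ts.day)
    return md >= WINTER_START or md <= WINTER_END


def winter_days() -> int:
    """Length of the winter season in days (difference Dec 28 -> Apr 15)."""
    import datetime as _dt
    return ( _dt.date(2001, 4, 15) - _dt.date(2000, 12, 28) ).days


@dataclass
class Track:
    individual_id: str
    times: np.ndarray      # datetime64[ns], strictly increasing
    xy: np.ndarray         # (n, 2) metres

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be (n, 2)")
        if len(self.times) != len(self.xy):
            raise ValueError("times and xy lengths differ")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > np.timedelta64(0, "s")):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class StepGeometry:
    start: tuple[float, float]
    end: tuple[float, float]
    sl: float                      # m
    bearing: float                 # radians CCW from +x
    ta: float | None               # (-pi, pi], None after a gap / first step
    t_end: np.datetime64 | None = None

    @classmethod
    def from_points(cls, start, end, prev_bearing=None, t_end=None) -> "StepGeometry":
        dx, dy = end[0] - start[0], end[1] - start[1]
        sl = math.hypot(dx, dy)
        bearing = math.atan2(dy, dx) if sl > 0 else (prev_bearing or 0.0)
        ta = None if prev_bearing is None else wrap_angle(bearing - prev_bearing)
        return cls(tuple(start), tuple(end), sl, bearing, ta, t_end)


def decompose_steps(track: Track, season_window: bool = True) -> list[StepGeometry]:
    """Break a track into steps at the nominal fix interval.

    Fix pairs whose interval deviates from 4 h by more than 10% are gaps: no
    step spans them and the turning-angle chain restarts afterwards.  With
    ``season_window`` steps are kept only when both endpoints fall in winter.
    """
    if len(track) < 2:
        raise ValueError("need at least 2 fixes")
    steps: list[StepGeometry] = []
    prev_bearing = None
    dt_h = np.diff(track.times) / np.timedelta64(1, "h")
    for i, dh in enumerate(dt_h):
        ok_interval = abs(dh - NOMINAL_INTERVAL_H) <= GAP_TOLERANCE * NOMINAL_INTERVAL_H
        in_season = (not season_window) or (
            in_winter(track.times[i]) and in_winter(track.times[i + 1])
        )
        if not ok_interval or not in_season:
            prev_bearing = None  # TA chain restarts after a gap
            continue
        step = StepGeometry.from_points(
            track.xy[i], track.xy[i + 1], prev_bearing, t_end=track.times[i + 1]
        )
        steps.append(step)
        prev_bearing = step.bearing
    if not steps:
        raise ValueError("no usable steps (all gaps or out of season)")
    return steps


@dataclass
class EmpiricalDistros:
    """Pooled winter step-length and turning-angle samples.

    Draws are i.i.d. resamples with replacement from the raw pooled samples
    (no parametric fit), independently for SL and TA.
    """

    sl: np.ndarray
    ta: np.ndarray

    def __post_init__(self):
        self.sl = np.asarray(self.sl, dtype=float)
        self.ta = np.asarray(self.ta, dtype=float)
        if self.sl.size == 0 or self.ta.size == 0:
            raise ValueError("empirical pools must be non-empty")

    def draw(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        return rng.choice(self.sl, size=n), rng.choice(self.ta, size=n)


def empirical_distributions(tracks, season_window: bool = True) -> EmpiricalDistros:
    """Pool SL and TA over the decomposed steps of all individuals."""
    sls, tas = [], []
    for tr in tracks:
        try:
            steps = decompose_steps(tr, season_window=season_window)
        except ValueError:
            continue
        sls.extend(s.sl for s in steps)
        tas.extend(s.ta for s in steps if s.ta is not None)
    if not sls:
        raise ValueError("empty step pool")
    if not tas:
        tas = [0.0]  # single-step tracks: no turning angles observed
    return EmpiricalDistros(np.array(sls), np.array(tas))


def draw_random_steps(start, heading, distros: EmpiricalDistros, n,
                      rng: np.random.Generator) -> list[StepGeometry]:
    """Draw n candidate steps from the same start point.

    Each candidate has SL ~ empirical SL and TA ~ empirical TA; its bearing is
    ``heading + TA`` and its end point follows by planar trigonometry.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sl, ta = distros.draw(n, rng)
    out = []
    for s, t in zip(sl, ta):
        b = wrap_angle(heading + t)
        end = (start[0] + s * math.cos(b), start[1] + s * math.sin(b))
        out.append(StepGeometry(tuple(start), end, float(s), b, float(t)))
    return out


def synthetic_step_pool(rng: np.random.Generator, n: int = 2000,
                        sl_median: float = 250.0, sl_sigma: float = 0.8,
                        ta_kappa: float = 1.3) -> EmpiricalDistros:
    """Synthetic stand-in for a pooled winter step sample.

    Step lengths are log-normal (median ``sl_median`` m) and turning angles
    wrapped-normal around 0 (directional persistence), the shapes routinely
    reported for 4 h large-herbivore steps.  Serves as the empirical pool
    when no GPS data are loaded.
    """
    sl = rng.lognormal(mean=math.log(sl_median), sigma=sl_sigma, size=n)
    ta = np.array([wrap_angle(a) for a in rng.normal(0.0, ta_kappa, size=n)])
    return EmpiricalDistros(sl, ta)


# ---------------------------------------------------------------------------
# CSV I/O (columns: id, datetime ISO-8601, x, y)


def read_tracks_csv(path) -> list[Track]:
    df = pd.read_csv(path, parse_dates=["datetime"])
    tracks = []
    for ind, sub in df.groupby("id", sort=True):
        sub = sub.sort_values("datetime")
        tracks.append(Track(str(ind), sub["datetime"].to_numpy(),
                            sub[["x", "y"]].to_numpy(float)))
    return tracks


def write_tracks_csv(tracks, path) -> None:
    rows = []
    for tr in tracks:
        for t, (x, y) in zip(tr.times, tr.xy):
            rows.append({"id": tr.individual_id, "datetime": pd.Timestamp(t).isoformat(),
                         "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False)
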