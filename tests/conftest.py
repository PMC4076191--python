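import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import ssfwalk as sw
import ssfwalk.replay as rp

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def uniform_grid(nrows=40, ncols=40, cls=11, cell_size=25.0, altitude=0.0):
    """Flat single-class landscape (lichen/cover from the class tables)."""
    from ssfwalk.landscape import LandscapeGrid, class_tables
    biomass, cover = class_tables()
    shape = (nrows, ncols)
    return LandscapeGrid(
        origin=(0.0, 0.0), cell_size=cell_size,
        cover_type=np.full(shape, cls, dtype=np.int32),
        lichen_baseline=np.full(shape, biomass[cls]),
        cover=np.full(shape, cover[cls]),
        altitude=np.full(shape, float(altitude)),
    )


@pytest.fixture(scope="session")
def study():
    """Small synthetic study: known truth, simulated tracks (proportional rule)."""
    return sw.make_study(seed=7, nrows=120, ncols=120, n_individuals=3,
                         n_steps=100)


@pytest.fixture(scope="session")
def cov_table(study):
    rng = np.random.default_rng(11)
    return rp.replay_tracks(study["tracks"], study["grid0"].copy(),
                            study["features"], study["distros"], rng=rng,
                            season_window=False)


def make_track(points, start="2009-01-05T00:00:00", hours=4.0, individual="a"):
    pts = np.asarray(points, dtype=float)
    t0 = np.datetime64(start)
    times = t0 + np.arange(len(pts)) * np.timedelta64(int(hours * 3600), "s")
    return sw.Track(individual, times, pts)
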