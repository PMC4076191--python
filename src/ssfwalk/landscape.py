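"""Gridded landscape: layers, raster I/O, features, and scenario transforms.

The environment is a stack of co-registered 25 m raster layers (landcover
class, lichen biomass, canopy cover, canopy-cover gradient, altitude) plus
anthropogenic feature masks (roads, recent and regenerating cuts, burns) that
change year to year.  Coordinates are continuous planar metres; cells are
row-major with row 0 at the north edge and half-open footprints [x, x+cell).

Lichen is stored as a mutable depletion overlay on the immutable class-derived
baseline, so resetting a grazed landscape or transforming classes is cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import load_defaults

FEATURE_KINDS = ("road", "recent_cut", "regenerating_cut", "burned")


def class_tables(cfg: dict | None = None) -> tuple[dict[int, float], dict[int, float]]:
    """(class -> lichen g/m^2, class -> canopy cover %) lookup tables."""
    cfg = cfg or load_defaults()
    classes = cfg["classes"]
    biomass = {int(k): float(v["lichen"]) for k, v in classes.items()}
    cover = {int(k): float(v["cover"]) for k, v in classes.items()}
    return biomass, cover


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_ascii_grid(path, array, origin, cell_size, nodata=-9999.0) -> None:
    arr = np.asarray(array, dtype=float)
    nrows, ncols = arr.shape
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcorner {origin[0]:.6f}\nyllcorner {origin[1]:.6f}\n"
        f"cellsize {cell_size:.6f}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt="%.17g")  # full float64 precision round trip


def read_ascii_grid(path) -> tuple[np.ndarray, tuple[float, float], float]:
    """Returns (array, (xllcorner, yllcorner), cell_size)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) != 2 or not parts[0][0].isalpha():
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
        arr = np.loadtxt(fh)
    arr = np.atleast_2d(arr)
    origin = (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0))
    return arr, origin, header.get("cellsize", 1.0)


# ---------------------------------------------------------------------------
# Edge (canopy-gradient) operator


def derive_edge(cover_layer: np.ndarray) -> np.ndarray:
    """Gradient magnitude of canopy cover over the 3x3 Moore neighbourhood.

    Sobel-type: the field is smoothed with the [1,2,1]/4 kernel along the
    transverse axis, then differentiated with central differences (one-sided
    at the borders).  At interior cells this equals the classic Sobel kernel
    divided by 8, i.e. units of % per cell.
    """
    cov = np.asarray(cover_layer, dtype=float)
    if not np.all(np.isfinite(cov)):
        raise ValueError("cover layer must be finite")
    if cov.ndim != 2:
        raise ValueError("cover layer must be 2-D")
    if cov.shape[0] < 2 or cov.shape[1] < 2:
        return np.zeros_like(cov)

    def smooth(a, axis):
        p = np.pad(a, [(1, 1) if ax == axis else (0, 0) for ax in range(2)], mode="edge")
        sl = [slice(None)] * 2
        out = np.zeros_like(a)
        for off, w in ((0, 0.25), (1, 0.5), (2, 0.25)):
            sl[axis] = slice(off, off + a.shape[axis])
            out += w * p[tuple(sl)]
        return out

    gx = np.gradient(smooth(cov, axis=0), axis=1)  # d/dcol of row-smoothed
    gy = np.gradient(smooth(cov, axis=1), axis=0)  # d/drow of col-smoothed
    return np.hypot(gx, gy)


# ---------------------------------------------------------------------------
# Core grid container


@dataclass
class LandscapeGrid:
    """Co-registered raster stack for the study landscape.

    ``origin`` is the lower-left (south-west) corner; ``cover_type`` holds
    integer classes 1-15; ``lichen`` (g/m^2) is baseline minus grazing
    depletion, floored at zero.
    """

    origin: tuple[float, float]
    cell_size: float
    cover_type: np.ndarray          # int, classes 1..15
    lichen_baseline: np.ndarray     # g/m^2, class-derived
    cover: np.ndarray               # % canopy, 0..100
    altitude: np.ndarray            # m
    edge: np.ndarray = field(default=None)  # %/cell, derived if None
    _depletion: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.cover_type = np.asarray(self.cover_type, dtype=np.int32)
        shape = self.cover_type.shape
        for name in ("lichen_baseline", "cover", "altitude"):
            layer = np.asarray(getattr(self, name), dtype=float)
            if layer.shape != shape:
                raise ValueError(f"layer {name} shape {layer.shape} != {shape}")
            setattr(self, name, layer)
        if not np.all((self.cover_type >= 1) & (self.cover_type <= 15)):
            raise ValueError("cover_type values must be in 1..15")
        if np.any(self.lichen_baseline < 0) or np.any((self.cover < 0) | (self.cover > 100)):
            raise ValueError("lichen must be >= 0 and cover in [0, 100]")
        if self.edge is None:
            self.edge = derive_edge(self.cover)
        if self._depletion is None:
            self._depletion = np.zeros(shape)

    # -- geometry ----------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.cover_type.shape[0]

    @property
    def ncols(self) -> int:
        return self.cover_type.shape[1]

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    def point_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing a point (half-open footprints)."""
        col = int(math.floor((x - self.origin[0]) / self.cell_size))
        row_s = int(math.floor((y - self.origin[1]) / self.cell_size))
        row = self.nrows - 1 - row_s
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise IndexError(f"point ({x}, {y}) outside grid")
        return row, col

    def contains(self, x: float, y: float) -> bool:
        return (
            self.origin[0] <= x < self.origin[0] + self.ncols * self.cell_size
            and self.origin[1] <= y < self.origin[1] + self.nrows * self.cell_size
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] + (self.nrows - row - 0.5) * self.cell_size
        return x, y

    # -- lichen bookkeeping ------------------------------------------------
    @property
    def lichen(self) -> np.ndarray:
        return np.maximum(self.lichen_baseline - self._depletion, 0.0)

    def lichen_at(self, row: int, col: int) -> float:
        return max(self.lichen_baseline[row, col] - self._depletion[row, col], 0.0)

    def deplete_mass(self, row: int, col: int, grams: float) -> float:
        """Remove up to ``grams`` of lichen mass from a cell; returns grams taken."""
        avail = self.lichen_at(row, col) * self.cell_area
        taken = min(max(grams, 0.0), avail)
        self._depletion[row, col] += taken / self.cell_area
        return taken

    def reset_lichen(self) -> None:
        self._depletion[:] = 0.0

    def total_lichen_mass(self) -> float:
        return float(self.lichen.sum() * self.cell_area)

    def copy(self) -> "LandscapeGrid":
        return LandscapeGrid(
            origin=self.origin,
            cell_size=self.cell_size,
            cover_type=self.cover_type.copy(),
            lichen_baseline=self.lichen_baseline.copy(),
            cover=self.cover.copy(),
            altitude=self.altitude.copy(),
            edge=self.edge.copy(),
            _depletion=self._depletion.copy(),
        )


# ---------------------------------------------------------------------------
# Anthropogenic features


@dataclass
class FeatureLayers:
    """Road/cut/burn masks for one year, aligned with a LandscapeGrid.

    ``cut_age`` is -1 where never cut; a cut is "recent" while its age is at
    most ``recent_max_age`` years and "regenerating" from then until
    ``regen_max_age``.
    """

    year: int
    road: np.ndarray
    cut_age: np.ndarray
    burned: np.ndarray
    recent_max_age: int = 5
    regen_max_age: int = 20

    def __post_init__(self):
        self.road = np.asarray(self.road, dtype=bool)
        self.cut_age = np.asarray(self.cut_age, dtype=np.int32)
        self.burned = np.asarray(self.burned, dtype=bool)
        if not (self.road.shape == self.cut_age.shape == self.burned.shape):
            raise ValueError("feature layers must share one shape")
        self._dt_cache: dict[str, tuple] = {}

    @classmethod
    def empty(cls, shape, year: int = 0) -> "FeatureLayers":
        return cls(year, np.zeros(shape, bool), np.full(shape, -1, np.int32),
                   np.zeros(shape, bool))

    def mask(self, kind: str, year: int | None = None) -> np.ndarray:
        if year is not None and year != self.year:
            raise KeyError(f"features hold year {self.year}, not {year}")
        if kind == "road":
            return self.road
        if kind == "recent_cut":
            return (self.cut_age >= 0) & (self.cut_age <= self.recent_max_age)
        if kind == "regenerating_cut":
            return (self.cut_age > self.recent_max_age) & (self.cut_age <= self.regen_max_age)
        if kind == "burned":
            return self.burned
        raise KeyError(f"unknown feature kind {kind!r}")

    def _distance_transform(self, kind: str, cell_size: float):
        key = (kind, cell_size)
        if key not in self._dt_cache:
            m = self.mask(kind)
            if not m.any():
                self._dt_cache[key] = None
            else:
                dist, (ir, ic) = ndimage.distance_transform_edt(
                    ~m, sampling=cell_size, return_indices=True
                )
                self._dt_cache[key] = (dist, ir, ic)
        return self._dt_cache[key]


def advance_year(features: FeatureLayers, new_cuts: np.ndarray | None = None) -> FeatureLayers:
    """Age all cuts by one year and register this year's fresh cuts (age 0)."""
    age = features.cut_age.copy()
    age[age >= 0] += 1
    if new_cuts is not None:
        new_cuts = np.asarray(new_cuts, dtype=bool)
        if new_cuts.shape != age.shape:
            raise ValueError("new_cuts not aligned with grid")
        age[new_cuts] = 0
    return FeatureLayers(
        year=features.year + 1,
        road=features.road.copy(),
        cut_age=age,
        burned=features.burned.copy(),
        recent_max_age=features.recent_max_age,
        regen_max_age=features.regen_max_age,
    )


def distance_angle_to_feature(point, heading, features: FeatureLayers, kind,
                              year=None, grid: LandscapeGrid = None):
    """Distance and direction cosine to the nearest feature cell of a kind.

    Returns ``(D, cos_theta)``: D is the Euclidean distance (m) from the point
    to the nearest feature cell centre (via a precomputed exact distance
    transform), theta the angle between the step heading and the direction to
    that cell.  With no feature of the kind present, D is +inf and the cosine
    contribution is defined as 0 (the disturbance kernel vanishes there).
    """
    if kind not in FEATURE_KINDS:
        raise KeyError(f"unknown feature kind {kind!r}")
    if grid is None:
        raise ValueError("grid geometry required")
    dt = features._distance_transform(kind, grid.cell_size)
    if dt is None:
        return math.inf, 0.0
    _, ir, ic = dt
    row, col = grid.point_to_cell(*point)
    nr, nc = int(ir[row, col]), int(ic[row, col])
    tx, ty = grid.cell_center(nr, nc)
    dx, dy = tx - point[0], ty - point[1]
    d = math.hypot(dx, dy)
    if d == 0.0:
        return 0.0, 1.0  # on the feature: treat as dead ahead
    theta = math.atan2(dy, dx) - heading
    return d, math.cos(theta)


# ---------------------------------------------------------------------------
# Loading and synthesis


def load_landscape(cover_path, dem_path, biomass_table=None, cover_table=None) -> LandscapeGrid:
    """Build a LandscapeGrid from a landcover-class raster and a DEM.

    Both rasters must be co-registered ESRI ASCII grids.  Lichen and canopy
    cover are initialized from the per-class lookup tables; the edge layer is
    derived from cover.
    """
    bio_default, cov_default = class_tables()
    biomass_table = biomass_table or bio_default
    cover_table = cover_table or cov_default
    classes, origin, cell = read_ascii_grid(cover_path)
    dem, dem_origin, dem_cell = read_ascii_grid(dem_path)
    if dem.shape != classes.shape or dem_origin != origin or dem_cell != cell:
        raise ValueError("cover and DEM rasters are not co-registered")
    cls = np.rint(classes).astype(np.int32)
    present = np.unique(cls)
    unknown = [int(c) for c in present if int(c) not in biomass_table]
    if unknown:
        raise ValueError(f"unknown class codes {unknown} (no biomass entry)")
    lichen = np.vectorize(biomass_table.__getitem__)(cls).astype(float)
    cover = np.vectorize(cover_table.__getitem__)(cls).astype(float)
    return LandscapeGrid(origin=origin, cell_size=cell, cover_type=cls,
                         lichen_baseline=lichen, cover=cover, altitude=dem)


def save_landscape(grid: LandscapeGrid, cover_path, dem_path) -> None:
    write_ascii_grid(cover_path, grid.cover_type, grid.origin, grid.cell_size)
    write_ascii_grid(dem_path, grid.altitude, grid.origin, grid.cell_size)


def synth_landscape(seed, nrows, ncols, class_mixture=None, road_density=2.0,
                    patchiness=200.0, cut_patches=0, cell_size=25.0,
                    origin=(0.0, 0.0)) -> tuple[LandscapeGrid, FeatureLayers]:
    """Seeded synthetic landscape with patchy classes, roads and a smooth DEM.

    ``class_mixture`` maps landcover class to its target areal fraction
    (must sum to 1); patches are grown as Voronoi cells of clustered seed
    points whose density is set by ``patchiness`` (mean patch size, cells).
    ``road_density`` is the expected number of linear road features;
    ``cut_patches`` optionally stamps square cutblocks of random age.
    Identical seeds give bit-identical outputs.
    """
    rng = np.random.default_rng(seed)
    if class_mixture is None:
        class_mixture = {11: 0.35, 10: 0.2, 9: 0.15, 5: 0.1, 12: 0.1, 3: 0.05, 1: 0.05}
    labels = np.array(sorted(class_mixture), dtype=np.int32)
    weights = np.array([class_mixture[k] for k in labels], dtype=float)
    if np.any(weights < 0):
        raise ValueError("class mixture weights must be non-negative")
    if not math.isclose(weights.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("class mixture must sum to 1")

    n_cells = nrows * ncols
    n_seeds = max(1, int(round(n_cells / max(patchiness, 1.0))))
    seed_rows = rng.integers(0, nrows, n_seeds)
    seed_cols = rng.integers(0, ncols, n_seeds)
    seed_cls = rng.choice(labels, size=n_seeds, p=weights)
    occupied = np.zeros((nrows, ncols), bool)
    occupied[seed_rows, seed_cols] = True
    _, (ir, ic) = ndimage.distance_transform_edt(~occupied, return_indices=True)
    # nearest-seed label; where several seeds share a cell the last write wins
    label_img = np.zeros((nrows, ncols), np.int32)
    label_img[seed_rows, seed_cols] = seed_cls
    cls = label_img[ir, ic]

    features = FeatureLayers.empty((nrows, ncols))
    n_roads = int(round(road_density))
    for _ in range(n_roads):
        if rng.random() < 0.5:
            r0, r1 = rng.integers(0, nrows, 2)
            c0, c1 = 0, ncols - 1
        else:
            c0, c1 = rng.integers(0, ncols, 2)
            r0, r1 = 0, nrows - 1
        n = max(abs(int(r1) - int(r0)), abs(int(c1) - int(c0))) + 1
        rr = np.rint(np.linspace(r0, r1, n)).astype(int)
        cc = np.rint(np.linspace(c0, c1, n)).astype(int)
        features.road[rr, cc] = True
        cls[rr, cc] = 15

    for _ in range(cut_patches):
        size = int(rng.integers(4, 12))
        r = int(rng.integers(0, max(nrows - size, 1)))
        c = int(rng.integers(0, max(ncols - size, 1)))
        age = int(rng.integers(0, features.regen_max_age + 1))
        features.cut_age[r:r + size, c:c + size] = age
        cls[r:r + size, c:c + size] = 14 if age <= features.recent_max_age else 13

    dem = rng.normal(size=(nrows, ncols))
    dem = ndimage.gaussian_filter(dem, sigma=max(min(nrows, ncols) / 10.0, 1.0))
    rng_span = dem.max() - dem.min()
    dem = 300.0 + 400.0 * (dem - dem.min()) / (rng_span if rng_span > 0 else 1.0)

    biomass, covtab = class_tables()
    lichen = np.vectorize(biomass.__getitem__)(cls).astype(float)
    cover = np.vectorize(covtab.__getitem__)(cls).astype(float)
    grid = LandscapeGrid(origin=origin, cell_size=cell_size, cover_type=cls,
                         lichen_baseline=lichen, cover=cover, altitude=dem)
    return grid, features


# ---------------------------------------------------------------------------
# Encroachment scenario


@dataclass
class ScenarioSpec:
    """Hardwood-encroachment scenario: convert the centred square covering
    ``converted_fraction`` of each quadrat to ``target_class``, sparing
    protected classes."""

    quadrat_area_km2: float = 225.0
    converted_fraction: float = 0.70
    target_class: int = 12
    protected_classes: tuple[int, ...] = (1, 3)

    def __post_init__(self):
        if not (0.0 < self.converted_fraction <= 1.0):
            raise ValueError("converted_fraction must be in (0, 1]")


def apply_encroachment(grid: LandscapeGrid, spec: ScenarioSpec | None = None) -> LandscapeGrid:
    """Tile the extent into quadrats and convert each quadrat's centre square.

    Every cell inside the centred square of area ``converted_fraction`` times
    the quadrat area whose class is not protected becomes the target class;
    lichen and cover are re-derived from the class lookup for converted cells.
    Returns a new grid; the input is untouched.
    """
    spec = spec or ScenarioSpec()
    out = grid.copy()
    side_m = math.sqrt(spec.quadrat_area_km2) * 1000.0
    q_cells = max(1, int(round(side_m / grid.cell_size)))
    sq_cells = int(round(q_cells * math.sqrt(spec.converted_fraction)))
    biomass, covtab = class_tables()
    nrows, ncols = grid.nrows, grid.ncols
    convert = np.zeros((nrows, ncols), bool)
    for r0 in range(0, nrows, q_cells):
        for c0 in range(0, ncols, q_cells):
            qr = min(q_cells, nrows - r0)
            qc = min(q_cells, ncols - c0)
            sr = min(sq_cells, qr)
            sc = min(sq_cells, qc)
            rs = r0 + (qr - sr) // 2
            cs = c0 + (qc - sc) // 2
            convert[rs:rs + sr, cs:cs + sc] = True
    protected = np.isin(out.cover_type, spec.protected_classes)
    convert &= ~protected
    out.cover_type[convert] = spec.target_class
    out.lichen_baseline[convert] = biomass[spec.target_class]
    out.cover[convert] = covtab[spec.target_class]
    out._depletion[convert] = 0.0
    out.edge = derive_edge(out.cover)
    return out
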