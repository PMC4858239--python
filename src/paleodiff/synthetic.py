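"""Parametric toy terrains for exercising the full pipeline offline.

The generator stands in for real elevation and hydrology rasters: islands
with coastal plains, interior ridges, 1-cell-wide river polylines and sea
gaps, built from template geometry plus smoothed seeded noise.  Terrains
are deterministic under a fixed seed and are shaped so the piecewise
scoring exercises every altitude band and every relief class.

Templates
---------
``uniform_plain``
    All-land constant-altitude plain (plus optional gentle noise) with
    straight rivers; every cell classifies flat.
``single_island``
    One radially tapered island in sea, with a river from the interior.
``two_islands``
    Two rectangular islands separated by a sea gap of a requested width;
    used to exercise sea-link connectivity and isolation.
``two_valley_island``
    The workhorse fixture: an island split by a high central ridge (with
    a low pass, a high shoulder and an above-cut-off peak) into two
    river-fed valleys, seeded with one population group per valley.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .engine import Seed
from .terrain_io import ElevationGrid

__all__ = ["TerrainSpec", "Fixture", "make_terrain", "make_fixture_suite"]

SEA_ALTITUDE = -50.0


@dataclass
class TerrainSpec:
    """Parameters of a synthetic terrain.

    Not every field applies to every template; unused fields are ignored.
    """

    template: str = "two_valley_island"
    shape: tuple[int, int] = (50, 50)
    cell_size_km: float = 1.0
    base_altitude_m: float = 120.0
    noise_m: float = 30.0
    ridge_height_m: float = 1500.0
    n_rivers: int = 1
    meander: int = 1
    gap_km: float = 10.0
    margin: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 1:
            raise ValueError("degenerate shape")
        templates = ("uniform_plain", "single_island", "two_islands", "two_valley_island")
        if self.template not in templates:
            raise ValueError(f"unknown template {self.template!r}")


@dataclass
class Fixture:
    """A named terrain with optional entry-point seeds."""

    name: str
    elev: ElevationGrid
    water: np.ndarray
    seeds: list[Seed] = field(default_factory=list)


def _smooth_noise(shape: tuple[int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    if amplitude <= 0:
        return np.zeros(shape)
    raw = rng.normal(size=shape)
    sm = ndimage.gaussian_filter(raw, sigma=1.5)
    peak = np.abs(sm).max()
    return sm / peak * amplitude if peak > 0 else sm


def _river_column(
    water: np.ndarray,
    col: int,
    row_lo: int,
    row_hi: int,
    meander: int,
    rng: np.random.Generator,
) -> None:
    """Carve a 1-cell-wide meandering north-south river polyline.

    Rows strictly inside [row_lo, row_hi); lateral drift bounded by
    ``meander`` cells so the line stays connected (8-neighbour) and does
    not sever the landmass.
    """
    c = col
    for r in range(row_lo, row_hi):
        water[r, c] = True
        if meander > 0:
            c = int(np.clip(c + rng.integers(-1, 2), col - meander, col + meander))


def make_terrain(spec: TerrainSpec) -> tuple[ElevationGrid, np.ndarray]:
    """Build ``(ElevationGrid, water mask)`` from a spec; deterministic
    under ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    rows, cols = spec.shape
    A = np.full(spec.shape, SEA_ALTITUDE)
    water = np.zeros(spec.shape, dtype=bool)
    m = spec.margin

    if spec.template == "uniform_plain":
        A[:] = spec.base_altitude_m + _smooth_noise(spec.shape, spec.noise_m, rng)
        if spec.n_rivers > 0 and rows >= 3:
            for k in range(spec.n_rivers):
                col = (k + 1) * cols // (spec.n_rivers + 1)
                _river_column(water, col, 1, rows - 1, spec.meander, rng)

    elif spec.template == "single_island":
        ii, jj = np.indices(spec.shape, dtype=float)
        r2 = ((ii - (rows - 1) / 2) / (rows / 2 - m)) ** 2 + (
            (jj - (cols - 1) / 2) / (cols / 2 - m)
        ) ** 2
        A = spec.ridge_height_m * (1.0 - r2) - 20.0
        A += _smooth_noise(spec.shape, spec.noise_m, rng)
        A[r2 >= 1.0] = SEA_ALTITUDE
        if spec.n_rivers > 0:
            _river_column(water, cols // 2 - 2, rows // 3, 2 * rows // 3, spec.meander, rng)
        water &= A > 0

    elif spec.template == "two_islands":
        n_gap = max(1, round(spec.gap_km / spec.cell_size_km))
        half = (cols - n_gap) // 2
        if half < 3:
            raise ValueError("grid too narrow for the requested gap")
        base = spec.base_altitude_m + _smooth_noise(spec.shape, spec.noise_m, rng)
        left = (slice(m, rows - m), slice(1, half))
        right = (slice(m, rows - m), slice(half + n_gap, cols - 1))
        A[left] = base[left]
        A[right] = base[right]
        for sl in (left, right):
            c0 = (sl[1].start + sl[1].stop) // 2
            _river_column(water, c0, m + 1, rows - m - 1, 0, rng)

    else:  # two_valley_island
        if rows < 30 or cols < 30:
            raise ValueError("two_valley_island needs at least a 30x30 grid")
        land = (slice(m, rows - m), slice(m, cols - m))
        A[land] = spec.base_altitude_m + _smooth_noise(spec.shape, spec.noise_m, rng)[land]
        c = cols // 2
        r_lo, r_hi = m + 2, rows - m - 2
        # central ridge with a low pass so the valleys stay connected
        A[r_lo:r_hi, c] = spec.ridge_height_m
        pass_rows = slice(rows // 2 - 3, rows // 2 + 3)
        A[pass_rows, c] = 350.0
        # high shoulder and above-cut-off peak (exercises every altitude band)
        A[r_lo + 4, c] = 3000.0
        A[r_lo + 2, c] = 4500.0
        # crag: a low cell walled in by ridge bulges -> uninhabitable relief
        A[r_lo + 9, c - 1] = 60.0
        A[r_lo + 8, c - 1] = A[r_lo + 10, c - 1] = spec.ridge_height_m
        # one river per valley, strictly interior so the landmass stays whole
        c_left, c_right = m + cols // 6, cols - m - cols // 6
        _river_column(water, c_left, m + 2, rows - m - 2, spec.meander, rng)
        _river_column(water, c_right, m + 2, rows - m - 2, spec.meander, rng)
        # mountain stream feeding the shoulder (high-plane rating case)
        A[r_lo + 4, c - 1] = 800.0
        water[r_lo + 4, c - 2] = True

    water &= A > 0
    elev = ElevationGrid(altitude=A, cell_size_km=spec.cell_size_km)
    if not (elev.altitude > 0).any():
        raise ValueError("generated terrain has no land")
    return elev, water


def default_seeds(spec: TerrainSpec) -> list[Seed]:
    """Two entry groups for the two-valley island (west and east valley),
    with populations in the 10^5 : 10^3 ratio of a dominant and a minor
    entry wave."""
    rows, cols = spec.shape
    m = spec.margin
    r = rows // 2
    return [
        Seed("west", r, m + cols // 6 + 2, 1e5),
        Seed("east", r, cols - m - cols // 6 - 2, 1e3),
    ]


def make_fixture_suite(rng_seed: int = 0) -> dict[str, Fixture]:
    """The canonical cross-module test fixtures.

    * ``two_cell``  — 1x2 land strip with unequal altitudes (flux oracle)
    * ``strip``     — uniform 1x21 land strip (contact-time oracle)
    * ``mirror_island`` — island mirror-symmetric about its central
      column, two symmetric rivers (symmetry checks)
    * ``two_valley_island`` — ridge-split island with two seeded groups
      (end-to-end runs)
    """
    fixtures: dict[str, Fixture] = {}

    elev = ElevationGrid(np.array([[100.0, 200.0]]))
    fixtures["two_cell"] = Fixture("two_cell", elev, np.zeros((1, 2), bool))

    elev = ElevationGrid(np.full((1, 21), 100.0))
    fixtures["strip"] = Fixture(
        "strip",
        elev,
        np.zeros((1, 21), bool),
        seeds=[Seed("a", 0, 3, 5e6), Seed("b", 0, 17, 5e6)],
    )

    rows, cols = 31, 31
    rng = np.random.default_rng(rng_seed)
    A = np.full((rows, cols), SEA_ALTITUDE)
    land = (slice(3, rows - 3), slice(3, cols - 3))
    A[land] = 120.0
    half = _smooth_noise((rows, cols // 2), 25.0, rng)
    noise = np.zeros((rows, cols))
    noise[:, : cols // 2] = half
    noise[:, cols // 2 + 1 :] = half[:, ::-1]
    A += np.where(A > 0, noise, 0.0)
    water = np.zeros((rows, cols), bool)
    water[5 : rows - 5, 8] = True
    water[5 : rows - 5, cols - 9] = True
    fixtures["mirror_island"] = Fixture(
        "mirror_island",
        ElevationGrid(A),
        water,
        seeds=[Seed("center", rows // 2, cols // 2, 5e6)],
    )

    spec = TerrainSpec(template="two_valley_island", rng_seed=rng_seed)
    elev, water = make_terrain(spec)
    fixtures["two_valley_island"] = Fixture(
        "two_valley_island", elev, water, seeds=default_seeds(spec)
    )
    return fixtures
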