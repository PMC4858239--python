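"""Piecewise desirability scoring and per-cell site rating.

Every cell of the landscape is scored on three normalized desirabilities in
[0, 1]:

* ``D_alt`` — altitude desirability, highest at sea level, dipping to 0.3
  at 300 m, recovering to 0.5 at 2100 m and falling to 0 at the 4100 m
  habitability cut-off;
* ``D_surf`` — surface (flatness) desirability, a function of the local
  relief ``d_surf`` (deviation of a cell from the mean altitude of its
  von Neumann 5-cell stencil, in km, altitude-weighted above 300 m) with
  three bands: flat, tolerable, uninhabitable;
* ``D_riv`` — water desirability, 1 within direct carrying distance of a
  freshwater source and decaying (by default with an inverse-square law)
  out to a maximum practical reach.

These combine into the population-independent site rating ``R_in`` through
a case table keyed on land class and water access, and into the local
carrying capacity ``P_best`` (persons), the arithmetic mean of a
location-based and a water-based optimum population scaled by the global
ceiling ``P_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .terrain_io import (
    FRESHWATER,
    LAND,
    SEA,
    ElevationGrid,
    classify_cells,
    distance_to_water,
)

__all__ = [
    "FLAT",
    "TOLERABLE",
    "UNINHABITABLE",
    "HabitabilityParams",
    "HabitabilityFields",
    "altitude_desirability",
    "local_relief",
    "surface_desirability",
    "water_desirability",
    "location_desirability",
    "site_rating",
    "optimum_population",
    "compute_habitability",
]

# land-class labels (relief bands)
FLAT = 0
TOLERABLE = 1
UNINHABITABLE = 2

#: altitude (m) above which land counts as "higher planes" in the rating
#: case table — the start of the third altitude-desirability band
HIGHLAND_ALTITUDE_M = 2100.0

#: altitude cut-off (m) beyond which nothing is habitable
ALTITUDE_CUTOFF_M = 4100.0


@dataclass
class HabitabilityParams:
    """Tunables of the desirability model.

    Attributes
    ----------
    L_flat : float
        Relief threshold below which land is flat (dimensionless relief,
        i.e. km of deviation per km-scale stencil).
    L_tol : float
        Relief threshold beyond which land is uninhabitable.
    W_flat : float
        Weight of ``D_surf`` in the diagnostic linear combination
        ``D_loc``.
    r_full : float
        Distance (km) up to which water can be directly accessed
        (carried); ``D_riv`` is 1 inside it.
    r_max : float
        Maximum practical reach of a water source (km); ``D_riv`` is 0
        beyond it.
    water_mode : str
        One of ``inverse_square`` (default), ``linear``,
        ``extended_range`` (inverse square with doubled ``r_max``), or
        ``wide_power_law`` (fixed 10/50-cell radii with a weak
        ``S**-0.0435`` power-law middle piece).
    water_aggregate : str
        ``nearest`` (default; evaluate at the nearest source, preserving
        the [0, 1] bound) or ``sum_clipped`` (sum over all sources,
        clipped at 1).
    rescale_rating : bool
        Affinely map raw ratings per land class onto the canonical ranges
        flat → [0.5, 1], tolerable → [0.25, 1].
    """

    L_flat: float = 0.2
    L_tol: float = 0.5
    W_flat: float = 0.5
    r_full: float = 2.0
    r_max: float = 10.0
    water_mode: str = "inverse_square"
    water_aggregate: str = "nearest"
    rescale_rating: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.L_flat < self.L_tol <= 1:
            raise ValueError("need 0 < L_flat < L_tol <= 1")
        if not 0 < self.r_full < self.r_max:
            raise ValueError("need 0 < r_full < r_max")
        if self.water_mode not in (
            "inverse_square",
            "linear",
            "extended_range",
            "wide_power_law",
        ):
            raise ValueError(f"unknown water_mode {self.water_mode!r}")
        if self.water_aggregate not in ("nearest", "sum_clipped"):
            raise ValueError(f"unknown water_aggregate {self.water_aggregate!r}")


@dataclass
class HabitabilityFields:
    """All pre-computed per-cell fields of a scored landscape."""

    classification: np.ndarray  # LAND / SEA / FRESHWATER
    water_distance_km: np.ndarray  # S(i,j)
    D_alt: np.ndarray
    d_surf: np.ndarray
    D_surf: np.ndarray
    D_loc: np.ndarray
    D_riv: np.ndarray
    land_class: np.ndarray  # FLAT / TOLERABLE / UNINHABITABLE
    R_in: np.ndarray
    P_best: np.ndarray  # persons
    cell_size_km: float = 1.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.R_in.shape

    @property
    def habitable(self) -> np.ndarray:
        """Boolean mask of cells that can hold population."""
        return (self.classification == LAND) & (self.land_class != UNINHABITABLE)


def altitude_desirability(A: np.ndarray | float) -> np.ndarray | float:
    """Desirability as a function of altitude A (m).

    Piecewise, continuous at 300 m, 2100 m and 4100 m:

    * A < 0 (sea): 0
    * 0 <= A <= 300: (1000 - (7/3) A) / 1000, falling 1 -> 0.3
    * 300 < A <= 2100: ((A - 300)/9 + 300) / 1000, rising 0.3 -> 0.5
    * 2100 < A <= 4100: (4100 - A) / 4000, falling 0.5 -> 0
    * A > 4100: 0
    """
    A = np.asarray(A, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("altitude must be finite")
    out = np.select(
        [
            A < 0,
            A <= 300,
            A <= 2100,
            A <= ALTITUDE_CUTOFF_M,
        ],
        [
            0.0,
            (1000.0 - (7.0 / 3.0) * A) / 1000.0,
            ((A - 300.0) / 9.0 + 300.0) / 1000.0,
            (ALTITUDE_CUTOFF_M - A) / 4000.0,
        ],
        default=0.0,
    )
    return out if out.ndim else float(out)


def local_relief(elev: ElevationGrid, cls: np.ndarray | None = None) -> np.ndarray:
    """Dimensionless local relief ``d_surf`` from the 5-cell stencil mean.

    ``A_mean(i,j)`` is the mean altitude over the von Neumann stencil
    {(i,j), (i±1,j), (i,j±1)}, with sea and nodata neighbours excluded
    from the mean; border cells use the stencil members that exist.
    The relief is |A_mean - A| / 1000 for A <= 300 m, additionally scaled
    by 300/A for 300 < A <= 4100 m, and 0 above the cut-off.
    """
    A = elev.altitude
    if cls is None:
        cls = classify_cells(elev, np.zeros(elev.shape, dtype=bool))
    valid = (cls != SEA) & ~elev.nodata

    Av = np.where(valid, A, 0.0)
    w = valid.astype(float)
    total = Av.copy()
    count = w.copy()
    for shift, axis in ((1, 0), (-1, 0), (1, 1), (-1, 1)):
        total += _shift(Av, shift, axis)
        count += _shift(w, shift, axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        A_mean = np.where(count > 0, total / count, A)

    dev = np.abs(A_mean - A) / 1000.0
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = dev * (300.0 / np.where(A > 300, A, 1.0))
    d = np.select(
        [A <= 300, A <= ALTITUDE_CUTOFF_M],
        [dev, scaled],
        default=0.0,
    )
    d[~valid] = 0.0
    return d


def _shift(a: np.ndarray, shift: int, axis: int) -> np.ndarray:
    """Shift with zero padding (no wrap-around)."""
    out = np.zeros_like(a)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if shift > 0:
        src[axis] = slice(0, -shift)
        dst[axis] = slice(shift, None)
    else:
        src[axis] = slice(-shift, None)
        dst[axis] = slice(0, shift)
    out[tuple(dst)] = a[tuple(src)]
    return out


def surface_desirability(
    d_surf: np.ndarray | float, params: HabitabilityParams | None = None
) -> tuple[np.ndarray | float, np.ndarray | int]:
    """Surface desirability and land class from the local relief.

    * d <= L_flat (flat): 1 - d / (2 L_flat), falling 1 -> 0.5
    * L_flat < d <= L_tol (tolerable): L_flat / (2 d), continuing 0.5 ->
      L_flat / (2 L_tol)
    * d > L_tol: 0, uninhabitable

    Returns ``(D_surf, land_class)``.
    """
    params = params or HabitabilityParams()
    d = np.asarray(d_surf, dtype=float)
    if np.any(d < 0):
        raise ValueError("relief must be non-negative")
    with np.errstate(divide="ignore"):
        D = np.select(
            [d <= params.L_flat, d <= params.L_tol],
            [1.0 - d / (2.0 * params.L_flat), params.L_flat / (2.0 * np.maximum(d, 1e-300))],
            default=0.0,
        )
    klass = np.select(
        [d <= params.L_flat, d <= params.L_tol],
        [FLAT, TOLERABLE],
        default=UNINHABITABLE,
    ).astype(np.int8)
    if D.ndim == 0:
        return float(D), int(klass)
    return D, klass


def water_desirability(
    S: np.ndarray | float,
    params: HabitabilityParams | None = None,
    cell_size_km: float = 1.0,
) -> np.ndarray | float:
    """Water desirability from the distance S (km) to the nearest source.

    All modes are 1 up to the direct-access radius and 0 beyond the
    maximum reach; they differ in the middle piece (see
    :class:`HabitabilityParams`).
    """
    params = params or HabitabilityParams()
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("distance must be non-negative")

    mode = params.water_mode
    r_full, r_max = params.r_full, params.r_max
    if mode == "extended_range":
        r_max = 2.0 * r_max
    if mode == "wide_power_law":
        # fixed radii of 10 and 50 cells, weak power law in between
        r_full, r_max = 10.0 * cell_size_km, 50.0 * cell_size_km
        mid = np.power(np.maximum(S, r_full), -0.0435)
    elif mode == "linear":
        mid = (r_max - S) / (r_max - r_full)
    else:
        mid = (r_full / np.maximum(S, r_full)) ** 2
    out = np.select([S <= r_full, S <= r_max], [1.0, mid], default=0.0)
    return out if out.ndim else float(out)


def location_desirability(
    D_alt: np.ndarray | float,
    D_surf: np.ndarray | float,
    params: HabitabilityParams | None = None,
) -> np.ndarray | float:
    """Diagnostic linear combination D_loc = W_flat*D_surf + (1-W_flat)*D_alt.

    Exported for inspection; the canonical rating uses the case table in
    :func:`site_rating` instead.
    """
    params = params or HabitabilityParams()
    return params.W_flat * np.asarray(D_surf, float) + (1.0 - params.W_flat) * np.asarray(
        D_alt, float
    )


def site_rating(
    D_alt: np.ndarray,
    D_surf: np.ndarray,
    D_riv: np.ndarray,
    land_class: np.ndarray,
    params: HabitabilityParams | None = None,
    altitude: np.ndarray | None = None,
    habitable: np.ndarray | None = None,
) -> np.ndarray:
    """Population-independent site rating R_in in [0, 1].

    Raw rating by case, evaluated on habitable cells only:

    * poor water access (D_riv <= 0.5): D_alt**2 * D_surf
    * higher planes (altitude > 2100 m): (D_alt * D_riv)**4
    * flat land with good water: D_surf**2 * D_alt * D_riv
    * tolerable land with good water: (D_surf * D_alt * D_riv)**2

    With ``rescale_rating`` the raw ratings are affinely mapped per land
    class onto flat → [0.5, 1] and tolerable → [0.25, 1] (using the class
    min/max over habitable cells of this grid); a class whose raw ratings
    are all equal maps to the upper bound.  Uninhabitable and non-land
    cells rate 0.
    """
    params = params or HabitabilityParams()
    D_alt = np.asarray(D_alt, float)
    D_surf = np.asarray(D_surf, float)
    D_riv = np.asarray(D_riv, float)
    if habitable is None:
        habitable = land_class != UNINHABITABLE
    if altitude is None:
        altitude = np.zeros_like(D_alt)

    poor_water = D_riv <= 0.5
    highland = altitude > HIGHLAND_ALTITUDE_M
    raw = np.select(
        [
            ~habitable,
            poor_water,
            highland,
            land_class == FLAT,
        ],
        [
            0.0,
            D_alt**2 * D_surf,
            (D_alt * D_riv) ** 4,
            D_surf**2 * D_alt * D_riv,
        ],
        default=(D_surf * D_alt * D_riv) ** 2,
    )
    raw = np.clip(raw, 0.0, 1.0)
    if not params.rescale_rating:
        return np.where(habitable, raw, 0.0)

    out = np.zeros_like(raw)
    for klass, lo in ((FLAT, 0.5), (TOLERABLE, 0.25)):
        mask = habitable & (land_class == klass)
        if not mask.any():
            continue
        vals = raw[mask]
        vmin, vmax = float(vals.min()), float(vals.max())
        if vmax > vmin:
            out[mask] = lo + (vals - vmin) * (1.0 - lo) / (vmax - vmin)
        else:
            out[mask] = 1.0
    return out


def optimum_population(
    D_alt: np.ndarray | float,
    D_surf: np.ndarray | float,
    D_riv: np.ndarray | float,
    P_max: float = 1e7,
    habitable: np.ndarray | None = None,
) -> np.ndarray | float:
    """Carrying capacity P_best (persons) of each cell.

    The arithmetic mean of a location-based optimum (0.5 D_surf +
    0.5 D_alt) and a water-based optimum (D_riv), scaled by the global
    ceiling P_max; zero on non-habitable cells.
    """
    if not P_max > 0:
        raise ValueError("P_max must be positive")
    loc = 0.5 * np.asarray(D_surf, float) + 0.5 * np.asarray(D_alt, float)
    best = P_max * 0.5 * (loc + np.asarray(D_riv, float))
    if habitable is not None:
        best = np.where(habitable, best, 0.0)
    return best if np.ndim(best) else float(best)


def _water_desirability_field(
    cls: np.ndarray,
    S: np.ndarray,
    params: HabitabilityParams,
    cell_size_km: float,
) -> np.ndarray:
    if params.water_aggregate == "nearest" or not np.isfinite(S).any():
        return np.asarray(water_desirability(S, params, cell_size_km))
    # sum over every source, clipped at 1 (can be slow on large grids)
    rows, cols = np.nonzero(cls == FRESHWATER)
    ii, jj = np.indices(cls.shape)
    total = np.zeros(cls.shape)
    for r, c in zip(rows, cols):
        d = np.hypot(ii - r, jj - c) * cell_size_km
        total += np.asarray(water_desirability(d, params, cell_size_km))
    return np.clip(total, 0.0, 1.0)


def compute_habitability(
    elev: ElevationGrid,
    water: np.ndarray,
    params: HabitabilityParams | None = None,
    P_max: float = 1e7,
) -> HabitabilityFields:
    """Score a landscape end to end.

    Classifies cells, computes the water-distance field and all
    desirabilities, the site rating R_in and the carrying capacity
    P_best.  Sea, freshwater, nodata and uninhabitable cells carry
    R_in = P_best = 0.
    """
    params = params or HabitabilityParams()
    cls = classify_cells(elev, water)
    S = distance_to_water(cls, elev.cell_size_km)

    D_alt = np.asarray(altitude_desirability(elev.altitude))
    d_surf = local_relief(elev, cls)
    D_surf, land_class = surface_desirability(d_surf, params)
    D_riv = _water_desirability_field(cls, S, params, elev.cell_size_km)
    D_loc = np.asarray(location_desirability(D_alt, D_surf, params))

    # only plain land below the altitude cut-off can hold population
    habitable = (
        (cls == LAND)
        & (land_class != UNINHABITABLE)
        & (elev.altitude <= ALTITUDE_CUTOFF_M)
    )
    land_class = np.where(habitable, land_class, UNINHABITABLE).astype(np.int8)

    R_in = site_rating(
        D_alt, D_surf, D_riv, land_class, params,
        altitude=elev.altitude, habitable=habitable,
    )
    P_best = np.asarray(
        optimum_population(D_alt, D_surf, D_riv, P_max, habitable=habitable)
    )
    D_alt = np.where(cls == SEA, 0.0, D_alt)
    D_surf = np.asarray(D_surf, float).copy()
    D_surf[cls != LAND] = 0.0

    return HabitabilityFields(
        classification=cls,
        water_distance_km=S,
        D_alt=D_alt,
        d_surf=d_surf,
        D_surf=D_surf,
        D_loc=D_loc,
        D_riv=D_riv,
        land_class=land_class,
        R_in=R_in,
        P_best=P_best,
        cell_size_km=elev.cell_size_km,
    )


def field_summary(fields: HabitabilityFields) -> dict:
    """JSON-ready summary: class counts and min/max per exported field."""
    hab = fields.habitable
    summary: dict = {
        "n_land": int(np.sum(fields.classification == LAND)),
        "n_sea": int(np.sum(fields.classification == SEA)),
        "n_freshwater": int(np.sum(fields.classification == FRESHWATER)),
        "n_flat": int(np.sum(hab & (fields.land_class == FLAT))),
        "n_tolerable": int(np.sum(hab & (fields.land_class == TOLERABLE))),
        "n_habitable": int(hab.sum()),
    }
    for name in ("D_alt", "D_surf", "D_riv", "R_in", "P_best"):
        arr = getattr(fields, name)
        finite = arr[np.isfinite(arr)]
        summary[name] = {
            "min": float(finite.min()) if finite.size else None,
            "max": float(finite.max()) if finite.size else None,
        }
    return summary
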