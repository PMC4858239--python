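"""Deterministic multi-group population-diffusion engine.

Populations are real-valued densities on the habitability grid.  Each
discrete step (nominally one year at a 1 km cell size) proceeds in a fixed
order, with all fluxes computed synchronously from the pre-step state:

1. **Effective ratings.**  The population-independent site rating R_in is
   degraded by crowding: in the canonical mode
   ``R = R_in * max(0, 1 - P / (2 P_best))``, so an empty cell rates R_in
   and a cell at twice its carrying capacity rates 0.
2. **Boundary fluxes.**  Every cell frees a mobile pool
   ``mu * P * (1 - R)`` (the less desirable the cell, the more of its
   population is willing to move, capped by the mobility ``mu``).  The
   pool is directed at habitable neighbours in proportion to their
   ratings; at each boundary the directed mass splits between the two
   sides in the ratio of their ratings (``F_in : F_out = R_nbr : R_self``),
   so flow is always net toward the better-rated side and a cell at
   capacity (R = 0) receives nothing.  Flows carry the group composition
   of their source cell.
3. **Births.**  ``P_g += g * P_g * R`` per group and cell; no births where
   R = 0.
4. **Overcrowding clamp.**  Cell totals are capped at the global ceiling
   P_max (proportionally across groups, with a logged warning).

Landmasses are connected by ordinary cell adjacency plus *sea links*:
minimal-gap coastal pairs between separate land components no farther
apart than a configurable cut-off (25 km by default), with flux damped by
``cell_size / gap`` so a wide crossing is proportionally slower.

With zero birth rate the update conserves total population exactly (up to
floating point); the model has no stochastic terms, so runs are
bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .habitability import HabitabilityFields
from .terrain_io import LAND

__all__ = [
    "SimConfig",
    "Seed",
    "SeaLink",
    "PopulationState",
    "Trajectory",
    "StateCorruptionError",
    "effective_rating",
    "boundary_flux",
    "apply_births",
    "build_sea_links",
    "seed_state",
    "step",
    "run",
]

logger = logging.getLogger(__name__)

_OFFSETS4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFSETS8 = _OFFSETS4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


class StateCorruptionError(RuntimeError):
    """Raised when a step produces NaN or negative populations."""


@dataclass
class SimConfig:
    """All tunables of the simulation.

    ``g`` is the per-step birth fraction (0.1 by default; 0.001 is the
    documented slow alternative), ``mu`` the per-step emigration ceiling,
    ``C`` the rating-population coupling used only by the literal rating
    mode.  ``rating_mode`` selects the canonical crowding law or the
    literal piecewise update; ``neighborhood`` the von Neumann 4- or
    Moore 9-cell stencil.
    """

    P_max: float = 1e7
    C: float = 1.0
    g: float = 0.1
    mu: float = 0.25
    neighborhood: str = "von_neumann4"
    sea_gap_max: float = 25.0
    rating_mode: str = "canonical"
    steps_per_epoch: int = 500
    n_epochs: int = 4
    rng_seed: int = 0
    contact_threshold: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.mu <= 1:
            raise ValueError("need 0 < mu <= 1")
        if self.g < 0:
            raise ValueError("birth rate must be non-negative")
        if self.sea_gap_max < 0:
            raise ValueError("sea_gap_max must be non-negative")
        if self.neighborhood not in ("von_neumann4", "moore9"):
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")
        if self.rating_mode not in ("canonical", "literal"):
            raise ValueError(f"unknown rating_mode {self.rating_mode!r}")

    @property
    def offsets(self) -> tuple[tuple[int, int], ...]:
        return _OFFSETS4 if self.neighborhood == "von_neumann4" else _OFFSETS8


@dataclass
class Seed:
    """One entry group: label, entry cell, initial population and the
    step at which it enters (0 = present from the start)."""

    label: str
    row: int
    col: int
    population: float
    start_step: int = 0


@dataclass
class SeaLink:
    """A permitted sea crossing between coastal cells of two landmasses."""

    cell_a: tuple[int, int]
    cell_b: tuple[int, int]
    gap_km: float
    damping: float


@dataclass
class PopulationState:
    """Per-group population layers P_g(i, j) and a step counter."""

    labels: list[str]
    P: np.ndarray  # (n_groups, rows, cols), persons
    step_index: int = 0

    @property
    def total(self) -> np.ndarray:
        return self.P.sum(axis=0)

    def copy(self) -> "PopulationState":
        return PopulationState(list(self.labels), self.P.copy(), self.step_index)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.P)):
            raise StateCorruptionError(f"non-finite population at step {self.step_index}")
        if np.any(self.P < 0):
            raise StateCorruptionError(f"negative population at step {self.step_index}")


@dataclass
class Trajectory:
    """Recorded output of a run: epoch snapshots, per-step totals and the
    online first-contact matrix between groups."""

    labels: list[str]
    snapshots: list[tuple[int, np.ndarray]]
    totals: list[float]
    contacts: np.ndarray  # (K, K) first-contact step, inf if never
    config: SimConfig

    @property
    def final(self) -> np.ndarray:
        return self.snapshots[-1][1]


def effective_rating(
    R_in: np.ndarray,
    P: np.ndarray,
    P_best: np.ndarray,
    config: SimConfig | None = None,
) -> np.ndarray:
    """Population-adjusted rating R.

    Canonical mode: ``R = R_in * max(0, 1 - P / (2 P_best))`` — equals
    R_in on empty cells, halves at the carrying capacity and reaches 0 at
    twice the capacity, beyond which immigration stops and emigration is
    maximal.  Literal mode implements the alternative piecewise update
    (rating rising with population below capacity), clipped to [0, 1].
    R = 0 wherever P_best = 0.
    """
    config = config or SimConfig()
    R_in = np.asarray(R_in, float)
    P = np.asarray(P, float)
    P_best = np.asarray(P_best, float)
    ok = P_best > 0
    safe_best = np.where(ok, P_best, 1.0)
    if config.rating_mode == "canonical":
        R = R_in * np.maximum(0.0, 1.0 - P / (2.0 * safe_best))
    else:
        S1 = (1.0 - R_in) / safe_best
        S2 = R_in / safe_best
        R = np.select(
            [P < safe_best, P < 2.0 * safe_best],
            [R_in + config.C * S1 * P, P - 2.0 * safe_best * S2],
            default=0.0,
        )
        R = np.clip(R, 0.0, 1.0)
    return np.where(ok, R, 0.0)


def _nb(a: np.ndarray, di: int, dj: int) -> np.ndarray:
    """out[i, j] = a[i + di, j + dj], zero off-grid."""
    out = np.zeros_like(a)
    rs = slice(max(di, 0), a.shape[0] + min(di, 0))
    rd = slice(max(-di, 0), a.shape[0] + min(-di, 0))
    cs = slice(max(dj, 0), a.shape[1] + min(dj, 0))
    cd = slice(max(-dj, 0), a.shape[1] + min(-dj, 0))
    out[rd, cd] = a[rs, cs]
    return out


def boundary_flux(
    P_total: np.ndarray,
    R: np.ndarray,
    config: SimConfig,
    links: list[SeaLink] | None = None,
) -> tuple[dict[tuple[int, int], np.ndarray], list[tuple[SeaLink, float, float]]]:
    """Directed boundary crossings for one step.

    Returns ``(cross, link_flows)`` where ``cross[(di, dj)][i, j]`` is the
    mass leaving cell (i, j) across its (di, dj) boundary this step, and
    ``link_flows`` lists ``(link, mass a->b, mass b->a)`` for each sea
    link.  The mobile pool of a cell is ``mu * P * (1 - R)``; it is
    apportioned to boundaries by destination rating and split at each
    boundary as ``F_in : F_out = R_nbr : R_self`` (sea-link crossings
    additionally damped).  Total outflow from a cell never exceeds its
    mobile pool.
    """
    links = links or []
    mobile = config.mu * P_total * (1.0 - R)
    mobile = np.maximum(mobile, 0.0)

    weights = {off: _nb(R, *off) for off in config.offsets}
    wsum = sum(weights.values())
    link_w_a = np.zeros_like(R)
    for lk in links:
        a, b = lk.cell_a, lk.cell_b
        link_w_a[a] += R[b]
        link_w_a[b] += R[a]
    wsum = wsum + link_w_a
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_wsum = np.where(wsum > 0, 1.0 / np.where(wsum > 0, wsum, 1.0), 0.0)

    cross: dict[tuple[int, int], np.ndarray] = {}
    for off, w in weights.items():
        pool = mobile * w * inv_wsum
        R_nbr = w
        denom = R + R_nbr
        frac = np.where(denom > 0, R_nbr / np.where(denom > 0, denom, 1.0), 0.0)
        cross[off] = pool * frac

    link_flows: list[tuple[SeaLink, float, float]] = []
    for lk in links:
        a, b = lk.cell_a, lk.cell_b
        flows = []
        for src, dst in ((a, b), (b, a)):
            if R[dst] > 0 and wsum[src] > 0:
                pool = mobile[src] * R[dst] / wsum[src]
                flows.append(pool * R[dst] / (R[src] + R[dst]) * lk.damping)
            else:
                flows.append(0.0)
        link_flows.append((lk, flows[0], flows[1]))
    return cross, link_flows


def apply_births(
    P: np.ndarray, R: np.ndarray, config: SimConfig
) -> np.ndarray:
    """Per-group net births: ``P_g += g * P_g * R`` (no births at R = 0)."""
    return P * (1.0 + config.g * R[None, :, :])


def build_sea_links(
    cls: np.ndarray,
    cell_size_km: float = 1.0,
    config: SimConfig | None = None,
) -> list[SeaLink]:
    """Minimal-gap coastal link between every pair of land components
    whose sea gap does not exceed ``sea_gap_max``.

    The gap is the sea span between the closest coastal cell centres
    (centre distance minus one cell size); damping is
    ``cell_size / gap``, clamped to at most 1.
    """
    config = config or SimConfig()
    land = cls == LAND
    structure = (
        ndimage.generate_binary_structure(2, 1)
        if config.neighborhood == "von_neumann4"
        else ndimage.generate_binary_structure(2, 2)
    )
    comp, n_comp = ndimage.label(land, structure=structure)
    if n_comp < 2:
        return []
    # coastal cells: land with a non-land 8-neighbour (or grid edge)
    dil = ndimage.binary_dilation(~land, structure=np.ones((3, 3), bool))
    edge = np.zeros_like(land)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    coast = land & (dil | edge)

    coords = {
        c: np.argwhere(coast & (comp == c)) for c in range(1, n_comp + 1)
    }
    links: list[SeaLink] = []
    for a_id in range(1, n_comp + 1):
        for b_id in range(a_id + 1, n_comp + 1):
            ca, cb = coords[a_id], coords[b_id]
            if len(ca) == 0 or len(cb) == 0:
                continue
            d = cdist(ca, cb)
            k = int(np.argmin(d))
            i, j = divmod(k, d.shape[1])
            gap = (float(d[i, j]) - 1.0) * cell_size_km
            if gap <= config.sea_gap_max:
                gap = max(gap, cell_size_km)
                links.append(
                    SeaLink(
                        cell_a=tuple(ca[i]),
                        cell_b=tuple(cb[j]),
                        gap_km=gap,
                        damping=min(1.0, cell_size_km / gap),
                    )
                )
    return links


def seed_state(fields: HabitabilityFields, seeds: list[Seed]) -> PopulationState:
    """Initial population state from a seed list (start_step 0 groups
    placed, later entrants registered with zero layers)."""
    labels = [s.label for s in seeds]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels")
    P = np.zeros((len(seeds), *fields.shape))
    hab = fields.habitable
    for k, s in enumerate(seeds):
        if not (0 <= s.row < fields.shape[0] and 0 <= s.col < fields.shape[1]):
            raise ValueError(f"seed {s.label!r} out of bounds")
        if not hab[s.row, s.col]:
            raise ValueError(
                f"seed {s.label!r} at ({s.row}, {s.col}) is not on habitable land"
            )
        if not s.population > 0:
            raise ValueError(f"seed {s.label!r} must have positive population")
        if s.start_step == 0:
            P[k, s.row, s.col] = s.population
    return PopulationState(labels=labels, P=P)


def step(
    state: PopulationState,
    fields: HabitabilityFields,
    config: SimConfig | None = None,
    links: list[SeaLink] | None = None,
) -> PopulationState:
    """Advance the state by one step (ratings, fluxes, births, clamp).

    Synchronous update: all fluxes are computed from the pre-step state.
    With ``g = 0`` total population is conserved.
    """
    config = config or SimConfig()
    state.validate()
    P = state.P
    P_total = state.total
    R = effective_rating(fields.R_in, P_total, fields.P_best, config)

    cross, link_flows = boundary_flux(P_total, R, config, links)

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(P_total > 0, P / np.where(P_total > 0, P_total, 1.0), 0.0)

    outflow = sum(cross.values())
    new_P = P - outflow[None] * frac
    for off, c in cross.items():
        moved = c[None] * frac  # group-resolved mass crossing each boundary
        di, dj = off
        for k in range(P.shape[0]):
            new_P[k] += _nb(moved[k], -di, -dj)
    for lk, m_ab, m_ba in link_flows:
        a, b = lk.cell_a, lk.cell_b
        if m_ab > 0:
            new_P[:, a[0], a[1]] -= m_ab * frac[:, a[0], a[1]]
            new_P[:, b[0], b[1]] += m_ab * frac[:, a[0], a[1]]
        if m_ba > 0:
            new_P[:, b[0], b[1]] -= m_ba * frac[:, b[0], b[1]]
            new_P[:, a[0], a[1]] += m_ba * frac[:, b[0], b[1]]

    new_P = np.maximum(new_P, 0.0)  # guard tiny negative float residue

    if config.g > 0:
        new_P = apply_births(new_P, R, config)
        new_total = new_P.sum(axis=0)
        over = new_total > config.P_max
        if over.any():
            logger.debug(
                "step %d: clamping %d cells at P_max", state.step_index + 1, int(over.sum())
            )
            scale = np.where(over, config.P_max / np.where(over, new_total, 1.0), 1.0)
            new_P = new_P * scale[None]

    out = PopulationState(list(state.labels), new_P, state.step_index + 1)
    out.validate()
    return out


def _update_contacts(
    contacts: np.ndarray, P: np.ndarray, step_index: int, threshold: float
) -> None:
    K = P.shape[0]
    occupied = P >= threshold
    for g in range(K):
        for h in range(g + 1, K):
            if np.isinf(contacts[g, h]) and np.any(occupied[g] & occupied[h]):
                contacts[g, h] = contacts[h, g] = step_index


def run(
    fields: HabitabilityFields,
    seeds: list[Seed],
    config: SimConfig | None = None,
    links: list[SeaLink] | None = None,
    record_every: int | None = None,
    track_contacts: bool = True,
) -> Trajectory:
    """Run the full simulation and record its trajectory.

    Snapshots are taken at step 0 and at the end of every epoch
    (``steps_per_epoch`` steps, ``n_epochs`` epochs); pass
    ``record_every`` to record at a finer interval instead (1 = every
    step).  First contacts between groups are detected online at every
    step against ``contact_threshold``.  The run is deterministic: the
    model has no stochastic terms (``rng_seed`` only feeds synthetic
    terrain generation).
    """
    config = config or SimConfig()
    if links is None:
        links = build_sea_links(fields.classification, fields.cell_size_km, config)
    state = seed_state(fields, seeds)
    K = len(seeds)
    contacts = np.full((K, K), np.inf)
    np.fill_diagonal(contacts, 0.0)

    interval = record_every if record_every is not None else config.steps_per_epoch
    n_steps = config.steps_per_epoch * config.n_epochs
    snapshots = [(0, state.P.copy())]
    totals = [float(state.total.sum())]
    if track_contacts:
        _update_contacts(contacts, state.P, 0, config.contact_threshold)

    for t in range(1, n_steps + 1):
        for k, s in enumerate(seeds):
            if s.start_step == t:
                state.P[k, s.row, s.col] += s.population
        state = step(state, fields, config, links)
        totals.append(float(state.total.sum()))
        if track_contacts:
            _update_contacts(contacts, state.P, t, config.contact_threshold)
        if t % interval == 0:
            snapshots.append((t, state.P.copy()))
    if snapshots[-1][0] != n_steps:
        snapshots.append((n_steps, state.P.copy()))

    return Trajectory(
        labels=list(state.labels),
        snapshots=snapshots,
        totals=totals,
        contacts=contacts,
        config=config,
    )
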