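"""First-contact statistics and comparison with genetic differentiation.

The time (in simulation steps) until populations seeded at different entry
points first co-occupy a cell is a proxy for how separated the
corresponding gene pools stayed.  Normalizing the K x K matrix of
first-contact steps by its largest finite entry yields the *distance
parameter*: 0 within a group, 1 for the latest-contacting pair.  The
distance parameter can then be correlated (Pearson, over unordered pairs)
against an externally supplied matrix of pairwise genetic distances such
as F_ST, the fixation index of allele-frequency differentiation.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .engine import Trajectory

__all__ = [
    "detect_contacts",
    "distance_parameter",
    "correlate",
    "zone_map",
    "read_distance_csv",
    "write_matrix_csv",
]


def detect_contacts(trajectory: Trajectory, threshold: float = 1.0) -> np.ndarray:
    """First-contact step matrix scanned from a recorded trajectory.

    ``t[g, h]`` is the earliest recorded step at which some cell holds at
    least ``threshold`` persons of both groups; 0 on the diagonal, inf if
    the pair never meets within the run.  For step-exact times the
    trajectory must have been recorded every step (``record_every=1``);
    the engine's online tracker gives the same numbers without the
    memory cost.
    """
    K = len(trajectory.labels)
    if K < 2:
        raise ValueError("need at least two groups to detect contacts")
    t = np.full((K, K), np.inf)
    np.fill_diagonal(t, 0.0)
    for step_idx, P in trajectory.snapshots:
        occ = P >= threshold
        for g in range(K):
            for h in range(g + 1, K):
                if np.isinf(t[g, h]) and np.any(occ[g] & occ[h]):
                    t[g, h] = t[h, g] = step_idx
    return t


def distance_parameter(contact_matrix: np.ndarray) -> np.ndarray:
    """Normalize first-contact steps to the distance parameter d = t / max t.

    The diagonal is 0, the latest-contacting (finite) pair is exactly 1;
    never-contacting pairs stay infinite and are excluded downstream.
    """
    t = np.asarray(contact_matrix, float)
    off = ~np.eye(t.shape[0], dtype=bool)
    finite = np.isfinite(t) & off
    if not finite.any():
        raise ValueError("no finite off-diagonal contact times")
    tmax = t[finite].max()
    if tmax == 0:
        # all contacts at step 0: every pair is at distance 0
        d = np.where(np.isfinite(t), 0.0, np.inf)
    else:
        d = t / tmax
    np.fill_diagonal(d, 0.0)
    return d


def correlate(
    d: np.ndarray | pd.DataFrame,
    genetic: np.ndarray | pd.DataFrame,
    labels: list[str] | None = None,
    exclude: list[str] | None = None,
) -> tuple[float, float]:
    """Pearson correlation between the distance parameter and a genetic
    distance matrix over unordered group pairs.

    Labeled DataFrames are aligned by label; ``exclude`` drops groups
    before vectorization (e.g. a genetically atypical population).  Pairs
    with an infinite distance parameter are dropped with a warning.
    Returns ``(r, p_value)``.
    """
    exclude = exclude or []
    if isinstance(d, pd.DataFrame):
        labels = list(d.index)
        d_arr = d.to_numpy(float)
    else:
        d_arr = np.asarray(d, float)
    if isinstance(genetic, pd.DataFrame):
        g_labels = list(genetic.index)
        if labels is not None:
            missing = set(labels) - set(g_labels)
            if missing:
                raise ValueError(f"genetic matrix is missing labels: {sorted(missing)}")
            genetic = genetic.loc[labels, labels]
        g_arr = genetic.to_numpy(float)
    else:
        g_arr = np.asarray(genetic, float)
    if d_arr.shape != g_arr.shape:
        raise ValueError("matrix shapes differ")

    keep = np.ones(d_arr.shape[0], dtype=bool)
    if exclude:
        if labels is None:
            raise ValueError("label list required to apply exclusions")
        keep = np.array([lab not in exclude for lab in labels])
    d_arr = d_arr[np.ix_(keep, keep)]
    g_arr = g_arr[np.ix_(keep, keep)]

    iu = np.triu_indices(d_arr.shape[0], k=1)
    x, y = d_arr[iu], g_arr[iu]
    finite = np.isfinite(x) & np.isfinite(y)
    if finite.sum() < len(x):
        warnings.warn(
            f"dropping {len(x) - int(finite.sum())} never-contacting pair(s) from correlation"
        )
    x, y = x[finite], y[finite]
    if len(x) < 3:
        raise ValueError("need at least 3 usable pairs for a correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def zone_map(
    trajectory: Trajectory, zones: np.ndarray, zone_labels: dict[int, str] | None = None
) -> pd.DataFrame:
    """Per-zone, per-group population totals at every snapshot.

    ``zones`` is an integer label raster on the simulation grid; cells
    with a label not present in ``zone_labels`` (when given) are grouped
    under ``"unassigned"``.  Returns a tidy DataFrame with columns
    ``step, zone, group, population, dominant``.
    """
    zones = np.asarray(zones)
    if zones.shape != trajectory.snapshots[0][1].shape[1:]:
        raise ValueError("zone raster shape does not match the grid")
    ids = np.unique(zones)
    names = {}
    for z in ids:
        if zone_labels is not None and int(z) not in zone_labels:
            names[int(z)] = "unassigned"
        else:
            names[int(z)] = (zone_labels or {}).get(int(z), str(int(z)))

    rows = []
    for step_idx, P in trajectory.snapshots:
        for z in ids:
            mask = zones == z
            totals = P[:, mask].sum(axis=1)
            dominant = (
                trajectory.labels[int(np.argmax(totals))] if totals.max() > 0 else None
            )
            for k, lab in enumerate(trajectory.labels):
                rows.append(
                    {
                        "step": step_idx,
                        "zone": names[int(z)],
                        "group": lab,
                        "population": float(totals[k]),
                        "dominant": dominant,
                    }
                )
    return pd.DataFrame(rows)


def read_distance_csv(path: str | Path) -> pd.DataFrame:
    """Read a labeled symmetric distance matrix (header row and index
    column of group labels) and validate symmetry and a zero diagonal."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    arr = df.to_numpy(float)
    if not np.allclose(arr, arr.T, equal_nan=True):
        raise ValueError(f"{path}: matrix is not symmetric")
    if not np.allclose(np.diag(arr), 0.0):
        raise ValueError(f"{path}: diagonal is not zero")
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError(f"{path}: negative distances")
    return df


def write_matrix_csv(
    matrix: np.ndarray, labels: list[str], path: str | Path
) -> Path:
    """Write a labeled matrix as CSV (inf preserved as 'inf')."""
    df = pd.DataFrame(np.asarray(matrix, float), index=labels, columns=labels)
    path = Path(path)
    df.to_csv(path)
    return path
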