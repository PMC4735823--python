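"""Invasion metrics: distance moved, net translocation, RoG, degradation,
cluster statistics.

All distance metrics operate on a trajectory array of shape
``(T, n_cells, 2)`` holding centroid positions in um sampled every MCS.
Cells that disappeared during a run carry NaN rows and are excluded (with a
warning) — disappearance is energetically enormous under the area constraint
and essentially never occurs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components


@dataclass
class MetricsReport:
    """Per-replicate summary of one simulation."""

    d_total_um: float
    d_net_um: float
    rog_um: float
    pct_degradation: float
    n_clusters: int
    mean_cluster_size: float
    cluster_sizes: list[int]


def _valid_cells(traj: np.ndarray) -> np.ndarray:
    traj = np.asarray(traj, dtype=float)
    if traj.ndim != 3 or traj.shape[2] != 2:
        raise ValueError("trajectory must have shape (T, n_cells, 2)")
    ok = ~np.isnan(traj).any(axis=(0, 2))
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} cell(s) with incomplete trajectories excluded",
            stacklevel=3,
        )
    if not ok.any():
        raise ValueError("no cell has a complete trajectory")
    return traj[:, ok, :]


def total_distance(traj: np.ndarray) -> float:
    """Population mean of the per-cell path length, summed MCS to MCS."""
    traj = _valid_cells(traj)
    if traj.shape[0] < 2:
        warnings.warn("single time point: total distance is 0", stacklevel=2)
        return 0.0
    steps = np.linalg.norm(np.diff(traj, axis=0), axis=2)
    return float(steps.sum(axis=0).mean())


def net_translocation(traj: np.ndarray) -> float:
    """Population mean of |final - initial| cell position."""
    traj = _valid_cells(traj)
    d = np.linalg.norm(traj[-1] - traj[0], axis=1)
    return float(d.mean())


def radius_of_gyration(final_positions: np.ndarray, centre: np.ndarray) -> float:
    """RoG of the population about the initial aggregate centre:
    sqrt(mean of squared distances)."""
    pos = np.asarray(final_positions, dtype=float).reshape(-1, 2)
    pos = pos[~np.isnan(pos).any(axis=1)]
    if pos.shape[0] == 0:
        raise ValueError("no positions")
    d2 = ((pos - np.asarray(centre, dtype=float)) ** 2).sum(axis=1)
    return float(np.sqrt(d2.mean()))


def percent_ecm_degradation(initial_fibre_px: int, final_fibre_px: int) -> float:
    """Percentage of initial fibre pixels degraded over the run."""
    if initial_fibre_px <= 0:
        raise ValueError("undefined: no fibre pixels initially")
    return 100.0 * (initial_fibre_px - final_fibre_px) / initial_fibre_px


def cluster_stats(sigma: np.ndarray) -> tuple[int, list[int]]:
    """Connected components of the cell-contact graph.

    Two cells are adjacent iff any of their pixels are 4-neighbours; a
    cluster is a connected component.  Returns (n_clusters, sizes) with
    sizes in descending order; sizes sum to the number of live cells.
    """
    sigma = np.asarray(sigma)
    ids = np.unique(sigma[sigma > 0])
    if ids.size == 0:
        raise ValueError("no cells on the lattice")
    remap = {int(c): k for k, c in enumerate(ids)}
    n = ids.size

    rows, cols = [], []
    for a, b in (
        (sigma[:-1, :], sigma[1:, :]),
        (sigma[:, :-1], sigma[:, 1:]),
    ):
        touch = (a > 0) & (b > 0) & (a != b)
        for u, v in zip(a[touch].ravel(), b[touch].ravel()):
            rows.append(remap[int(u)])
            cols.append(remap[int(v)])
    adj = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    sizes = sorted(np.bincount(labels).tolist(), reverse=True)
    return n_comp, sizes


def alignment_cosine(traj: np.ndarray, axis: tuple[float, float] = (1.0, 0.0)) -> float:
    """Mean |cos(theta)| between per-cell net displacements and a fibre axis.

    1.0 means motion purely along the axis; isotropic motion gives ~2/pi.
    Cells that did not move are skipped.
    """
    traj = _valid_cells(traj)
    d = traj[-1] - traj[0]
    norms = np.linalg.norm(d, axis=1)
    moved = norms > 0
    if not moved.any():
        raise ValueError("no cell moved")
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    cos = (d[moved] @ ax) / norms[moved]
    return float(np.abs(cos).mean())


def report(
    traj_um: np.ndarray,
    sigma: np.ndarray,
    initial_fibre_px: int,
    final_fibre_px: int,
    initial_centre_um: np.ndarray,
) -> MetricsReport:
    """Assemble the standard per-replicate metrics bundle."""
    d_tot = total_distance(traj_um)
    d_net = net_translocation(traj_um)
    if d_net > d_tot + 1e-9:
        raise AssertionError("triangle inequality violated: d_net > d_total")
    rog = radius_of_gyration(traj_um[-1], initial_centre_um)
    pct = (
        percent_ecm_degradation(initial_fibre_px, final_fibre_px)
        if initial_fibre_px > 0
        else 0.0
    )
    n_clust, sizes = cluster_stats(sigma)
    return MetricsReport(
        d_total_um=d_tot,
        d_net_um=d_net,
        rog_um=rog,
        pct_degradation=pct,
        n_clusters=n_clust,
        mean_cluster_size=float(np.mean(sizes)),
        cluster_sizes=sizes,
    )
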