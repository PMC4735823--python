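"""The GGH/CPM engine: energy evaluation, Metropolis dynamics, polarity.

Cells are multi-pixel lattice domains evolved by energy-biased pixel copies
(Graner-Glazier-Hogeweg dynamics).  The static Hamiltonian has three terms::

    E = sum_edges J(type_i, type_j)                      contact energy
      + sum_cells lam_a * (a(c) - a0)^2                  area constraint
      + sum_cells lam_p * (p(c) - p0)^2                  perimeter constraint

Contact energy is charged on 4-neighbour lattice edges whose two pixels
belong to different domains (different sigma); fluid is a single domain and
carries no area/perimeter/motility terms.

Active motility enters the acceptance rule as a self-propulsion work term
rather than a state energy: every copy attempt is biased by

    w = -mu0 * sum_(affected cells) phat(c) . (x_target - x_source)

where the copy vector has length one pixel (one unit of L = 2 um, matching
mu0's units of k_BT per L).  A copy aligned with a cell's polarity is
favoured by ~mu0, the same order as the contact energies, which is what
lets cells crawl in the low-noise regime (T_m = 0.01 k_BT) where every
purely thermal fluctuation is suppressed.  The bias is not the gradient of
any lattice energy (it is a non-variational active force), so
``delta_energy`` equals the full static-energy difference *plus*
``motility_delta``, each verifiable independently.

The per-cell polarity is the normalized sum of the cell's last ``tau``
centroid displacements, recomputed once per MCS — cells tend to keep moving
the way they have been moving (a persistent, velocity-aligned random walk).
At t = 0, before any displacement history exists, every cell starts with a
randomly oriented unit polarity: the Table-style parameter regime is deep in
the low-noise limit (interface energies of order 10 k_BT against
T_m = 0.01 k_BT), where an unpolarized aggregate would have no downhill
moves at all and the dynamics would never start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import _kernels
from .params import (
    ID_FIBRE,
    ID_FLUID,
    MCS_SECONDS,
    PIXEL_UM,
    TYPE_CELL,
    TYPE_FIBRE,
    TYPE_FLUID,
    EnergyParams,
    MMPParams,
)
from .mmp import contact_fibre_pixels


@dataclass
class CellRecord:
    """Read-only snapshot of one cell's bookkeeping state."""

    id: int
    area: int
    perimeter_px: float
    centroid_px: tuple[float, float]
    polarity: tuple[float, float]


def metropolis_accept(delta_e: float, t_m: float, u: float) -> bool:
    """Boltzmann acceptance: always if dE < 0, else with prob exp(-dE/T_m)."""
    if t_m <= 0:
        raise ValueError("T_m must be positive")
    if delta_e < 0:
        return True
    return u < math.exp(-delta_e / t_m)


def update_polarity(displacements: np.ndarray) -> np.ndarray:
    """Unit polarity from a (k, 2) history of centroid displacements.

    Returns the normalized vector sum, or the zero vector when the
    displacements cancel exactly (the motility term is then inert).
    """
    s = np.asarray(displacements, dtype=float).reshape(-1, 2).sum(axis=0)
    norm = float(np.hypot(s[0], s[1]))
    if norm == 0.0:
        return np.zeros(2)
    return s / norm


def _pixel_type(sigma: np.ndarray) -> np.ndarray:
    typ = np.full(sigma.shape, TYPE_FLUID, dtype=np.int8)
    typ[sigma == ID_FIBRE] = TYPE_FIBRE
    typ[sigma > 0] = TYPE_CELL
    return typ


def motility_delta(
    source: tuple[int, int],
    target: tuple[int, int],
    source_polarity: np.ndarray | None,
    target_polarity: np.ndarray | None,
    mu0: float,
) -> float:
    """Self-propulsion work for one copy attempt.

    Pass the polarity of the source-side cell and of the target-side cell
    (``None`` for fluid, which is not self-propelled).  A copy whose vector
    aligns with a cell's polarity returns a negative (favoured) value; zero
    polarities contribute nothing.
    """
    d = np.asarray(target, dtype=float) - np.asarray(source, dtype=float)
    w = 0.0
    for pol in (source_polarity, target_polarity):
        if pol is not None:
            w -= mu0 * float(np.dot(np.asarray(pol, dtype=float), d))
    return w


def total_energy(sigma: np.ndarray, params: EnergyParams) -> float:
    """Full recompute of the static Hamiltonian from the lattice alone.

    Contact + area + perimeter terms; the motility bias is work, not state
    energy, and is excluded (see module docstring).  Used as the global
    counterpart in local/global consistency checks and for diagnostics; the
    Metropolis kernel never calls this.
    """
    J = params.j_matrix()
    typ = _pixel_type(sigma)

    e = 0.0
    for axis in (0, 1):
        s1 = sigma.take(range(sigma.shape[axis] - 1), axis=axis)
        s2 = sigma.take(range(1, sigma.shape[axis]), axis=axis)
        t1 = typ.take(range(typ.shape[axis] - 1), axis=axis)
        t2 = typ.take(range(1, typ.shape[axis]), axis=axis)
        diff = s1 != s2
        e += J[t1[diff], t2[diff]].sum()

    ids = sigma[sigma > 0]
    if ids.size:
        nmax = int(ids.max())
        areas = np.bincount(ids, minlength=nmax + 1).astype(float)
        perim = _perimeters(sigma, nmax)
        live = areas > 0
        live[0] = False
        e += params.lam_a * ((areas[live] - params.a0) ** 2).sum()
        e += params.lam_p * ((perim[live] - params.p0) ** 2).sum()
    return float(e)


def _perimeters(sigma: np.ndarray, nmax: int) -> np.ndarray:
    """Per-cell boundary edge counts (lattice-interior 4-neighbour edges)."""
    perim = np.zeros(nmax + 1)
    for axis in (0, 1):
        s1 = sigma.take(range(sigma.shape[axis] - 1), axis=axis)
        s2 = sigma.take(range(1, sigma.shape[axis]), axis=axis)
        diff = s1 != s2
        a = s1[diff]
        b = s2[diff]
        perim += np.bincount(a[a > 0], minlength=nmax + 1)[: nmax + 1]
        perim += np.bincount(b[b > 0], minlength=nmax + 1)[: nmax + 1]
    return perim


class Simulation:
    """Full hybrid simulation state: lattice + cells + MMP field.

    Parameters
    ----------
    sigma:
        Initial cell-id lattice (0 fluid, -1 fibre, >=1 cell), modified in
        place as the simulation runs.
    params:
        Hamiltonian coefficients.
    mmp:
        Reaction-diffusion parameters; pass ``None`` (or set
        ``proteolysis=False``) to disable the MMP machinery entirely.
    seed:
        Seeds both the Metropolis kernel and the initial random polarities.
    """

    def __init__(
        self,
        sigma: np.ndarray,
        params: EnergyParams | None = None,
        mmp: MMPParams | None = None,
        proteolysis: bool = True,
        seed: int = 0,
        record_every: int = 1,
    ):
        self.sigma = np.ascontiguousarray(sigma, dtype=np.int32)
        self.params = params or EnergyParams()
        self.mmp = mmp if proteolysis else None
        self.proteolysis = proteolysis and mmp is not None
        self.rng = np.random.default_rng(seed)
        self.record_every = record_every

        ids = self.sigma[self.sigma > 0]
        self.n_cells = int(ids.max()) if ids.size else 0
        n1 = self.n_cells + 1
        self.areas = np.bincount(ids, minlength=n1).astype(np.float64)
        self.perim = _perimeters(self.sigma, self.n_cells)
        xs, ys = np.nonzero(self.sigma > 0)
        cid = self.sigma[xs, ys]
        self.sx = np.bincount(cid, weights=xs, minlength=n1)
        self.sy = np.bincount(cid, weights=ys, minlength=n1)

        # polarity: random unit vectors at t=0 (see module docstring)
        theta = self.rng.uniform(0.0, 2.0 * np.pi, size=n1)
        self.polx = np.cos(theta)
        self.poly = np.sin(theta)
        self.polx[0] = self.poly[0] = 0.0
        dead = self.areas == 0
        self.polx[dead] = self.poly[dead] = 0.0

        tau = self.params.tau
        self._hist = np.zeros((n1, tau, 2))
        self._hist_len = np.zeros(n1, dtype=np.int64)
        self._hist_pos = np.zeros(n1, dtype=np.int64)

        self.field = np.zeros_like(self.sigma, dtype=np.float64)
        self._field_box: tuple[int, int, int, int] | None = None
        self._evolvable = np.flatnonzero(self.sigma.ravel() != ID_FIBRE).astype(
            np.int64
        )
        self.mcs = 0
        self.substeps_last_mcs = 0
        self.substeps_total = 0
        self.attempts_total = 0
        self.accepted_total = 0
        self.degradation_events = 0
        self.removed_cells: list[tuple[int, int]] = []  # (mcs, cell_id)
        self.fragmentation_log: list[int] = []

        self._J = self.params.j_matrix()
        self._prev_centroids = self.centroids_px()
        self.initial_fibre_px = int(np.count_nonzero(self.sigma == ID_FIBRE))
        self.trajectory_px: list[np.ndarray] = [self._prev_centroids.copy()]
        self.mmp_total_series: list[float] = [0.0]
        self.fibre_px_series: list[int] = [self.initial_fibre_px]

    # ------------------------------------------------------------------ state

    def centroids_px(self) -> np.ndarray:
        """(n_cells+1, 2) centroid array in pixel units; NaN for dead cells."""
        out = np.full((self.areas.shape[0], 2), np.nan)
        live = self.areas > 0
        live[0] = False
        out[live, 0] = self.sx[live] / self.areas[live]
        out[live, 1] = self.sy[live] / self.areas[live]
        return out

    def polarity(self) -> np.ndarray:
        return np.stack([self.polx, self.poly], axis=1)

    def cell_records(self) -> list[CellRecord]:
        cents = self.centroids_px()
        return [
            CellRecord(
                c,
                int(self.areas[c]),
                float(self.perim[c]),
                (float(cents[c, 0]), float(cents[c, 1])),
                (float(self.polx[c]), float(self.poly[c])),
            )
            for c in range(1, self.n_cells + 1)
            if self.areas[c] > 0
        ]

    def total_energy(self) -> float:
        return total_energy(self.sigma, self.params)

    def delta_energy(self, source: tuple[int, int], target: tuple[int, int]) -> float:
        """Acceptance energy change for copying source onto target.

        Equals the static-Hamiltonian difference plus the motility work
        (see :func:`motility_delta`).  Raises on geometry that the
        Metropolis kernel would never attempt: non-neighbouring pixels,
        fibre involvement, or a same-domain copy (which the dynamics skips
        and for which dE is undefined).
        """
        (x, y), (nx, ny) = source, target
        if abs(x - nx) + abs(y - ny) != 1:
            raise ValueError("source and target must be 4-neighbours")
        if self.sigma[x, y] == ID_FIBRE or self.sigma[nx, ny] == ID_FIBRE:
            raise ValueError("fibre pixels do not participate in copy attempts")
        if self.sigma[x, y] == self.sigma[nx, ny]:
            raise ValueError("same-domain copy: attempt is skipped, dE undefined")
        de, _, _ = _kernels.attempt_delta_energy(
            self.sigma, x, y, nx, ny, self._J,
            self.areas, self.perim, self.polx, self.poly,
            self.params.lam_a, self.params.lam_p, self.params.a0,
            self.params.p0, self.params.mu0,
        )
        return float(de)

    # ---------------------------------------------------------------- dynamics

    def _active_field_box(self, cxs: np.ndarray, cys: np.ndarray):
        """Padded bounding box of the non-negligible MMP field + secretion sites.

        The PDE substeps run on a lattice sub-view: the field outside the
        box is below 1e-9 molecules (irrelevant against the degradation
        threshold of 1) and the 1e-9 contour spreads by well under the
        10-px pad per MCS.  Returns None when there is nothing to
        integrate.
        """
        prev = self._field_box
        boxes = []
        if prev is not None:
            x0, x1, y0, y1 = prev
            sub = self.field[x0:x1, y0:y1]
            nz = np.nonzero(sub > 1e-9)
            if nz[0].size:
                boxes.append((
                    x0 + int(nz[0].min()), x0 + int(nz[0].max()) + 1,
                    y0 + int(nz[1].min()), y0 + int(nz[1].max()) + 1,
                ))
        if cxs.size:
            boxes.append((
                int(cxs.min()), int(cxs.max()) + 1,
                int(cys.min()), int(cys.max()) + 1,
            ))
        if not boxes:
            self._field_box = None
            return None
        pad = 10
        n = self.sigma.shape[0]
        x0 = max(0, min(b[0] for b in boxes) - pad)
        x1 = min(n, max(b[1] for b in boxes) + pad)
        y0 = max(0, min(b[2] for b in boxes) - pad)
        y1 = min(self.sigma.shape[1], max(b[3] for b in boxes) + pad)
        self._field_box = (x0, x1, y0, y1)
        return self._field_box

    def run_mcs(self) -> None:
        """Advance the simulation by one Monte Carlo step.

        Order of operations: N copy attempts over the evolvable (cell +
        fluid) pixels; record per-cell centroid displacements and update
        polarities; run the 36 one-second MMP substeps (secretion +
        diffusion/decay); apply threshold ECM degradation once; record the
        trajectory row.
        """
        p = self.params
        evolvable = self._evolvable
        n = evolvable.shape[0]
        pick = self.rng.integers(0, n, size=n, dtype=np.int64)
        dirs = self.rng.integers(0, 4, size=n, dtype=np.int64)
        unif = self.rng.random(size=n)
        n_att, n_acc = _kernels.run_mcs_attempts(
            self.sigma, evolvable, self._J,
            self.areas, self.perim, self.sx, self.sy, self.polx, self.poly,
            p.lam_a, p.lam_p, p.a0, p.p0, p.t_m, p.mu0,
            pick, dirs, unif,
        )
        self.attempts_total += n_att
        self.accepted_total += n_acc

        # displacement history and polarity (once per MCS, fixed thereafter)
        cents = self.centroids_px()
        disp = cents - self._prev_centroids
        live = self.areas > 0
        live[0] = False
        died = ~live
        died[0] = False
        newly_dead = died & (
            (self.polx != 0.0) | (self.poly != 0.0) | (self._hist_len > 0)
        )
        if newly_dead.any():
            for c in np.nonzero(newly_dead)[0]:
                self.removed_cells.append((self.mcs + 1, int(c)))
            self.polx[newly_dead] = self.poly[newly_dead] = 0.0
            self._hist_len[newly_dead] = 0

        ids = np.nonzero(live)[0]
        if ids.size:
            # ring buffer: slots beyond the filled length stay zero, so the
            # window sum is simply the sum over the whole tau axis
            self._hist[ids, self._hist_pos[ids], 0] = disp[ids, 0]
            self._hist[ids, self._hist_pos[ids], 1] = disp[ids, 1]
            self._hist_pos[ids] = (self._hist_pos[ids] + 1) % p.tau
            self._hist_len[ids] = np.minimum(self._hist_len[ids] + 1, p.tau)
            hsum = self._hist[ids].sum(axis=1)
            norm = np.hypot(hsum[:, 0], hsum[:, 1])
            moved = (np.abs(self._hist[ids]) > 0.0).any(axis=(1, 2))
            # cells whose whole window is exactly zero keep their current
            # (bootstrap or previous) polarity so a transiently stuck cell
            # keeps probing instead of de-polarizing for good
            upd = moved & (norm > 0.0)
            self.polx[ids[upd]] = hsum[upd, 0] / norm[upd]
            self.poly[ids[upd]] = hsum[upd, 1] / norm[upd]
            cancel = moved & (norm == 0.0)
            self.polx[ids[cancel]] = self.poly[ids[cancel]] = 0.0
        self._prev_centroids = cents

        # MMP secretion/diffusion/decay substeps, then per-MCS degradation
        self.substeps_last_mcs = 0
        if self.proteolysis and self.mmp is not None:
            m = self.mmp
            cxs, cys = contact_fibre_pixels(self.sigma)
            box = self._active_field_box(cxs, cys)
            if box is not None:
                x0, x1, y0, y1 = box
                nsub, vmax = _kernels.mmp_substeps(
                    self.field, cxs, cys,
                    m.secretion_per_s * m.dt_s,
                    m.stability_number,
                    m.decay_per_s * m.dt_s,
                    m.substeps_per_mcs,
                    x0, x1, y0, y1,
                )
                if vmax > 1e6:
                    raise FloatingPointError(
                        f"MMP solver unstable at MCS {self.mcs}: max={vmax:.3g}"
                    )
            else:
                nsub = m.substeps_per_mcs  # nothing to integrate: field is zero
            self.substeps_last_mcs = nsub
            self.substeps_total += nsub
            mask = (self.sigma == ID_FIBRE) & (self.field >= m.degrade_threshold)
            n_events = int(np.count_nonzero(mask))
            if n_events:
                self.sigma[mask] = ID_FLUID
                self.field[mask] -= 1.0
                # degraded pixels become fluid and join the evolvable set
                self._evolvable = np.concatenate(
                    [self._evolvable, np.flatnonzero(mask.ravel())]
                )
                self.degradation_events += n_events

        self.mcs += 1
        if self.mcs % self.record_every == 0:
            self.trajectory_px.append(cents)
            self.mmp_total_series.append(float(self.field.sum()))
            self.fibre_px_series.append(int(np.count_nonzero(self.sigma == ID_FIBRE)))

    def run(self, n_mcs: int) -> "Simulation":
        for _ in range(n_mcs):
            self.run_mcs()
        return self

    # ---------------------------------------------------------------- outputs

    @property
    def simulated_hours(self) -> float:
        """Wall-clock duration represented so far (36 s per MCS)."""
        return self.mcs * MCS_SECONDS / 3600.0

    def trajectory_um(self) -> np.ndarray:
        """(T, n_cells, 2) centroid trajectory in um (cells 1..n, by MCS)."""
        arr = np.stack(self.trajectory_px, axis=0)[:, 1:, :]
        return (arr + 0.5) * PIXEL_UM

    def trajectory_to_csv(self, path) -> None:
        """Long-format trajectory: one row per (mcs, cell)."""
        import pandas as pd

        traj = self.trajectory_um()
        rows = []
        pol = self.polarity()
        for t in range(traj.shape[0]):
            for c in range(1, self.n_cells + 1):
                if np.isnan(traj[t, c - 1, 0]):
                    continue
                rows.append(
                    (t * self.record_every, c, traj[t, c - 1, 0],
                     traj[t, c - 1, 1], int(self.areas[c]),
                     pol[c, 0], pol[c, 1])
                )
        pd.DataFrame(
            rows,
            columns=["mcs", "cell_id", "x_um", "y_um", "area_px",
                     "polarity_x", "polarity_y"],
        ).to_csv(path, index=False, float_format="%.6g")

    def save_snapshot(self, path) -> None:
        """Compressed state snapshot: pixel classes, cell ids, MMP field."""
        pixel_class = _pixel_type(self.sigma)
        np.savez_compressed(
            path, pixel_class=pixel_class, cell_id=self.sigma,
            mmp_field=self.field, mcs=self.mcs,
        )

    def check_integrity(self) -> None:
        """Verify cached areas/perimeters/centroids against the lattice."""
        ids = self.sigma[self.sigma > 0]
        n1 = self.n_cells + 1
        areas = np.bincount(ids, minlength=n1).astype(float)
        if not np.array_equal(areas, self.areas):
            raise RuntimeError("cached areas inconsistent with lattice")
        if not np.array_equal(_perimeters(self.sigma, self.n_cells), self.perim):
            raise RuntimeError("cached perimeters inconsistent with lattice")
        xs, ys = np.nonzero(self.sigma > 0)
        cid = self.sigma[xs, ys]
        sx = np.bincount(cid, weights=xs, minlength=n1)
        sy = np.bincount(cid, weights=ys, minlength=n1)
        if not (np.allclose(sx, self.sx) and np.allclose(sy, self.sy)):
            raise RuntimeError("cached centroid sums inconsistent with lattice")
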