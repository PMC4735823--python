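"""Soluble-MMP field: secretion at cell-fibre contacts, PDE, degradation.

Cells in contact with ECM fibres secrete matrix metalloproteinases at rate
``lambda`` per second *at the fibre pixel* (ECM-density-dependent secretion:
denser meshes expose more contact pixels and therefore receive more enzyme).
The field then diffuses (D = 0.1 um^2/s) and decays (delta = 0.002/s) by
forward-Euler substeps of 1 s, 36 per MCS.  Once per MCS, every fibre pixel
whose local MMP count has reached 1 is degraded: the pixel becomes fluid and
the count there is decremented by 1.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .params import ID_FIBRE, ID_FLUID, MMPParams


def contact_fibre_pixels(sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fibre pixels with at least one cell among their 8 neighbours.

    Returns the (xs, ys) index arrays of secretion sites.  Deposition is one
    unit-rate per contacting fibre pixel regardless of how many cell pixels
    touch it.
    """
    cell = sigma > 0
    near = np.zeros_like(cell)
    # dilate the cell mask by one pixel in the Moore (8-) neighbourhood
    near[1:, :] |= cell[:-1, :]
    near[:-1, :] |= cell[1:, :]
    near[:, 1:] |= cell[:, :-1]
    near[:, :-1] |= cell[:, 1:]
    near[1:, 1:] |= cell[:-1, :-1]
    near[1:, :-1] |= cell[:-1, 1:]
    near[:-1, 1:] |= cell[1:, :-1]
    near[:-1, :-1] |= cell[1:, 1:]
    xs, ys = np.nonzero((sigma == ID_FIBRE) & near)
    return xs.astype(np.int64), ys.astype(np.int64)


def secrete(field: np.ndarray, sigma: np.ndarray, lam: float, dt: float = 1.0) -> np.ndarray:
    """One secretion substep: add lam*dt at every cell-contacted fibre pixel."""
    if lam < 0:
        raise ValueError("secretion rate must be non-negative")
    xs, ys = contact_fibre_pixels(sigma)
    field[xs, ys] += lam * dt
    return field


def diffuse_decay_step(field: np.ndarray, mmp: MMPParams | None = None) -> np.ndarray:
    """One forward-Euler diffusion/decay substep (in place).

    5-point Laplacian with zero-flux boundaries; negativity is clamped at 0
    (unreachable within the stability bound, kept as a hard floor).
    """
    m = mmp or MMPParams()
    empty = np.empty(0, dtype=np.int64)
    _, vmax = _kernels.mmp_substeps(
        field, empty, empty, 0.0, m.stability_number, m.decay_per_s * m.dt_s, 1,
        0, field.shape[0], 0, field.shape[1],
    )
    if vmax > 1e6:
        raise FloatingPointError(f"MMP solver unstable: max={vmax:.3g}")
    return field


def degrade_ecm_inplace(field: np.ndarray, sigma: np.ndarray, threshold: float = 1.0) -> int:
    """Threshold ECM degradation, called once per MCS after the substeps.

    Every fibre pixel whose MMP count is >= threshold becomes fluid and the
    count there drops by 1.  Returns the number of degradation events.
    """
    mask = (sigma == ID_FIBRE) & (field >= threshold)
    n = int(np.count_nonzero(mask))
    if n:
        sigma[mask] = ID_FLUID
        field[mask] -= 1.0
    return n


def degrade_ecm(field: np.ndarray, sigma: np.ndarray, threshold: float = 1.0):
    """Functional wrapper: returns (new_sigma, new_field, event_coordinates)."""
    sigma = sigma.copy()
    field = field.copy()
    mask = (sigma == ID_FIBRE) & (field >= threshold)
    events = list(zip(*np.nonzero(mask)))
    sigma[mask] = ID_FLUID
    field[mask] -= 1.0
    return sigma, field, events
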