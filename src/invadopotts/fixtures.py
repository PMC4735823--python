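"""Deterministic toy inputs for oracle tests and examples.

Every fixture is built programmatically — nothing is read from disk — and
returns a small lattice (or trajectory) together with hand-derivable
expected values.
"""

from __future__ import annotations

import numpy as np

from .params import ID_FIBRE

FIXTURE_NAMES = ("two_cells", "secretion_unit", "round_trip", "three_clusters")


def make_fixture(name: str):
    """Return (payload, expected) for a named fixture.

    ``two_cells``      20x20 lattice, two adjacent 10x10 cells sharing a
                       10-edge boundary wall.
    ``secretion_unit`` 9x9 lattice with one fibre pixel and one cell pixel
                       touching it.
    ``round_trip``     a 6-step out-and-back single-cell trajectory (um)
                       with d_net = 0 and d_total = 20.
    ``three_clusters`` 20x20 lattice with six cells in components of sizes
                       3, 2 and 1.
    """
    if name == "two_cells":
        # kept clear of the lattice boundary so every cell edge is interior
        sigma = np.zeros((22, 20), dtype=np.int32)
        sigma[1:11, 5:15] = 1
        sigma[11:21, 5:15] = 2
        return sigma, {"n_cells": 2, "shared_edges": 10, "area": 100,
                       "outer_edges": 60}
    if name == "secretion_unit":
        sigma = np.zeros((9, 9), dtype=np.int32)
        sigma[4, 4] = ID_FIBRE
        sigma[3, 4] = 1
        return sigma, {"n_contact_pixels": 1}
    if name == "round_trip":
        out = np.array([[0, 0], [2, 0], [4, 0], [6, 0], [8, 0], [10, 0]], float)
        back = out[::-1][1:]
        traj = np.concatenate([out, back])[:, None, :]
        return traj, {"d_net_um": 0.0, "d_total_um": 20.0}
    if name == "three_clusters":
        sigma = np.zeros((20, 20), dtype=np.int32)
        # chain of three cells: 1-2 and 2-3 touch
        sigma[0:4, 0:4] = 1
        sigma[4:8, 0:4] = 2
        sigma[8:12, 0:4] = 3
        # pair: 4-5 touch
        sigma[0:4, 10:14] = 4
        sigma[0:4, 14:18] = 5
        # singleton
        sigma[14:18, 10:14] = 6
        return sigma, {"n_clusters": 3, "sizes": [3, 2, 1]}
    raise ValueError(f"unknown fixture {name!r}; valid: {FIXTURE_NAMES}")
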