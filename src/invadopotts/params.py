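"""Parameter containers for the hybrid CPM invasion model.

Internal unit conventions
-------------------------
Energies are expressed in units of k_B*T.  Lengths are kept in *pixels*
internally (one pixel is 2 um on a side), so cell areas are in px^2 and
perimeters in px (one boundary edge = 1 px = 2 um of membrane).  Quantities
are converted to um / um^2 only at I/O and in reported metrics.  Under this
convention the target area is 100 px^2 (400 um^2) and the target perimeter
35 px.  The perimeter target is read in lattice edge units, not
micrometres: a 400 um^2 cell has at least 80 um (40 edges) of physical
perimeter, so a literal 35-um target would be geometrically unreachable
and would freeze the adhesion-driven dynamics under a permanent ~45 k_BT
per-edge penalty; 35 edges sits just below the 40-edge resting perimeter
of a 10x10 square, keeping cells compact but deformable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

#: edge length of one lattice pixel, in micrometres
PIXEL_UM: float = 2.0

#: default lattice side, in pixels (1 mm x 1 mm domain)
LATTICE_PX: int = 500

#: wall-clock seconds represented by one Monte Carlo step
MCS_SECONDS: float = 36.0

# pixel-type codes used in the J lookup table
TYPE_FLUID = 0
TYPE_FIBRE = 1
TYPE_CELL = 2

# cell-id codes on the lattice
ID_FLUID = 0
ID_FIBRE = -1


@dataclass
class EnergyParams:
    """Hamiltonian coefficients of the CPM energy.

    Interface energies ``j_xy`` are per lattice edge (k_B*T); low J means
    strong adhesion.  ``j_cc`` is the swept cell-cell adhesion energy
    (1 = high adhesion / epithelial, 40 = low adhesion / mesenchymal).
    """

    j_cc: float = 16.0
    j_ce: float = 16.0
    j_cf: float = 32.0
    j_ef: float = 35.0
    j_ee: float = 5.0
    j_ff: float = 35.0
    lam_a: float = 1.0      # area constraint (inverse compressibility)
    lam_p: float = 0.5      # perimeter constraint (cortical tension)
    a0: float = 100.0       # target area, px^2 (= 400 um^2)
    p0: float = 35.0        # target perimeter, lattice edges (see module docs)
    t_m: float = 0.01       # Boltzmann noise strength, k_B*T
    mu0: float = 50.0       # active-motility strength
    tau: int = 10           # polarity memory, in MCS

    def j_matrix(self) -> np.ndarray:
        """Symmetric 3x3 interface-energy table indexed by pixel type.

        Index order is (fluid, fibre, cell); entry [a, b] is the energy per
        boundary edge between domains of types a and b.
        """
        j = np.empty((3, 3), dtype=np.float64)
        j[TYPE_FLUID, TYPE_FLUID] = self.j_ff
        j[TYPE_FIBRE, TYPE_FIBRE] = self.j_ee
        j[TYPE_CELL, TYPE_CELL] = self.j_cc
        j[TYPE_FLUID, TYPE_FIBRE] = j[TYPE_FIBRE, TYPE_FLUID] = self.j_ef
        j[TYPE_FLUID, TYPE_CELL] = j[TYPE_CELL, TYPE_FLUID] = self.j_cf
        j[TYPE_FIBRE, TYPE_CELL] = j[TYPE_CELL, TYPE_FIBRE] = self.j_ce
        return j

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MMPParams:
    """Reaction-diffusion parameters of the soluble-MMP field.

    The field evolves by forward-Euler substeps of ``dt`` seconds; with
    D = 0.1 um^2/s, dt = 1 s and dx = 2 um the stability number
    r = D*dt/dx^2 = 0.025, well inside the 2D forward-Euler bound of 0.25.
    """

    diffusion_um2_s: float = 0.1      # 1.0e-9 cm^2/s
    decay_per_s: float = 0.002        # delta_MMP
    secretion_per_s: float = 0.05     # lambda, swept over 0.01-0.1
    dt_s: float = 1.0
    substeps_per_mcs: int = 36
    degrade_threshold: float = 1.0

    @property
    def stability_number(self) -> float:
        return self.diffusion_um2_s * self.dt_s / PIXEL_UM**2

    def __post_init__(self) -> None:
        if self.stability_number > 0.25:
            raise ValueError(
                f"forward-Euler unstable: r={self.stability_number:.3f} > 0.25"
            )
        if self.secretion_per_s < 0:
            raise ValueError("secretion rate must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)
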