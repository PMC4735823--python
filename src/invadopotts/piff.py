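"""PIFF layout I/O.

The pixel initialization format (PIFF) lists rectangular pixel runs, one per
line::

    <cellID> <TypeName> <x1> <x2> <y1> <y2> <z1> <z2>

with 0-based inclusive coordinates; this package writes the single-section
2D dialect (z1 = z2 = 0) with type names ``Cell``, ``Fibre`` and ``Fluid``.
Fluid is the background and is normally omitted on write; overlapping
records apply last-writer-wins (with a warning) on lattice reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .params import ID_FIBRE, ID_FLUID, LATTICE_PX

TYPE_NAMES = ("Cell", "Fibre", "Fluid")


@dataclass(frozen=True)
class PiffRecord:
    cell_id: int
    type_name: str
    x1: int
    x2: int
    y1: int
    y2: int
    z1: int = 0
    z2: int = 0

    def __post_init__(self):
        if self.type_name not in TYPE_NAMES:
            raise ValueError(f"unknown type name {self.type_name!r}")
        if self.x1 > self.x2 or self.y1 > self.y2 or self.z1 != 0 or self.z2 != 0:
            raise ValueError("malformed record extents")

    def to_line(self) -> str:
        return (
            f"{self.cell_id} {self.type_name} "
            f"{self.x1} {self.x2} {self.y1} {self.y2} {self.z1} {self.z2}"
        )


@dataclass
class PiffDocument:
    records: list[PiffRecord]

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def read_piff(path) -> PiffDocument:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 8:
                raise ValueError(f"{path}:{lineno}: expected 8 fields, got {len(parts)}")
            try:
                cid = int(parts[0])
                coords = [int(v) for v in parts[2:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            try:
                records.append(PiffRecord(cid, parts[1], *coords))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return PiffDocument(records)


def write_piff(doc: PiffDocument, path) -> None:
    with open(path, "w") as fh:
        for rec in doc.records:
            fh.write(rec.to_line() + "\n")


def lattice_to_piff(sigma: np.ndarray) -> PiffDocument:
    """Encode a lattice as horizontal per-row runs (canonical form).

    Fluid pixels are implicit.  Runs are emitted row-major (by y, then x),
    which makes write(read(f)) byte-identical for canonically written files.
    """
    records = []
    W, H = sigma.shape
    for y in range(H):
        col = sigma[:, y]
        x = 0
        while x < W:
            v = col[x]
            if v == ID_FLUID:
                x += 1
                continue
            x2 = x
            while x2 + 1 < W and col[x2 + 1] == v:
                x2 += 1
            if v == ID_FIBRE:
                records.append(PiffRecord(0, "Fibre", x, x2, y, y))
            else:
                records.append(PiffRecord(int(v), "Cell", x, x2, y, y))
            x = x2 + 1
    return PiffDocument(records)


def piff_to_lattice(doc: PiffDocument, lattice_px: int = LATTICE_PX) -> np.ndarray:
    """Reconstruct the cell-id lattice; overlaps are last-writer-wins."""
    sigma = np.full((lattice_px, lattice_px), ID_FLUID, dtype=np.int32)
    painted = np.zeros_like(sigma, dtype=bool)
    overlap_warned = False
    for rec in doc.records:
        if rec.x2 >= lattice_px or rec.y2 >= lattice_px or rec.x1 < 0 or rec.y1 < 0:
            raise ValueError(f"record outside lattice: {rec.to_line()!r}")
        block = (slice(rec.x1, rec.x2 + 1), slice(rec.y1, rec.y2 + 1))
        if not overlap_warned and painted[block].any():
            warnings.warn("overlapping PIFF records: last writer wins", stacklevel=2)
            overlap_warned = True
        if rec.type_name == "Fibre":
            sigma[block] = ID_FIBRE
        elif rec.type_name == "Cell":
            sigma[block] = rec.cell_id
        else:
            sigma[block] = ID_FLUID
        painted[block] = True
    return sigma
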