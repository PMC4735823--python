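"""Fibrillar ECM mesh generation and the initial tumour-cell aggregate.

The extracellular matrix is a planar mesh of straight fibre segments, each
2 um thick (one pixel) and 30-40 um long, rasterized onto the simulation
lattice with an 8-connected Bresenham line.  Matrix density is controlled by
the fibre count ``xi`` and matrix organization by the orientation mode
``psi`` (random angles on [0, pi) versus all-horizontal "aligned" fibres).

The invading population starts as a disk-shaped aggregate of 10x10-pixel
(20 um) square cells placed block-wise at the lattice centre; with the
default disk radius the aggregate contains exactly 69 cells.  Fibre pixels
underneath the initial aggregate are removed so no pixel starts in an
illegal cell-on-fibre state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import ID_FIBRE, ID_FLUID, LATTICE_PX, PIXEL_UM

#: fibre length range, um
FIBRE_LEN_UM = (30.0, 40.0)
FIBRE_THICKNESS_UM = 2.0

RANDOM = "random"
ALIGNED = "aligned"

#: number of cells in the reference tumour aggregate
AGGREGATE_N_CELLS = 69


@dataclass(frozen=True)
class FibreSegment:
    """A straight fibre in continuous lattice coordinates (um)."""

    start: tuple[float, float]
    end: tuple[float, float]
    thickness: float = FIBRE_THICKNESS_UM

    @property
    def length(self) -> float:
        return math.hypot(self.end[0] - self.start[0], self.end[1] - self.start[1])

    @property
    def angle(self) -> float:
        """Orientation on [0, pi)."""
        a = math.atan2(self.end[1] - self.start[1], self.end[0] - self.start[0])
        return a % math.pi


@dataclass
class FibreMesh:
    """A rasterized fibre network: segments plus their deduplicated pixels."""

    segments: list[FibreSegment]
    pixels: set[tuple[int, int]]
    count: int
    orientation_mode: str
    lattice_px: int = LATTICE_PX

    def to_mask(self) -> np.ndarray:
        mask = np.zeros((self.lattice_px, self.lattice_px), dtype=bool)
        if self.pixels:
            xs, ys = zip(*self.pixels)
            mask[list(xs), list(ys)] = True
        return mask


def _clip_segment(
    p0: tuple[float, float], p1: tuple[float, float], lo: float, hi: float
) -> tuple[tuple[float, float], tuple[float, float]] | None:
    """Liang-Barsky clip of a segment to the axis-aligned box [lo, hi]^2.

    Returns the clipped endpoints, or None when the segment misses the box.
    """
    x0, y0 = p0
    dx, dy = p1[0] - x0, p1[1] - y0
    t0, t1 = 0.0, 1.0
    for p, q in (
        (-dx, x0 - lo),
        (dx, hi - x0),
        (-dy, y0 - lo),
        (dy, hi - y0),
    ):
        if p == 0.0:
            if q < 0.0:
                return None
        else:
            t = q / p
            if p < 0.0:
                t0 = max(t0, t)
            else:
                t1 = min(t1, t)
    if t0 > t1:
        return None
    return (x0 + t0 * dx, y0 + t0 * dy), (x0 + t1 * dx, y0 + t1 * dy)


def _um_to_px(u: float, lattice_px: int) -> int:
    """Continuous um coordinate -> pixel index (pixel i covers [2i, 2i+2) um)."""
    return min(int(u // PIXEL_UM), lattice_px - 1)


def rasterize_segment(seg: FibreSegment, lattice_px: int = LATTICE_PX) -> set[tuple[int, int]]:
    """Rasterize a (clipped) fibre as an 8-connected Bresenham pixel chain.

    A zero-length segment yields a single pixel.  Pixels outside the lattice
    are discarded.
    """
    x0 = _um_to_px(seg.start[0], lattice_px)
    y0 = _um_to_px(seg.start[1], lattice_px)
    x1 = _um_to_px(seg.end[0], lattice_px)
    y1 = _um_to_px(seg.end[1], lattice_px)

    pixels: set[tuple[int, int]] = set()
    dx, dy = abs(x1 - x0), abs(y1 - y0)
    sx = 1 if x1 >= x0 else -1
    sy = 1 if y1 >= y0 else -1
    err = dx - dy
    x, y = x0, y0
    while True:
        if 0 <= x < lattice_px and 0 <= y < lattice_px:
            pixels.add((x, y))
        if x == x1 and y == y1:
            break
        e2 = 2 * err
        if e2 > -dy:
            err -= dy
            x += sx
        if e2 < dx:
            err += dx
            y += sy
    return pixels


def generate_fibre_mesh(
    xi: int,
    mode: str = RANDOM,
    seed: int = 0,
    lattice_px: int = LATTICE_PX,
) -> FibreMesh:
    """Draw ``xi`` fibres and rasterize them onto the lattice.

    Random mode draws each fibre centre uniformly over the domain, its angle
    uniformly on [0, pi) and its length uniformly on [30, 40] um; aligned
    mode forces angle 0 (horizontal).  Fibres crossing the boundary are
    clipped, not redrawn, so the segment count is exactly ``xi``.
    """
    if xi < 0:
        raise ValueError(f"fibre count must be non-negative, got {xi}")
    if mode not in (RANDOM, ALIGNED):
        raise ValueError(f"orientation mode must be {RANDOM!r} or {ALIGNED!r}")

    rng = np.random.default_rng(seed)
    extent = lattice_px * PIXEL_UM
    segments: list[FibreSegment] = []
    pixels: set[tuple[int, int]] = set()
    for _ in range(xi):
        cx = rng.uniform(0.0, extent)
        cy = rng.uniform(0.0, extent)
        angle = 0.0 if mode == ALIGNED else rng.uniform(0.0, math.pi)
        length = rng.uniform(*FIBRE_LEN_UM)
        hx = 0.5 * length * math.cos(angle)
        hy = 0.5 * length * math.sin(angle)
        clipped = _clip_segment((cx - hx, cy - hy), (cx + hx, cy + hy), 0.0, extent)
        if clipped is None:  # centre is inside the box, cannot happen
            continue
        seg = FibreSegment(clipped[0], clipped[1])
        segments.append(seg)
        pixels |= rasterize_segment(seg, lattice_px)
    return FibreMesh(segments, pixels, xi, mode, lattice_px)


@dataclass
class AggregateLayout:
    """Initial cell aggregate: mapping of cell id -> pixel set."""

    cell_pixel_map: dict[int, set[tuple[int, int]]]
    n_cells: int
    disk_radius_um: float
    cell_side_um: float = 20.0

    def centroid_px(self) -> tuple[float, float]:
        pts = [p for pix in self.cell_pixel_map.values() for p in pix]
        arr = np.asarray(pts, dtype=float)
        return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def _blocks_within_disk(radius_px: float, lattice_px: int, side_px: int):
    """Block-grid offsets (i, j) whose block centre lies within the disk."""
    centre = (lattice_px - 1) / 2.0
    max_k = int(radius_px // side_px) + 1
    hits = []
    for i in range(-max_k, max_k + 1):
        for j in range(-max_k, max_k + 1):
            if math.hypot(i * side_px, j * side_px) <= radius_px:
                hits.append((i, j))
    return hits, centre


def find_disk_radius_px(
    n_cells: int = AGGREGATE_N_CELLS,
    lattice_px: int = LATTICE_PX,
    cell_side_um: float = 20.0,
) -> float:
    """Smallest disk radius (scanned in 1-px steps) holding ``n_cells`` blocks."""
    side_px = int(round(cell_side_um / PIXEL_UM))
    for r in range(1, lattice_px // 2 + 1):
        hits, _ = _blocks_within_disk(float(r), lattice_px, side_px)
        if len(hits) >= n_cells:
            if len(hits) != n_cells:
                raise ValueError(
                    f"no 1-px-step radius yields exactly {n_cells} blocks "
                    f"(jumped {len(hits)})"
                )
            return float(r)
    raise ValueError(f"{n_cells} blocks do not fit in the lattice")


def build_initial_aggregate(
    disk_radius_um: float | None = None,
    cell_side_um: float = 20.0,
    lattice_px: int = LATTICE_PX,
) -> AggregateLayout:
    """Place square cells block-wise on a disk at the lattice centre.

    A block becomes a cell iff its centre lies within ``disk_radius_um`` of
    the lattice centre.  With the default (None) radius, the smallest radius
    producing the reference 69-cell aggregate is used.
    """
    side_px = int(round(cell_side_um / PIXEL_UM))
    if abs(side_px * PIXEL_UM - cell_side_um) > 1e-9:
        raise ValueError("cell side must be an integer number of pixels")
    if disk_radius_um is None:
        radius_px = find_disk_radius_px(AGGREGATE_N_CELLS, lattice_px, cell_side_um)
    else:
        radius_px = disk_radius_um / PIXEL_UM
    if radius_px > lattice_px / 2:
        raise ValueError("aggregate disk does not fit in the lattice")

    hits, centre = _blocks_within_disk(radius_px, lattice_px, side_px)
    # deterministic cell numbering: row-major over block offsets
    hits.sort()
    cell_pixel_map: dict[int, set[tuple[int, int]]] = {}
    half = side_px // 2
    for cid, (i, j) in enumerate(hits, start=1):
        bx = int(centre - half + 1 + i * side_px)
        by = int(centre - half + 1 + j * side_px)
        if bx < 0 or by < 0 or bx + side_px > lattice_px or by + side_px > lattice_px:
            raise ValueError("aggregate disk does not fit in the lattice")
        cell_pixel_map[cid] = {
            (bx + u, by + v) for u in range(side_px) for v in range(side_px)
        }
    return AggregateLayout(cell_pixel_map, len(hits), radius_px * PIXEL_UM, cell_side_um)


def compose_lattice(mesh: FibreMesh | None, layout: AggregateLayout | None,
                    lattice_px: int = LATTICE_PX) -> np.ndarray:
    """Build the cell-id lattice: 0 fluid, -1 fibre, >=1 cell.

    Fibre pixels overlapped by the initial aggregate are deleted (cells win
    at t = 0), so the composed lattice never holds a cell on a fibre pixel.
    """
    sigma = np.full((lattice_px, lattice_px), ID_FLUID, dtype=np.int32)
    if mesh is not None:
        for (x, y) in mesh.pixels:
            sigma[x, y] = ID_FIBRE
    if layout is not None:
        for cid, pix in layout.cell_pixel_map.items():
            for (x, y) in pix:
                sigma[x, y] = cid
    return sigma
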