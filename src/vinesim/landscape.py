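"""Abstract 10 km x 10 km landscape generation and vineyard parcel carving.

The landscape is a square integer grid (origin top-left, row-major) whose
cells each carry one of six land use/cover classes. Class shares are honoured
by exact cell quotas (largest-remainder rounding) and classes are laid out as
contiguous blobs by seeded competitive region growing, so the map reads as an
abstract landscape rather than salt-and-pepper noise. Vineyards are carved as
elongated axis-aligned rectangles (aspect ratio >= 3) entirely on viticulture
cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .config import COVER_CLASSES
from .distributions import DistributionSpec

__all__ = [
    "LandCoverGrid",
    "VineyardParcel",
    "LandscapeError",
    "generate_abstract_landscape",
    "carve_parcels",
    "cover_shares",
    "save_grid",
    "load_grid",
    "parcels_to_frame",
]

#: Single-character codes used in the ASCII raster export.
CLASS_CODES = {c: c[0].upper() for c in COVER_CLASSES}
# urban=U, viticulture=V, other_agriculture=O, forest=F, semi_natural=S, wetland_water=W
CODE_CLASSES = {v: k for k, v in CLASS_CODES.items()}


class LandscapeError(ValueError):
    """Raised for infeasible landscape or parcel requests."""


@dataclass(frozen=True)
class LandCoverGrid:
    """A square land-cover raster of side ``extent_m`` metres."""

    cells: np.ndarray  # 2-D array of class indices into COVER_CLASSES
    cell_size_m: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    @property
    def extent_m(self) -> float:
        return self.cells.shape[0] * self.cell_size_m

    def class_name(self, row: int, col: int) -> str:
        return COVER_CLASSES[int(self.cells[row, col])]

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        return (
            isinstance(other, LandCoverGrid)
            and self.cell_size_m == other.cell_size_m
            and np.array_equal(self.cells, other.cells)
        )


@dataclass(frozen=True)
class VineyardParcel:
    """An elongated rectangular vineyard footprint on the grid.

    ``row``/``col`` index the top-left cell; the footprint spans ``rows`` x
    ``cols`` cells and must lie entirely on viticulture cells.
    """

    id: int
    row: int
    col: int
    rows: int
    cols: int
    area_ha: float
    orientation: str  # "horizontal" (cols > rows) or "vertical"

    @property
    def footprint(self) -> list[tuple[int, int]]:
        return [
            (r, c)
            for r in range(self.row, self.row + self.rows)
            for c in range(self.col, self.col + self.cols)
        ]

    @property
    def aspect_ratio(self) -> float:
        long, short = max(self.rows, self.cols), min(self.rows, self.cols)
        return long / short


_NEIGHBOURS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def _quotas(shares: dict[str, float], n_cells: int) -> dict[str, int]:
    """Largest-remainder apportionment of n_cells across classes."""
    raw = {c: shares.get(c, 0.0) * n_cells for c in COVER_CLASSES}
    quotas = {c: int(np.floor(v)) for c, v in raw.items()}
    remainder = n_cells - sum(quotas.values())
    by_frac = sorted(COVER_CLASSES, key=lambda c: raw[c] - quotas[c], reverse=True)
    for c in by_frac[:remainder]:
        quotas[c] += 1
    return quotas


def generate_abstract_landscape(
    shares: dict[str, float],
    dims: int | tuple[int, int] = 100,
    seed: int = 0,
    cell_size_m: float = 100.0,
) -> LandCoverGrid:
    """Generate a contiguous-blob land-cover grid matching *shares*.

    Each class receives an exact cell quota (largest-remainder rounding of
    ``share * n_cells``), so realized fractions differ from requests by less
    than one cell per class — comfortably inside the ±0.005 tolerance. Blobs
    are grown from random seed cells by competitive region growing; a class
    whose frontier is exhausted restarts from a fresh unassigned cell, so a
    class may occasionally split into a few components but never scatters.

    Deterministic in ``(shares, dims, seed)``.
    """
    if isinstance(dims, tuple):
        if dims[0] != dims[1]:
            raise LandscapeError("grid must be square")
        side = dims[0]
    else:
        side = int(dims)
    n_cells = side * side
    active = [c for c in COVER_CLASSES if shares.get(c, 0.0) > 0]
    if side < 10 and len(active) > 1:
        raise LandscapeError(f"grid side {side} too small to honour share tolerance")
    quotas = _quotas(shares, n_cells)
    rng = np.random.default_rng([int(seed), 0x1A2D])

    cells = np.full((side, side), -1, dtype=np.int16)
    deficit = {c: quotas[c] for c in COVER_CLASSES if quotas[c] > 0}
    frontiers: dict[str, list[tuple[int, int]]] = {c: [] for c in deficit}

    def claim(cls: str, cell: tuple[int, int]) -> None:
        r, c = cell
        cells[r, c] = COVER_CLASSES.index(cls)
        deficit[cls] -= 1
        for dr, dc in _NEIGHBOURS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < side and 0 <= cc < side and cells[rr, cc] == -1:
                frontiers[cls].append((rr, cc))

    # initial seeds, one per class, on distinct cells
    order = sorted(deficit, key=lambda c: -deficit[c])
    taken: set[tuple[int, int]] = set()
    for cls in order:
        while True:
            cell = (int(rng.integers(side)), int(rng.integers(side)))
            if cell not in taken:
                taken.add(cell)
                claim(cls, cell)
                break

    classes = list(order)
    while any(d > 0 for d in deficit.values()):
        # pick the class with the largest remaining deficit (stable, seeded growth)
        weights = np.array([max(deficit[c], 0) for c in classes], dtype=float)
        total = weights.sum()
        cls = classes[int(rng.choice(len(classes), p=weights / total))]
        frontier = frontiers[cls]
        cell = None
        while frontier:
            i = int(rng.integers(len(frontier)))
            frontier[i], frontier[-1] = frontier[-1], frontier[i]
            cand = frontier.pop()
            if cells[cand] == -1:
                cell = cand
                break
        if cell is None:
            # frontier exhausted: restart this class from a fresh unassigned cell
            free = np.argwhere(cells == -1)
            cell = tuple(int(v) for v in free[int(rng.integers(len(free)))])
        claim(cls, cell)

    return LandCoverGrid(cells=cells, cell_size_m=cell_size_m)


def cover_shares(grid: LandCoverGrid) -> dict[str, float]:
    """Exact realized per-class cell fractions (they sum to 1)."""
    n = grid.cells.size
    counts = np.bincount(grid.cells.ravel(), minlength=len(COVER_CLASSES))
    return {c: counts[i] / n for i, c in enumerate(COVER_CLASSES)}


def carve_parcels(
    grid: LandCoverGrid,
    n: int,
    area_dist: DistributionSpec,
    seed: int = 0,
) -> list[VineyardParcel]:
    """Place *n* disjoint elongated vineyard parcels on viticulture cells.

    Parcel areas (ha) are drawn from *area_dist*; the cell footprint is a
    1 x k rectangle with ``k = max(3, round(area_ha / cell_area_ha))`` so the
    aspect ratio is always >= 3. Placement is by seeded rejection sampling
    over viticulture cells with a deterministic exhaustive fallback.

    Raises
    ------
    LandscapeError
        Naming the achievable number of parcels when the viticulture area
        cannot host all *n*.
    """
    if n < 1:
        raise LandscapeError("n must be >= 1")
    rng = np.random.default_rng([int(seed), 0x9A8C])
    side = grid.shape[0]
    vit_idx = COVER_CLASSES.index("viticulture")
    vit_mask = grid.cells == vit_idx
    vit_cells = np.argwhere(vit_mask)
    if len(vit_cells) == 0:
        raise LandscapeError("no viticulture cells; achievable n = 0")
    occupied = np.zeros_like(vit_mask)
    cell_area_ha = (grid.cell_size_m / 100.0) ** 2  # 100 m cells -> 1 ha

    areas = area_dist.sample(rng, size=n)
    parcels: list[VineyardParcel] = []
    for pid in range(n):
        area = float(areas[pid])
        k = max(3, int(round(area / cell_area_ha)))
        placed = None
        while placed is None and k >= 3:
            placed = _place_run(rng, vit_mask, occupied, vit_cells, k)
            if placed is None:
                k -= 1  # shrink footprint rather than fail outright
        if placed is None:
            raise LandscapeError(
                f"insufficient viticulture area: achievable n = {len(parcels)} of {n}"
            )
        r, c, rows, cols = placed
        orientation = "horizontal" if cols > rows else "vertical"
        occupied[r : r + rows, c : c + cols] = True
        parcels.append(
            VineyardParcel(
                id=pid, row=r, col=c, rows=rows, cols=cols,
                area_ha=area, orientation=orientation,
            )
        )
    return parcels


def _place_run(
    rng: np.random.Generator,
    vit_mask: np.ndarray,
    occupied: np.ndarray,
    vit_cells: np.ndarray,
    k: int,
) -> tuple[int, int, int, int] | None:
    """Find a free 1 x k viticulture run; random tries then exhaustive scan."""
    side = vit_mask.shape[0]
    free = vit_mask & ~occupied

    def fits(r: int, c: int, horizontal: bool) -> bool:
        if horizontal:
            return c + k <= side and bool(free[r, c : c + k].all())
        return r + k <= side and bool(free[r : r + k, c].all())

    for _ in range(200):
        r, c = vit_cells[int(rng.integers(len(vit_cells)))]
        horizontal = bool(rng.integers(2))
        for horiz in (horizontal, not horizontal):
            if fits(int(r), int(c), horiz):
                return (int(r), int(c), 1, k) if horiz else (int(r), int(c), k, 1)
    # deterministic fallback: scan every cell in row-major order
    for r in range(side):
        for c in range(side):
            if fits(r, c, True):
                return (r, c, 1, k)
            if fits(r, c, False):
                return (r, c, k, 1)
    return None


# ---------------------------------------------------------------------------
# export / import


def save_grid(grid: LandCoverGrid, path: str | Path) -> None:
    """Write the grid as an ASCII class-code raster with a small header."""
    side = grid.shape[0]
    lines = [f"# vinesim landcover raster", f"side {side}", f"cell_size_m {grid.cell_size_m}"]
    for r in range(side):
        lines.append("".join(CLASS_CODES[COVER_CLASSES[int(i)]] for i in grid.cells[r]))
    Path(path).write_text("\n".join(lines) + "\n")


def load_grid(path: str | Path) -> LandCoverGrid:
    """Read a raster written by :func:`save_grid`."""
    lines = [ln for ln in Path(path).read_text().splitlines() if not ln.startswith("#")]
    side = int(lines[0].split()[1])
    cell_size = float(lines[1].split()[1])
    cells = np.array(
        [[COVER_CLASSES.index(CODE_CLASSES[ch]) for ch in row] for row in lines[2 : 2 + side]],
        dtype=np.int16,
    )
    return LandCoverGrid(cells=cells, cell_size_m=cell_size)


def parcels_to_frame(parcels: Iterable[VineyardParcel]) -> pd.DataFrame:
    """Tabulate parcels as (id, row, col, rows, cols, area_ha, orientation)."""
    return pd.DataFrame(
        [
            {
                "id": p.id, "row": p.row, "col": p.col, "rows": p.rows,
                "cols": p.cols, "area_ha": p.area_ha, "orientation": p.orientation,
            }
            for p in parcels
        ]
    )
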