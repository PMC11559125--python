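"""The artificial Visium-like hexagonal array over a stitched group.

After stitching, the per-area ``array_row``/``array_col`` indices no longer
describe spatial adjacency: areas were rotated and translated, and their
index ranges collide.  This module builds a fresh hexagonal lattice spanning
the whole group — spots 100 µm from each of six neighbors, exactly like a
real Visium array but larger — and assigns every transformed spot the index
of its nearest lattice point.  Spots from different areas that landed on the
same tissue location share an array position (multi-occupancy is legal and
is precisely what lets hex-grid clustering methods see across seams).

Indexing convention (matching SpaceRanger): ``array_row`` increases with
``pxl_row_in_fullres`` (vertical, downward), ``array_col`` with
``pxl_col_in_fullres``; row and column share parity; consecutive spots
within a row are two columns apart.  One column step is half a pitch in x;
one row step is pitch·√3/2 in y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SPOT_DIAMETER_UM",
    "SPOT_PITCH_UM",
    "HexLattice",
    "build_hex_lattice",
    "assign_array_coords",
    "hex_neighbors",
    "NEIGHBOR_OFFSETS",
]

#: physical diameter of a Visium spot (platform constant, µm)
SPOT_DIAMETER_UM = 55.0
#: physical center-to-center distance between neighboring spots (µm)
SPOT_PITCH_UM = 100.0

#: the six hexagonal neighbor offsets in (array_row, array_col) index space
NEIGHBOR_OFFSETS = (
    (-1, -1),
    (-1, 1),
    (0, -2),
    (0, 2),
    (1, -1),
    (1, 1),
)

_ROW_SPACING = np.sqrt(3.0) / 2.0  # row step in units of pitch


@dataclass
class HexLattice:
    """An artificial hexagonal spot array in group fullres pixel space.

    Lattice point (r, c) — defined only where r and c share parity — sits at

        x = x0 + c · pitch/2,   y = y0 + r · pitch·√3/2.
    """

    origin: tuple[float, float]
    pitch_px: float
    n_rows: int
    n_cols: int

    def point(self, row: np.ndarray | int, col: np.ndarray | int) -> np.ndarray:
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.origin[0] + col * (self.pitch_px / 2.0)
        y = self.origin[1] + row * (self.pitch_px * _ROW_SPACING)
        return np.stack(np.broadcast_arrays(x, y), axis=-1)

    def all_points(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(rows, cols, xy) for every valid (equal-parity) lattice point."""
        rows, cols = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        keep = (rows % 2) == (cols % 2)
        rows, cols = rows[keep], cols[keep]
        return rows, cols, self.point(rows, cols)


def build_hex_lattice(
    coords: np.ndarray,
    spot_diameter_fullres: float,
    spot_diameter_um: float = SPOT_DIAMETER_UM,
    pitch_um: float = SPOT_PITCH_UM,
) -> HexLattice:
    """Build the lattice covering all transformed spot coordinates.

    The pixel pitch converts the physical 100 µm spot spacing through the
    spot diameter: ``pitch_px = spot_diameter_fullres × pitch_um /
    spot_diameter_um``.  The lattice is anchored at (min x, min y) of the
    coordinates — index 0 along each axis — and extends one pitch beyond the
    bounding box.  For multi-area groups the index ranges generally exceed a
    single capture area's 77 rows and 127 columns.

    Parameters
    ----------
    coords
        n×2 array of (x, y) = (pxl_col, pxl_row) group fullres coordinates.
    spot_diameter_fullres
        Spot diameter in group fullres pixels (from the reference area).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size == 0:
        raise ValueError("cannot build a lattice over zero spots")
    if not spot_diameter_fullres > 0:
        raise ValueError("spot_diameter_fullres must be positive")
    pitch_px = spot_diameter_fullres * (pitch_um / spot_diameter_um)
    x0, y0 = coords[:, 0].min(), coords[:, 1].min()
    extent_x = coords[:, 0].max() - x0
    extent_y = coords[:, 1].max() - y0
    n_rows = int(np.ceil(extent_y / (pitch_px * _ROW_SPACING))) + 2
    n_cols = int(np.ceil(extent_x / (pitch_px / 2.0))) + 3
    return HexLattice(origin=(float(x0), float(y0)), pitch_px=pitch_px,
                      n_rows=n_rows, n_cols=n_cols)


def assign_array_coords(coords: np.ndarray, lattice: HexLattice) -> pd.DataFrame:
    """Assign each spot the indices of its Euclidean-nearest lattice point.

    Exactly equivalent to brute-force search over all lattice points; ties
    are broken by lowest row, then lowest column.  Returns a DataFrame with
    ``array_row``, ``array_col`` and ``distance_to_centroid`` (pixels), one
    row per input spot.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    pitch = lattice.pitch_px
    fx = (coords[:, 0] - lattice.origin[0]) / (pitch / 2.0)
    fy = (coords[:, 1] - lattice.origin[1]) / (pitch * _ROW_SPACING)

    # candidate rows around the fractional row index, clipped to range
    base_row = np.floor(fy).astype(int)
    cand_rows = base_row[:, None] + np.arange(-1, 3)[None, :]  # n x 4
    cand_rows = np.clip(cand_rows, 0, lattice.n_rows - 1)

    best = np.full(n, np.inf)
    best_row = np.zeros(n, dtype=int)
    best_col = np.zeros(n, dtype=int)
    for k in range(cand_rows.shape[1]):
        rows = cand_rows[:, k]
        # nearest columns of matching parity: round fx to the row's parity
        parity = rows % 2
        base = np.floor((fx - parity) / 2.0) * 2 + parity  # largest parity col <= fx
        for delta in (0.0, 2.0, -2.0, 4.0):
            cols = np.clip(base + delta, parity, lattice.n_cols - 1).astype(int)
            # clipping can break parity at the upper edge; repair downward
            bad = (cols % 2) != parity
            cols[bad] -= 1
            pts = lattice.point(rows, cols)
            d2 = np.sum((coords - pts) ** 2, axis=1)
            better = d2 < best - 1e-12
            tie = np.abs(d2 - best) <= 1e-12
            tie &= (rows < best_row) | ((rows == best_row) & (cols < best_col))
            take = better | tie
            best[take] = d2[take]
            best_row[take] = rows[take]
            best_col[take] = cols[take]
    return pd.DataFrame(
        {
            "array_row": best_row,
            "array_col": best_col,
            "distance_to_centroid": np.sqrt(best),
        }
    )


def hex_neighbors(
    assignment: pd.DataFrame, row: int, col: int
) -> tuple[list, int]:
    """Spots occupying the six hexagonal neighbor positions of (row, col).

    ``assignment`` is a table with ``array_row`` and ``array_col`` columns
    (its index provides the spot ids).  Returns ``(neighbor_spot_ids,
    n_occupied_positions)``; a position holding spots from several capture
    areas contributes all of them, so an interior spot in a doubly-occupied
    overlap has twelve unique neighbors at six unique array coordinates.
    """
    ids: list = []
    occupied = 0
    for dr, dc in NEIGHBOR_OFFSETS:
        r, c = row + dr, col + dc
        if r < 0 or c < 0:
            continue
        mask = (assignment["array_row"] == r) & (assignment["array_col"] == c)
        hits = assignment.index[mask]
        if len(hits):
            occupied += 1
            ids.extend(hits.tolist())
    return ids, occupied
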