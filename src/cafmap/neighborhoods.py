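"""Per-neighborhood phenotype composition over the raster grid.

Each grid point's neighborhood is the set of classified cells within the
closed ball of the grid radius; the composition is the per-phenotype count
vector (optionally row-normalized to fractions).  Vessel tiles, when
supplied, are counted as a pseudo-phenotype "vessel".
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from cafmap.core import PHENOTYPES, UNCLASSIFIED
from cafmap.geometry import RasterGrid, TileSet

__all__ = ["CompositionMatrix", "compute_neighborhoods", "normalize"]


@dataclass
class CompositionMatrix:
    """One row per grid point: location, per-phenotype counts, total, empty flag.

    ``normalization`` is "counts" (raw, the clustering default) or
    "fraction" (rows divided by their totals; empty rows stay zero).
    """

    table: pd.DataFrame
    phenotypes: list[str]
    radius_um: float
    grid_shape: tuple[int, int]
    normalization: str = "counts"

    def __len__(self) -> int:
        return len(self.table)

    @property
    def values(self) -> np.ndarray:
        return self.table[self.phenotypes].to_numpy(dtype=float)

    @property
    def empty_mask(self) -> np.ndarray:
        return self.table["empty"].to_numpy(dtype=bool)


def compute_neighborhoods(
    cells: pd.DataFrame,
    grid: RasterGrid,
    tiles: TileSet | None = None,
    phenotype_col: str = "phenotype",
) -> CompositionMatrix:
    """Count each phenotype within the grid radius of every grid point.

    Uses a k-d tree per phenotype with closed-ball membership
    (distance <= radius).  Unclassified cells are never counted.
    """
    if phenotype_col not in cells.columns:
        raise ValueError(
            f"cell table has no {phenotype_col!r} column; run phenotyping first"
        )
    pts = grid.points
    phenos = list(PHENOTYPES)
    counts = np.zeros((len(pts), len(phenos) + (1 if tiles is not None else 0)),
                      dtype=int)
    labels = cells[phenotype_col].to_numpy()
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    for j, p in enumerate(phenos):
        mask = labels == p
        if not mask.any():
            continue
        tree = cKDTree(xy[mask])
        counts[:, j] = tree.query_ball_point(pts, r=grid.radius_um,
                                             return_length=True)
    columns = phenos.copy()
    if tiles is not None:
        columns.append("vessel")
        if len(tiles) > 0:
            tree = cKDTree(tiles.centroids)
            counts[:, -1] = tree.query_ball_point(pts, r=grid.radius_um,
                                                  return_length=True)
    total = counts.sum(axis=1)
    table = pd.DataFrame({
        "grid_index": np.arange(len(pts)),
        "x_um": pts[:, 0],
        "y_um": pts[:, 1],
        **{c: counts[:, j] for j, c in enumerate(columns)},
        "total": total,
        "empty": total == 0,
    })
    return CompositionMatrix(
        table=table, phenotypes=columns, radius_um=grid.radius_um,
        grid_shape=grid.shape, normalization="counts",
    )


def normalize(comp: CompositionMatrix, mode: str = "fraction") -> CompositionMatrix:
    """Row-normalize counts to fractions ("fraction") or pass through ("none")."""
    if mode == "none":
        return comp
    if mode != "fraction":
        raise ValueError(f"unknown normalization mode {mode!r}")
    if comp.normalization == "fraction":
        return comp
    table = comp.table.copy()
    totals = table["total"].to_numpy(dtype=float)
    denom = np.where(totals > 0, totals, 1.0)
    for c in comp.phenotypes:
        table[c] = table[c].to_numpy(dtype=float) / denom
    return replace(comp, table=table, normalization="fraction")
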