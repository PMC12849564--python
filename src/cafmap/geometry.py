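"""Vessel tiling and the raster sampling grid.

Vessel annotations (polygons, µm) are subdivided into fixed-size square
tiles whose centroids act as proxy "cells" for distance analysis — a
stand-in for endothelial segmentation, which fails on vessel morphology.
The raster grid is the lattice of sample points at which fixed-radius
neighborhoods are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box

__all__ = ["VesselGeometry", "TileSet", "RasterGrid", "tile_vessels", "make_grid"]


@dataclass
class VesselGeometry:
    """Vessel polygons in µm, with a provenance tag."""

    polygons: list[Polygon]
    source: str = "annotation"

    def validate(self) -> None:
        for i, poly in enumerate(self.polygons):
            if poly.is_empty or poly.area <= 0:
                raise ValueError(f"vessel polygon {i} has zero area")
            if not poly.is_valid:
                raise ValueError(f"vessel polygon {i} is invalid (self-intersecting?)")


@dataclass
class TileSet:
    """Square tiles covering vessel polygons; centroids are proxy cells."""

    tile_side_um: float
    table: pd.DataFrame  # columns: polygon_id, x_um, y_um, area_um2

    def __len__(self) -> int:
        return len(self.table)

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["x_um", "y_um"]].to_numpy()

    @property
    def areas(self) -> np.ndarray:
        return self.table["area_um2"].to_numpy()


def tile_vessels(
    vessels: VesselGeometry,
    tile_side_um: float = 10.0,
    min_area_fraction: float = 0.25,
    small_tiles: str = "drop",
) -> TileSet:
    """Subdivide vessel polygons into square tiles of side ``tile_side_um``.

    The grid is aligned to absolute multiples of the tile side, so a polygon
    translated by exactly one tile side yields tiles translated by the same
    vector.  Edge tiles whose clipped area falls below
    ``min_area_fraction`` of a full tile are dropped (default) or kept.
    Centroids are centroids of the clipped shapes.
    """
    if small_tiles not in ("drop", "keep"):
        raise ValueError(f"small_tiles must be 'drop' or 'keep', got {small_tiles!r}")
    if tile_side_um <= 0:
        raise ValueError("tile_side_um must be positive")
    vessels.validate()
    side = float(tile_side_um)
    min_area = (min_area_fraction * side * side) if small_tiles == "drop" else 0.0

    records = []
    for pid, poly in enumerate(vessels.polygons):
        minx, miny, maxx, maxy = poly.bounds
        i0 = int(np.floor(minx / side))
        j0 = int(np.floor(miny / side))
        i1 = int(np.ceil(maxx / side))
        j1 = int(np.ceil(maxy / side))
        for i in range(i0, i1):
            for j in range(j0, j1):
                cell = box(i * side, j * side, (i + 1) * side, (j + 1) * side)
                clip = poly.intersection(cell)
                if clip.is_empty or clip.area <= 0:
                    continue
                if small_tiles == "drop" and clip.area < min_area:
                    continue
                c = clip.centroid
                records.append((pid, c.x, c.y, clip.area))
    table = pd.DataFrame(records, columns=["polygon_id", "x_um", "y_um", "area_um2"])
    return TileSet(tile_side_um=side, table=table)


@dataclass
class RasterGrid:
    """Axis-aligned lattice of neighborhood sample points.

    Points are ordered row-major (y outer, x inner).  ``radius_um`` is the
    neighborhood radius; membership uses the closed ball (distance <= r).
    """

    x0: float
    y0: float
    nx: int
    ny: int
    spacing_um: float
    radius_um: float

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_points(self) -> int:
        return self.nx * self.ny

    @property
    def points(self) -> np.ndarray:
        xs = self.x0 + self.spacing_um * np.arange(self.nx)
        ys = self.y0 + self.spacing_um * np.arange(self.ny)
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])


def make_grid(
    cells: pd.DataFrame, spacing_um: float = 50.0, radius_um: float = 50.0
) -> RasterGrid:
    """Lattice covering the cells' bounding box padded by the radius.

    Default spacing equals the radius, giving overlapping 50-µm
    neighborhoods on a 50-µm pitch.
    """
    if len(cells) < 1:
        raise ValueError("need at least one cell to build a grid")
    if spacing_um <= 0:
        raise ValueError("spacing_um must be positive")
    x = cells["x_um"].to_numpy(dtype=float)
    y = cells["y_um"].to_numpy(dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite cell coordinates")
    x0, x1 = x.min() - radius_um, x.max() + radius_um
    y0, y1 = y.min() - radius_um, y.max() + radius_um
    nx = int(np.floor((x1 - x0) / spacing_um + 1e-9)) + 1
    ny = int(np.floor((y1 - y0) / spacing_um + 1e-9)) + 1
    return RasterGrid(x0=x0, y0=y0, nx=nx, ny=ny,
                      spacing_um=spacing_um, radius_um=radius_um)
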