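"""Readers/writers for the cell-table dialect, GeoJSON vessels and models.

The cell table is delimited text with one row per segmented cell; a column
map adapts measurement exports from interactive pathology software (e.g.
"Centroid X µm" -> ``x_um``).  Vessel polygons travel as a GeoJSON
FeatureCollection; region models as JSON with the codebook inlined.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from cafmap.core import MARKERS, REQUIRED_COLUMNS
from cafmap.geometry import TileSet, VesselGeometry
from cafmap.neighborhoods import CompositionMatrix
from cafmap.regions import RegionModel, SOMFit
from cafmap.som import SelfOrganizingMap

__all__ = ["PipelineConfig", "read_cell_table", "write_cell_table",
           "read_vessels_geojson", "write_vessels_geojson",
           "write_composition", "read_composition",
           "write_region_model", "read_region_model"]


@dataclass
class PipelineConfig:
    """All stage parameters with their defaults.

    The defaults reproduce the published analysis settings: 50-µm
    neighborhood radius (spacing = radius), 10-µm vessel tiles, a 10%
    shared-border cutoff, and 10/100-µm distance reporting radii.
    """

    stage: str = "late"
    seed: int = 0
    density_scale: float = 1.0
    field_um: float = 3000.0
    radius_um: float = 50.0
    spacing_um: float = 50.0
    tile_side_um: float = 10.0
    som_shape: tuple[int, int] = (10, 10)
    som_epochs: int = 10000
    k_min: int = 2
    k_max: int = 15
    features: str = "hellinger"
    cutoff_pct: float = 10.0
    censor_radii_um: tuple[float, float] = (10.0, 100.0)
    calibration: str = "gmm"
    column_map: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        for key in ("som_shape", "censor_radii_um"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def read_cell_table(path: str | Path, column_map: dict | None = None,
                    sep: str = ",") -> pd.DataFrame:
    """Read and validate a delimited-text cell table (coordinates in µm).

    ``column_map`` renames source columns to the canonical dialect before
    validation.  Duplicate (sample_id, cell_id) pairs and non-numeric
    intensities are rejected with row numbers.
    """
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required columns {missing}; available: "
            f"{list(df.columns)} (pass column_map to rename)"
        )
    dup = df.duplicated(subset=["sample_id", "cell_id"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate cell ids at rows {list(df.index[dup][:10])}"
        )
    for col in ["x_um", "y_um"] + [m for m in MARKERS if m in df.columns]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            raise ValueError(
                f"{path}: non-numeric values in {col!r} at rows "
                f"{list(df.index[bad][:10])}"
            )
        df[col] = vals
    return df


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, index=False)


def write_vessels_geojson(vessels: VesselGeometry, path: str | Path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature",
             "properties": {"id": i, "source": vessels.source},
             "geometry": mapping(poly)}
            for i, poly in enumerate(vessels.polygons)
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_vessels_geojson(path: str | Path) -> VesselGeometry:
    fc = json.loads(Path(path).read_text())
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    polys, source = [], "annotation"
    for i, feat in enumerate(fc.get("features", [])):
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:
            raise ValueError(f"{path}: invalid geometry in feature {i}: {exc}")
        if geom.geom_type == "MultiPolygon":
            polys.extend(geom.geoms)
        elif geom.geom_type == "Polygon":
            polys.append(geom)
        else:
            raise ValueError(f"{path}: feature {i} is {geom.geom_type}, "
                             "expected Polygon")
        source = feat.get("properties", {}).get("source", source)
    return VesselGeometry(polygons=polys, source=source)


def write_composition(comp: CompositionMatrix, path: str | Path) -> None:
    df = comp.table.copy()
    df.attrs = {}
    header = {
        "phenotypes": comp.phenotypes, "radius_um": comp.radius_um,
        "grid_shape": list(comp.grid_shape), "normalization": comp.normalization,
    }
    path = Path(path)
    df.to_csv(path, index=False)
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(header))


def read_composition(path: str | Path) -> CompositionMatrix:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    table = pd.read_csv(path)
    return CompositionMatrix(
        table=table, phenotypes=meta["phenotypes"], radius_um=meta["radius_um"],
        grid_shape=tuple(meta["grid_shape"]), normalization=meta["normalization"],
    )


def write_region_model(model: RegionModel, path: str | Path) -> None:
    som = model.som_fit.som
    doc = {
        "codebook": som.codebook.tolist(),
        "som_shape": [som.n_rows, som.n_cols],
        "features": model.som_fit.features,
        "feature_names": model.som_fit.feature_names,
        "feature_mean": model.som_fit.feature_mean.tolist(),
        "feature_std": model.som_fit.feature_std.tolist(),
        "node_labels": model.node_labels.tolist(),
        "labels": model.labels.tolist(),
        "row_index": model.row_index.tolist(),
        "k_range": model.k_range,
        "db_scores": {str(k): v for k, v in model.db_scores.items()},
        "selected_k": model.selected_k,
        "seed": model.seed,
    }
    Path(path).write_text(json.dumps(doc))


def read_region_model(path: str | Path) -> RegionModel:
    doc = json.loads(Path(path).read_text())
    som = SelfOrganizingMap(*doc["som_shape"], seed=doc["seed"])
    som.codebook = np.asarray(doc["codebook"], dtype=float)
    som_fit = SOMFit(
        som=som, features=doc["features"], feature_names=doc["feature_names"],
        feature_mean=np.asarray(doc["feature_mean"]),
        feature_std=np.asarray(doc["feature_std"]),
    )
    return RegionModel(
        som_fit=som_fit,
        node_labels=np.asarray(doc["node_labels"], dtype=int),
        labels=np.asarray(doc["labels"], dtype=int),
        row_index=np.asarray(doc["row_index"], dtype=int),
        k_range=[int(k) for k in doc["k_range"]],
        db_scores={int(k): float(v) for k, v in doc["db_scores"].items()},
        selected_k=int(doc["selected_k"]),
        seed=int(doc["seed"]),
    )
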