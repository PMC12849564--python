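"""Tissue regions: SOM clustering of neighborhood compositions.

Neighborhood composition vectors are mapped to a feature space (default:
per-row fractions followed by a square root — the Hellinger embedding,
which stabilizes multinomial counting variance so every region contributes
comparable dispersion), quantized by a self-organizing map, and the
codebook nodes are meta-clustered by Ward linkage into k regions for every
candidate k.  The Davies-Bouldin index of the induced neighborhood
partition guides the choice of k: argmin over the candidate range, ties to
the smaller k, with the full curve retained for inspection.  Empty
neighborhoods are excluded from clustering and mapped to a background
label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from cafmap.geometry import RasterGrid
from cafmap.neighborhoods import CompositionMatrix, normalize
from cafmap.som import SelfOrganizingMap

__all__ = ["SOMFit", "RegionModel", "fit_som", "davies_bouldin",
           "cluster_regions", "region_map"]

BACKGROUND = 0
"""Raster label for empty neighborhoods."""

FEATURE_SCHEMES = ("hellinger", "zscore")


@dataclass
class SOMFit:
    """A trained SOM plus the feature mapping it was trained under."""

    som: SelfOrganizingMap
    features: str
    feature_names: list[str]
    feature_mean: np.ndarray   # identity (0/1) for the hellinger scheme
    feature_std: np.ndarray

    @property
    def codebook(self) -> np.ndarray:
        return self.som.codebook


def _featurize(comp: CompositionMatrix, features: str) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix for non-empty rows plus their grid indices."""
    if features not in FEATURE_SCHEMES:
        raise ValueError(f"features must be one of {FEATURE_SCHEMES}")
    keep = ~comp.empty_mask
    idx = comp.table["grid_index"].to_numpy()[keep]
    if features == "hellinger":
        frac = normalize(comp, "fraction")
        X = np.sqrt(frac.values[keep])
    else:
        X = comp.values[keep].astype(float)
    return X, idx


@dataclass
class RegionModel:
    """Region clustering result for one composition matrix."""

    som_fit: SOMFit
    node_labels: np.ndarray        # region of each codebook node, selected k
    labels: np.ndarray             # region (1..k) per non-empty neighborhood row
    row_index: np.ndarray          # grid_index of each labeled row
    k_range: list[int]
    db_scores: dict[int, float]    # Davies-Bouldin per candidate k
    selected_k: int
    seed: int

    @property
    def codebook(self) -> np.ndarray:
        return self.som_fit.codebook


def fit_som(
    comp: CompositionMatrix,
    som_shape: tuple[int, int] = (10, 10),
    epochs: int = 10000,
    seed: int = 0,
    features: str = "hellinger",
) -> SOMFit:
    """Train a SOM on the non-empty composition rows.

    ``epochs`` counts single-sample presentations (the online-SOM
    convention).  With the "zscore" scheme the raw composition values are
    standardized per feature and the scaling stored; the default
    "hellinger" scheme needs no data-dependent scaling.
    """
    X, _ = _featurize(comp, features)
    n_nodes = som_shape[0] * som_shape[1]
    if len(X) < n_nodes:
        raise ValueError(
            f"{len(X)} non-empty neighborhoods for {n_nodes} SOM nodes; "
            "use a smaller som_shape"
        )
    if features == "zscore":
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std > 0, std, 1.0)
    else:
        mean = np.zeros(X.shape[1])
        std = np.ones(X.shape[1])
    som = SelfOrganizingMap(som_shape[0], som_shape[1], seed=seed)
    som.fit((X - mean) / std, n_iter=epochs)
    return SOMFit(som=som, features=features, feature_names=list(comp.phenotypes),
                  feature_mean=mean, feature_std=std)


def davies_bouldin(X: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index: mean over clusters of the worst
    (sigma_i + sigma_j) / d(c_i, c_j) ratio, where sigma is the mean
    Euclidean distance to the cluster centroid.  Lower is better.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Davies-Bouldin needs at least 2 clusters")
    centroids = np.stack([X[labels == u].mean(axis=0) for u in uniq])
    sigmas = np.array([
        np.linalg.norm(X[labels == u] - c, axis=1).mean()
        for u, c in zip(uniq, centroids)
    ])
    diff = centroids[:, None, :] - centroids[None, :, :]
    M = np.sqrt((diff ** 2).sum(-1))
    off = ~np.eye(len(uniq), dtype=bool)
    if np.any(M[off] == 0) and np.all(sigmas == 0):
        raise ValueError("coincident zero-dispersion clusters: DB undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (sigmas[:, None] + sigmas[None, :]) / M
    np.fill_diagonal(R, -np.inf)
    return float(np.max(R, axis=1).mean())


def cluster_regions(
    comp: CompositionMatrix,
    k_range=range(2, 16),
    som_shape: tuple[int, int] = (10, 10),
    epochs: int = 10000,
    seed: int = 0,
    features: str = "hellinger",
    db_on: str = "neighborhoods",
) -> RegionModel:
    """Cluster neighborhoods into regions and pick k by Davies-Bouldin.

    The SOM is fitted once; for each candidate k the codebook nodes are
    merged into k meta-clusters by Ward linkage and node labels propagate
    to neighborhoods via their best-matching unit.  ``db_on`` selects
    whether the index is evaluated on the neighborhood vectors (default) or
    on the codebook nodes.
    """
    k_range = [int(k) for k in k_range]
    if not k_range:
        raise ValueError("empty k_range")
    if db_on not in ("neighborhoods", "nodes"):
        raise ValueError(f"db_on must be 'neighborhoods' or 'nodes', got {db_on!r}")
    som_fit = fit_som(comp, som_shape=som_shape, epochs=epochs, seed=seed,
                      features=features)
    X, row_index = _featurize(comp, features)
    Z = (X - som_fit.feature_mean) / som_fit.feature_std
    bmu = som_fit.som.bmu(Z)
    link = linkage(som_fit.codebook, method="ward")

    db_scores: dict[int, float] = {}
    labelings: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for k in k_range:
        node_lab = fcluster(link, t=k, criterion="maxclust")
        row_lab = node_lab[bmu]
        labelings[k] = (node_lab, row_lab)
        # meta-clusters can lose all their rows; score what is present
        if db_on == "neighborhoods":
            present = len(np.unique(row_lab))
            db_scores[k] = davies_bouldin(Z, row_lab) if present > 1 else float("inf")
        else:
            present = len(np.unique(node_lab))
            db_scores[k] = (davies_bouldin(som_fit.codebook, node_lab)
                            if present > 1 else float("inf"))

    finite = {k: v for k, v in db_scores.items() if np.isfinite(v)}
    if not finite:
        selected = min(k_range)
    else:
        best = min(finite.values())
        selected = min(k for k, v in finite.items() if v == best)
    node_labels, labels = labelings[selected]
    return RegionModel(
        som_fit=som_fit, node_labels=node_labels, labels=labels,
        row_index=row_index, k_range=k_range, db_scores=db_scores,
        selected_k=selected, seed=seed,
    )


def region_map(model: RegionModel, grid: RasterGrid) -> np.ndarray:
    """Rasterize region labels onto the grid lattice.

    Returns an (ny, nx) int array; empty neighborhoods get the background
    label 0, clustered neighborhoods their region label 1..k.
    """
    if model.row_index.max(initial=-1) >= grid.n_points:
        raise ValueError("model was not fitted on this grid (index out of range)")
    flat = np.full(grid.n_points, BACKGROUND, dtype=int)
    flat[model.row_index] = model.labels
    return flat.reshape(grid.shape)
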