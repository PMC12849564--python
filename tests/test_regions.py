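"""SOM region clustering and Davies-Bouldin model selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import davies_bouldin_score

from cafmap.geometry import RasterGrid
from cafmap.neighborhoods import CompositionMatrix
from cafmap.regions import (cluster_regions, davies_bouldin, fit_som,
                            region_map)
from cafmap.som import SelfOrganizingMap


def _comp_from_array(X, phenos=None, spacing=50.0):
    """Wrap a raw feature array as a counts CompositionMatrix."""
    n, d = X.shape
    phenos = phenos or [f"p{i}" for i in range(d)]
    table = pd.DataFrame(X, columns=phenos)
    table.insert(0, "grid_index", np.arange(n))
    table.insert(1, "x_um", (np.arange(n) % 10) * spacing)
    table.insert(2, "y_um", (np.arange(n) // 10) * spacing)
    table["total"] = X.sum(axis=1)
    table["empty"] = table["total"] == 0
    return CompositionMatrix(table=table, phenotypes=phenos, radius_um=50.0,
                             grid_shape=((n + 9) // 10, 10),
                             normalization="counts")


def test_davies_bouldin_hand_example():
    """Two unit-dispersion clusters 10 apart give exactly (1+1)/10 = 0.2."""
    X = np.array([[0.0, -1], [0.0, 1], [10.0, -1], [10.0, 1]])
    labels = np.array([0, 0, 1, 1])
    assert davies_bouldin(X, labels) == pytest.approx(0.2, abs=1e-12)


def test_davies_bouldin_duplication_invariance(rng):
    X = rng.normal(size=(60, 4))
    labels = rng.integers(0, 3, 60)
    base = davies_bouldin(X, labels)
    doubled = davies_bouldin(np.vstack([X, X]), np.concatenate([labels, labels]))
    assert doubled == pytest.approx(base, abs=1e-12)


def test_davies_bouldin_decreases_with_separation():
    rng = np.random.default_rng(0)
    blob = rng.normal(scale=0.5, size=(100, 2))
    labels = np.repeat([0, 1], 100)
    scores = [davies_bouldin(np.vstack([blob, blob + [sep, 0]]), labels)
              for sep in (3.0, 6.0, 12.0)]
    assert scores[0] > scores[1] > scores[2]


def test_davies_bouldin_matches_sklearn(rng):
    """Independent cross-check against the reference implementation."""
    for _ in range(5):
        X = rng.normal(size=(80, 5))
        labels = rng.integers(0, 4, 80)
        assert davies_bouldin(X, labels) == pytest.approx(
            davies_bouldin_score(X, labels), abs=1e-12)


def test_davies_bouldin_degenerate_inputs():
    with pytest.raises(ValueError, match="2 clusters"):
        davies_bouldin(np.zeros((5, 2)), np.zeros(5))
    X = np.zeros((4, 2))
    with pytest.raises(ValueError, match="coincident"):
        davies_bouldin(X, np.array([0, 0, 1, 1]))


def test_som_determinism_and_seed_sensitivity(rng):
    X = rng.normal(size=(300, 4))
    a = SelfOrganizingMap(4, 4, seed=3).fit(X).codebook
    b = SelfOrganizingMap(4, 4, seed=3).fit(X).codebook
    c = SelfOrganizingMap(4, 4, seed=4).fit(X).codebook
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_som_identical_rows_converge():
    X = np.tile([2.0, -1.0, 0.5], (200, 1))
    som = SelfOrganizingMap(3, 3, seed=0).fit(X, n_iter=3000)
    assert np.allclose(som.codebook, [2.0, -1.0, 0.5], atol=1e-6)


def test_som_two_masses_matches_kmeans_oracle(rng):
    """A 2x1 SOM on two distant point masses lands one node per mass."""
    from sklearn.cluster import KMeans
    a = rng.normal(loc=0.0, scale=0.1, size=(150, 2))
    b = rng.normal(loc=10.0, scale=0.1, size=(150, 2))
    X = np.vstack([a, b])
    som = SelfOrganizingMap(2, 1, sigma0=0.2, seed=0).fit(X, n_iter=6000)
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
    got = som.codebook[np.argsort(som.codebook[:, 0])]
    want = km.cluster_centers_[np.argsort(km.cluster_centers_[:, 0])]
    assert np.allclose(got, want, atol=0.3)


def test_fit_som_requires_enough_rows(rng):
    comp = _comp_from_array(rng.poisson(5.0, size=(30, 3)).astype(float))
    with pytest.raises(ValueError, match="smaller"):
        fit_som(comp, som_shape=(10, 10))


def _three_archetype_comp(seed, n_per=120, scale=40):
    """Neighborhood counts drawn from three well-separated archetypes."""
    rng = np.random.default_rng(seed)
    profiles = np.array([[0.8, 0.1, 0.05, 0.05],
                         [0.05, 0.8, 0.1, 0.05],
                         [0.05, 0.1, 0.05, 0.8]])
    rows = [rng.poisson(scale * p, size=(n_per, 4)) for p in profiles]
    X = np.vstack(rows).astype(float)
    return _comp_from_array(X), np.repeat([0, 1, 2], n_per)


def test_cluster_regions_recovers_planted_three(rng):
    """Planted k=3 selected by the Davies-Bouldin argmin in most seeds."""
    hits = 0
    for seed in range(10):
        comp, _ = _three_archetype_comp(seed)
        model = cluster_regions(comp, k_range=range(2, 7), som_shape=(6, 6),
                                epochs=4000, seed=seed)
        hits += model.selected_k == 3
    assert hits >= 9


def test_cluster_regions_forced_k(rng):
    comp, _ = _three_archetype_comp(0)
    model = cluster_regions(comp, k_range=[2], som_shape=(6, 6), seed=0)
    assert model.selected_k == 2


def test_labels_are_a_function_of_rows():
    comp, _ = _three_archetype_comp(1)
    model = cluster_regions(comp, k_range=range(2, 5), som_shape=(6, 6), seed=1)
    assert len(model.labels) == (~comp.empty_mask).sum()
    assert set(np.unique(model.labels)) <= set(range(1, 5))


def test_empty_k_range_rejected():
    comp, _ = _three_archetype_comp(2)
    with pytest.raises(ValueError, match="k_range"):
        cluster_regions(comp, k_range=[])


def test_region_map_shape_and_background():
    comp, _ = _three_archetype_comp(3)
    model = cluster_regions(comp, k_range=[3], som_shape=(6, 6), seed=3)
    grid = RasterGrid(x0=0, y0=0, nx=10, ny=36, spacing_um=50, radius_um=50)
    raster = region_map(model, grid)
    assert raster.shape == grid.shape
    assert (raster.ravel()[model.row_index] == model.labels).all()


def test_region_map_mismatched_grid_rejected():
    comp, _ = _three_archetype_comp(4)
    model = cluster_regions(comp, k_range=[3], som_shape=(6, 6), seed=4)
    small = RasterGrid(x0=0, y0=0, nx=2, ny=2, spacing_um=50, radius_um=50)
    with pytest.raises(ValueError, match="grid"):
        region_map(model, small)


def test_region_recovery_on_reference_architecture(late_sample_classified):
    """Recovered region labels agree with the planted layout (ARI >= 0.8)."""
    from sklearn.metrics import adjusted_rand_score
    from cafmap.geometry import make_grid
    from cafmap.neighborhoods import compute_neighborhoods
    cells, truth = late_sample_classified
    grid = make_grid(cells)
    comp = compute_neighborhoods(cells, grid)
    model = cluster_regions(comp, seed=11)
    pts = grid.points[model.row_index]
    planted = truth.region_labels(pts[:, 0], pts[:, 1])
    assert adjusted_rand_score(planted, model.labels) >= 0.8
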