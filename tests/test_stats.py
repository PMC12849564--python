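"""Pseudo-space ordering, nearest distances and rank-sum comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cafmap.geometry import RasterGrid, TileSet
from cafmap.neighborhoods import compute_neighborhoods, normalize
from cafmap.stats import (composition_summary, nearest_distances, pseudospace,
                          significance_stars, wilcoxon_compare)


def _comp_two_rows():
    cells = pd.DataFrame({
        "cell_id": list("abcdefghij"),
        "sample_id": "s",
        "x_um": [0.0] * 5 + [500.0] * 5,
        "y_um": 0.0,
        "phenotype": ["immune"] * 4 + ["tumor"]
                     + ["tumor"] * 4 + ["immune"],
    })
    grid = RasterGrid(x0=0, y0=0, nx=2, ny=1, spacing_um=500, radius_um=50)
    return normalize(compute_neighborhoods(cells, grid), "fraction")


def test_immune_rich_neighborhood_ordered_first():
    ps = pseudospace(_comp_two_rows())
    assert ps.curves["immune"].iloc[0] > ps.curves["immune"].iloc[-1]


def test_key_sign_reverses_permutation():
    comp = _comp_two_rows()
    fwd = pseudospace(comp, key_spec="immune-tumor")
    rev = pseudospace(comp, key_spec="tumor-immune")
    assert np.array_equal(fwd.order, rev.order[::-1])


def test_pseudospace_row_order_invariance():
    comp = _comp_two_rows()
    shuffled = comp
    shuffled.table = comp.table.iloc[::-1].reset_index(drop=True)
    curves_a = pseudospace(_comp_two_rows()).curves
    curves_b = pseudospace(shuffled).curves
    pd.testing.assert_frame_equal(curves_a, curves_b)


def test_pseudospace_requires_fractions():
    cells = pd.DataFrame({"cell_id": ["a"], "sample_id": "s", "x_um": [0.0],
                          "y_um": [0.0], "phenotype": ["tumor"]})
    grid = RasterGrid(x0=0, y0=0, nx=1, ny=1, spacing_um=50, radius_um=50)
    comp = compute_neighborhoods(cells, grid)
    with pytest.raises(ValueError, match="fraction"):
        pseudospace(comp)
    with pytest.raises(ValueError, match="key_spec"):
        pseudospace(normalize(comp, "fraction"), key_spec="foo")


def _cells_for_distance():
    return pd.DataFrame({
        "cell_id": ["src", "imm", "tum"],
        "sample_id": "s",
        "x_um": [0.0, 3.0, 30.0],
        "y_um": [0.0, 4.0, 0.0],
        "phenotype": ["vCAF1", "immune", "tumor"],
    })


def test_three_four_five_triangle():
    ds = nearest_distances(_cells_for_distance(), ["vCAF1"])
    row = ds.per_cell.iloc[0]
    assert row["distance_immune"] == pytest.approx(5.0)
    assert row["distance_tumor"] == pytest.approx(30.0)


def test_censoring_beyond_radius():
    cells = _cells_for_distance()
    cells.loc[1, ["x_um", "y_um"]] = [12.0, 0.0]
    ds = nearest_distances(cells, ["vCAF1"], censor_radius_um=10.0)
    row = ds.per_cell.iloc[0]
    assert row["censored_immune"] and not np.isnan(row["distance_immune"])
    # censored values never enter per-sample means
    assert "immune" not in set(
        ds.per_sample.query("phenotype == 'vCAF1'")["target"])


def test_distances_match_brute_force(rng):
    n = 200
    cells = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "sample_id": "s",
        "x_um": rng.uniform(0, 300, n),
        "y_um": rng.uniform(0, 300, n),
        "phenotype": rng.choice(["vCAF1", "immune", "tumor"], n),
    })
    ds = nearest_distances(cells, ["vCAF1"])
    src = cells[cells.phenotype == "vCAF1"].reset_index(drop=True)
    for target in ("immune", "tumor"):
        txy = cells.loc[cells.phenotype == target, ["x_um", "y_um"]].to_numpy()
        want = np.array([
            np.hypot(txy[:, 0] - r.x_um, txy[:, 1] - r.y_um).min()
            for r in src.itertuples()
        ])
        got = ds.per_cell[f"distance_{target}"].to_numpy()
        assert np.allclose(np.sort(got), np.sort(want))


def test_missing_target_class_censored():
    cells = _cells_for_distance()
    cells = cells[cells.phenotype != "immune"]
    ds = nearest_distances(cells, ["vCAF1"])
    assert bool(ds.per_cell["censored_immune"].iloc[0])


def test_vessel_tile_targets():
    tiles = TileSet(10.0, pd.DataFrame({
        "polygon_id": [0], "x_um": [6.0], "y_um": [8.0], "area_um2": [100.0]}))
    ds = nearest_distances(_cells_for_distance(), ["vCAF1"], tiles=tiles)
    assert ds.per_cell["distance_vessel"].iloc[0] == pytest.approx(10.0)


def test_composition_summary_simple():
    cells = pd.DataFrame({
        "cell_id": list("abcd"), "sample_id": "s", "stage": "late",
        "x_um": 0.0, "y_um": 0.0,
        "phenotype": ["tumor", "tumor", "immune", "mCAF1"],
    })
    out = composition_summary(cells).set_index("phenotype")
    assert out.loc["tumor", "percent"] == pytest.approx(50.0)
    assert out.loc["immune", "percent"] == pytest.approx(25.0)
    assert out["percent"].sum() == pytest.approx(100.0)


def test_composition_summary_excludes_unclassified():
    cells = pd.DataFrame({
        "cell_id": list("abc"), "sample_id": "s", "stage": "late",
        "x_um": 0.0, "y_um": 0.0,
        "phenotype": ["tumor", "unclassified", "unclassified"],
    })
    out = composition_summary(cells)
    assert out["percent"].iloc[0] == pytest.approx(100.0)
    none = cells.assign(phenotype="unclassified")
    assert composition_summary(none).empty


def test_wilcoxon_minimum_ranksum_exact_p():
    """{1,2,3} vs {4,5,6}: W = 6 (minimum), exact two-sided p = 0.1."""
    cmp = wilcoxon_compare([1, 2, 3], [4, 5, 6])
    assert cmp.rank_sum == pytest.approx(6.0)
    assert cmp.p_value == pytest.approx(0.1)
    assert cmp.method == "exact"


def test_wilcoxon_identical_groups_p_one():
    cmp = wilcoxon_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert cmp.p_value == pytest.approx(1.0)


def test_wilcoxon_scale_invariance():
    a, b = [1.0, 5.0, 2.0, 8.0], [3.0, 9.0, 4.0]
    c1 = wilcoxon_compare(a, b)
    c2 = wilcoxon_compare([10 * x for x in a], [10 * x for x in b])
    assert c1.rank_sum == c2.rank_sum and c1.p_value == c2.p_value


def test_wilcoxon_empty_group_rejected():
    with pytest.raises(ValueError):
        wilcoxon_compare([], [1.0])


def _exact_p_enumeration(a, b):
    """Exact two-sided p by enumerating all rank assignments."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(a)
    observed = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2
    sums = [sum(c) for c in itertools.combinations(ranks, n1)]
    extreme = sum(abs(s - mean) >= abs(observed - mean) - 1e-12 for s in sums)
    return extreme / len(sums)


@settings(max_examples=40, derandomize=True)
@given(st.integers(1, 5), st.integers(1, 5), st.integers(0, 10**6))
def test_wilcoxon_matches_enumeration(n1, n2, seed):
    rng = np.random.default_rng(seed)
    vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # untied
    a, b = vals[:n1], vals[n1:]
    cmp = wilcoxon_compare(a, b)
    assert cmp.p_value == pytest.approx(_exact_p_enumeration(a, b), abs=1e-12)


@pytest.mark.parametrize("p,stars", [
    (0.2, "ns"), (0.05, "*"), (0.02, "*"), (0.01, "**"),
    (0.0009, "***"), (0.00005, "****"),
])
def test_significance_star_bands(p, stars):
    assert significance_stars(p) == stars
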