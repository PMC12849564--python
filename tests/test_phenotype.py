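"""Threshold calibration and the hierarchical gating scheme."""

import numpy as np
import pandas as pd
import pytest

from cafmap.core import UNCLASSIFIED
from cafmap.phenotype import (calibrate_thresholds, classify_cells,
                              intensity_by_phenotype)


def _mixture_table(rng, n=600, lo_mean=1.0, hi_mean=3.0, sd=0.3):
    """Cells whose every marker is a 50/50 bimodal log-normal mixture."""
    cols = {}
    for m in ["PDGFRa", "MCAM", "aSMA", "CD31", "CD45", "PanCK"]:
        comp = rng.uniform(size=n) < 0.5
        logx = np.where(comp, rng.normal(hi_mean, sd, n),
                        rng.normal(lo_mean, sd, n))
        cols[m] = np.exp(logx)
    df = pd.DataFrame(cols)
    df["DAPI"] = np.exp(rng.normal(hi_mean, sd, n))
    df["cell_id"] = [f"c{i}" for i in range(n)]
    df["sample_id"] = "s"
    df["x_um"] = df["y_um"] = 0.0
    return df


def _grid_posterior_crossing(x, lo_mean, hi_mean, sd):
    """Equal-posterior point of the known 50/50 mixture by 1-D grid search."""
    grid = np.linspace(lo_mean, hi_mean, 20001)
    lo_pdf = np.exp(-0.5 * ((grid - lo_mean) / sd) ** 2)
    hi_pdf = np.exp(-0.5 * ((grid - hi_mean) / sd) ** 2)
    return float(np.exp(grid[np.argmin(np.abs(lo_pdf - hi_pdf))]))


def test_gmm_threshold_lands_between_modes(rng):
    df = _mixture_table(rng)
    calls = calibrate_thresholds(df, method="gmm")
    oracle = _grid_posterior_crossing(None, 1.0, 3.0, 0.3)
    for call in calls:
        # crossing of the ideal mixture is exp(2.0); estimate must sit
        # between the modes and near the oracle
        assert np.exp(1.0) < call.threshold < np.exp(3.0)
        assert abs(np.log(call.threshold) - np.log(oracle)) < 0.35


def test_threshold_determinism(rng):
    df = _mixture_table(rng)
    a = calibrate_thresholds(df)
    b = calibrate_thresholds(df)
    assert [c.threshold for c in a] == [c.threshold for c in b]


def test_constant_column_errors(rng):
    df = _mixture_table(rng)
    df["CD31"] = 5.0
    with pytest.raises(ValueError, match="CD31"):
        calibrate_thresholds(df)


def test_quantile_calibration(rng):
    df = _mixture_table(rng)
    calls = calibrate_thresholds(df, method="quantile:0.5")
    for c in calls:
        assert c.threshold == pytest.approx(float(np.median(df[c.marker])))


def test_too_few_cells_rejected(tiny_cells):
    with pytest.raises(ValueError, match="100"):
        calibrate_thresholds(tiny_cells)


THRESHOLDS = {m: 10.0 for m in ["PDGFRa", "MCAM", "aSMA", "CD31", "CD45", "PanCK"]}


def _classify(df):
    from cafmap.phenotype import MarkerCall
    calls = [MarkerCall(m, t, "fixed") for m, t in THRESHOLDS.items()]
    return classify_cells(df, calls=calls)


def test_hierarchy_assignments(tiny_cells):
    out = _classify(tiny_cells)
    expected = ["mCAF1", "mCAF2", "vCAF1", "intCAF", "immune", UNCLASSIFIED]
    assert list(out["phenotype"]) == expected


@pytest.mark.parametrize("pattern,label", [
    ({"PDGFRa", "aSMA"}, "mCAF1"),
    ({"PDGFRa"}, "mCAF2"),
    ({"MCAM", "aSMA"}, "vCAF1"),
    ({"MCAM"}, "vCAF2"),
    ({"MCAM", "PDGFRa"}, "intCAF"),
    ({"MCAM", "PDGFRa", "aSMA"}, "intCAF"),   # intermediate absorbs aSMA
    ({"CD31"}, "endothelial"),
    ({"CD45"}, "immune"),
    ({"PanCK"}, "tumor"),
    ({"aSMA"}, "myofibroblast"),
    ({"CD45", "PanCK"}, "immune"),            # sequential order: CD45 first
    ({"CD31", "CD45"}, "endothelial"),
    ({"CD31", "MCAM"}, "vCAF2"),              # CAF branch runs before CD31
    (set(), UNCLASSIFIED),
])
def test_marker_patterns(pattern, label):
    row = {m: (30.0 if m in pattern else 2.0) for m in THRESHOLDS}
    df = pd.DataFrame([row])
    df["DAPI"] = 30.0
    df["cell_id"], df["sample_id"] = "c0", "s"
    df["x_um"] = df["y_um"] = 0.0
    assert _classify(df)["phenotype"].iloc[0] == label


def test_partition_property(late_sample_classified):
    cells, _ = late_sample_classified
    counts = cells["phenotype"].value_counts()
    assert counts.sum() == len(cells)


def test_row_order_invariance(tiny_cells, rng):
    out = _classify(tiny_cells).set_index("cell_id")["phenotype"]
    shuffled = tiny_cells.sample(frac=1.0, random_state=7)
    out2 = _classify(shuffled).set_index("cell_id")["phenotype"]
    assert out.sort_index().equals(out2.sort_index())


def test_missing_marker_column_errors(tiny_cells):
    with pytest.raises(ValueError, match="missing"):
        _classify(tiny_cells.drop(columns=["CD45"]))


def test_accuracy_on_planted_intensities(late_sample_classified):
    """Planted log-normal separability must yield >= 99% gating accuracy."""
    cells, _ = late_sample_classified
    acc = (cells["phenotype"] == cells["true_phenotype"]).mean()
    assert acc >= 0.99


def test_intensity_by_phenotype_single_and_constant(tiny_cells):
    out = _classify(tiny_cells)
    tab = intensity_by_phenotype(out, "aSMA")
    row = tab[tab["phenotype"] == "mCAF1"]
    assert row["mean_intensity"].iloc[0] == pytest.approx(
        out.loc[out["phenotype"] == "mCAF1", "aSMA"].iloc[0])
    out2 = out.copy()
    out2["aSMA"] = 7.0
    tab2 = intensity_by_phenotype(out2, "aSMA")
    assert (tab2["mean_intensity"] == 7.0).all()


def test_planted_asma_ordering_recovered(late_sample_classified):
    """aSMA+ substates show higher mean aSMA than their aSMA- partners."""
    cells, _ = late_sample_classified
    tab = intensity_by_phenotype(cells, "aSMA").set_index("phenotype")
    assert tab.loc["mCAF1", "mean_intensity"] > tab.loc["mCAF2", "mean_intensity"]
    assert tab.loc["vCAF1", "mean_intensity"] > tab.loc["vCAF2", "mean_intensity"]
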