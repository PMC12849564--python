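"""Shared fixtures: small synthetic samples generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cafmap.core import MARKERS
from cafmap.phenotype import calibrate_thresholds, classify_cells
from cafmap.simulate import reference_architecture


@pytest.fixture(scope="session")
def late_sample():
    """One compact late-stage sample with ground truth (half-size field)."""
    cells, truth = reference_architecture("late", seed=11, field_um=1500.0)
    return cells, truth


@pytest.fixture(scope="session")
def late_sample_classified(late_sample):
    cells, truth = late_sample
    calls = calibrate_thresholds(cells)
    return classify_cells(cells, calls=calls), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_cells():
    """Hand-built 6-cell table with unambiguous marker patterns."""
    hi, lo = 30.0, 2.0
    rows = [
        # PDGFRa, MCAM, aSMA, CD31, CD45, PanCK -> expected phenotype
        ("c1", hi, lo, hi, lo, lo, lo),   # mCAF1
        ("c2", hi, lo, lo, lo, lo, lo),   # mCAF2
        ("c3", lo, hi, hi, lo, lo, lo),   # vCAF1
        ("c4", hi, hi, hi, lo, lo, lo),   # intCAF (double positive)
        ("c5", lo, lo, lo, lo, hi, lo),   # immune
        ("c6", lo, lo, lo, lo, lo, lo),   # unclassified
    ]
    df = pd.DataFrame(rows, columns=["cell_id", "PDGFRa", "MCAM", "aSMA",
                                     "CD31", "CD45", "PanCK"])
    df["DAPI"] = hi
    df["sample_id"] = "s1"
    df["stage"] = "late"
    df["x_um"] = np.arange(len(df)) * 10.0
    df["y_um"] = 0.0
    return df
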