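"""Hierarchical phenotype gating from marker mean intensities.

Each marker gets a binary positive/negative call from a calibrated
intensity threshold; cells are then assigned one label by a fixed
sequential hierarchy.  The two CAF lineage markers (MCAM, PDGFRa) are
evaluated jointly first: double-positives are intermediate CAFs,
single-positives enter the vCAF or mCAF branch where aSMA splits the
myofibroblastic substate 1 from the immunomodulatory substate 2.  Cells
failing the CAF branch are tested sequentially CD31 (endothelial), CD45
(immune), PanCK (tumor), then aSMA alone (myofibroblast); anything else is
unclassified and excluded from downstream analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from cafmap.core import MARKERS, PHENOTYPES, UNCLASSIFIED

__all__ = ["MarkerCall", "PhenotypeScheme", "calibrate_thresholds",
           "classify_cells", "intensity_by_phenotype"]

log = logging.getLogger(__name__)

#: markers used for gating, in the sequential order applied after the
#: joint MCAM/PDGFRa step (staining-cycle importance)
SEQUENTIAL_ORDER = ["CD31", "CD45", "PanCK", "aSMA"]
GATING_MARKERS = ["PDGFRa", "MCAM", "aSMA", "CD31", "CD45", "PanCK"]


@dataclass(frozen=True)
class MarkerCall:
    """A calibrated positivity threshold for one marker."""

    marker: str
    threshold: float
    method: str

    def __post_init__(self) -> None:
        if not (np.isfinite(self.threshold) and self.threshold > 0):
            raise ValueError(f"{self.marker}: threshold must be finite and > 0")


@dataclass(frozen=True)
class PhenotypeScheme:
    """The decision hierarchy; the default encodes the CAF-substate scheme."""

    sequential_order: tuple[str, ...] = tuple(SEQUENTIAL_ORDER)
    labels: tuple[str, ...] = tuple(PHENOTYPES)


def _gmm_threshold(log_x: np.ndarray, seed: int = 0) -> float:
    """Equal-posterior crossing of a 2-component 1-D Gaussian mixture."""
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
    gm.fit(log_x.reshape(-1, 1))
    means = gm.means_.ravel()
    lo, hi = np.sort(means)
    # posterior crossing located by bisection between the component means
    def diff(v):
        post = gm.predict_proba(np.array([[v]])).ravel()
        return post[np.argmax(means)] - post[np.argmin(means)]
    a, b = lo, hi
    fa = diff(a)
    for _ in range(80):
        m = 0.5 * (a + b)
        fm = diff(m)
        if fa * fm <= 0:
            b = m
        else:
            a, fa = m, fm
    return float(np.exp(0.5 * (a + b)))


def calibrate_thresholds(
    cells: pd.DataFrame,
    method: str = "gmm",
    markers: list[str] | None = None,
    seed: int = 0,
) -> list[MarkerCall]:
    """Per-marker positivity thresholds from the intensity distributions.

    ``method`` is "gmm" (2-component mixture on log intensity, threshold at
    the equal-posterior point) or "quantile:q" (fixed quantile of the
    intensity distribution, e.g. "quantile:0.5").  Deterministic given the
    table and method.
    """
    markers = markers if markers is not None else list(GATING_MARKERS)
    if len(cells) < 100:
        raise ValueError("need at least 100 cells to calibrate thresholds")
    calls = []
    for m in markers:
        if m not in cells.columns:
            raise ValueError(f"marker column {m!r} missing from cell table")
        x = cells[m].to_numpy(dtype=float)
        if (x <= 0).any():
            raise ValueError(f"marker {m}: intensities must be positive")
        if np.ptp(x) == 0:
            raise ValueError(f"marker {m}: constant intensity column, "
                             "cannot calibrate a threshold")
        if method == "gmm":
            thr = _gmm_threshold(np.log(x), seed=seed)
        elif method.startswith("quantile:"):
            q = float(method.split(":", 1)[1])
            if not 0 < q < 1:
                raise ValueError(f"quantile must be in (0,1), got {q}")
            thr = float(np.quantile(x, q))
        else:
            raise ValueError(f"unknown calibration method {method!r}")
        calls.append(MarkerCall(marker=m, threshold=thr, method=method))
    return calls


def classify_cells(
    cells: pd.DataFrame,
    scheme: PhenotypeScheme | None = None,
    calls: list[MarkerCall] | None = None,
) -> pd.DataFrame:
    """Assign one phenotype per cell; returns a copy with a 'phenotype' column.

    Decision order: (1) MCAM and PDGFRa jointly — double-positive ->
    intCAF; PDGFRa-only -> mCAF1/mCAF2 by aSMA; MCAM-only -> vCAF1/vCAF2 by
    aSMA; (2) remaining cells sequentially CD31 -> endothelial, CD45 ->
    immune, PanCK -> tumor, aSMA -> myofibroblast; (3) otherwise
    unclassified.  Row order never affects any label.
    """
    scheme = scheme or PhenotypeScheme()
    if calls is None:
        calls = calibrate_thresholds(cells)
    thr = {c.marker: c.threshold for c in calls}
    missing = [m for m in GATING_MARKERS if m not in cells.columns]
    if missing:
        raise ValueError(f"missing marker columns: {missing}")
    missing_thr = [m for m in GATING_MARKERS if m not in thr]
    if missing_thr:
        raise ValueError(f"no threshold calibrated for: {missing_thr}")

    pos = {m: cells[m].to_numpy(dtype=float) > thr[m] for m in GATING_MARKERS}
    n = len(cells)
    label = np.full(n, UNCLASSIFIED, dtype=object)
    undecided = np.ones(n, dtype=bool)

    both = pos["MCAM"] & pos["PDGFRa"]
    label[undecided & both] = "intCAF"
    undecided &= ~both
    m_only = pos["PDGFRa"] & ~pos["MCAM"]
    label[undecided & m_only & pos["aSMA"]] = "mCAF1"
    label[undecided & m_only & ~pos["aSMA"]] = "mCAF2"
    v_only = pos["MCAM"] & ~pos["PDGFRa"]
    label[undecided & v_only & pos["aSMA"]] = "vCAF1"
    label[undecided & v_only & ~pos["aSMA"]] = "vCAF2"
    undecided &= ~(m_only | v_only)

    seq_label = {"CD31": "endothelial", "CD45": "immune",
                 "PanCK": "tumor", "aSMA": "myofibroblast"}
    for m in scheme.sequential_order:
        hit = undecided & pos[m]
        label[hit] = seq_label[m]
        undecided &= ~hit

    out = cells.copy()
    out["phenotype"] = label.astype(str)
    return out


def intensity_by_phenotype(
    cells: pd.DataFrame, marker: str, phenotype_col: str = "phenotype"
) -> pd.DataFrame:
    """Per-sample mean marker intensity per phenotype (unclassified excluded).

    Returns a tidy table (sample_id, phenotype, mean_intensity, n_cells)
    ready for rank-sum comparisons; (sample, phenotype) pairs with no cells
    are omitted with a warning.
    """
    if phenotype_col not in cells.columns:
        raise ValueError("cell table is not phenotyped")
    if marker not in cells.columns:
        raise ValueError(f"no intensity column for marker {marker!r}")
    keep = cells[cells[phenotype_col] != UNCLASSIFIED]
    grouped = (
        keep.groupby(["sample_id", phenotype_col], observed=True)[marker]
        .agg(["mean", "size"]).reset_index()
        .rename(columns={"mean": "mean_intensity", "size": "n_cells",
                         phenotype_col: "phenotype"})
    )
    n_samples = keep["sample_id"].nunique()
    for p in PHENOTYPES:
        n_here = (grouped["phenotype"] == p).sum()
        if 0 < n_here < n_samples:
            log.warning("phenotype %s absent from %d/%d samples; rows omitted",
                        p, n_samples - n_here, n_samples)
    return grouped
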