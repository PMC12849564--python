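"""Pseudo-space ordering, nearest-distance analysis, composition summaries
and rank-sum group comparisons.

Pseudo-space sorts neighborhoods along a 1-D composition axis (default:
immune fraction minus tumor fraction, descending) and smooths per-phenotype
abundance along the ordering, visualizing how CAF substates redistribute
between the immune-rich and tumor-rich ends of the tissue.  Distance
analysis measures each source cell's Euclidean nearest-neighbor distance to
target classes (immune cells, tumor cells, vessel tiles), with optional
censoring at a reporting radius.  Group comparisons use the two-sided
Wilcoxon rank-sum test with the conventional significance-star bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu

from cafmap.core import UNCLASSIFIED
from cafmap.geometry import TileSet
from cafmap.neighborhoods import CompositionMatrix

__all__ = ["PseudospaceOrdering", "DistanceSummary", "GroupComparison",
           "pseudospace", "nearest_distances", "composition_summary",
           "wilcoxon_compare", "significance_stars"]

log = logging.getLogger(__name__)


@dataclass
class PseudospaceOrdering:
    """A 1-D ordering of neighborhoods plus smoothed abundance curves."""

    order: np.ndarray            # permutation of row positions, best-first
    key: np.ndarray              # sort key per row (original row order)
    key_spec: str
    curves: pd.DataFrame         # one row per position, one column per phenotype
    window: int


def pseudospace(
    comp: CompositionMatrix,
    key_spec: str = "immune-tumor",
    window_frac: float = 0.05,
) -> PseudospaceOrdering:
    """Order non-empty neighborhoods along a composition axis.

    ``key_spec`` is "immune-tumor" (immune fraction minus tumor fraction,
    descending: immune-rich first, tumor-rich last) or "tumor-immune" (the
    reverse sign).  Ties break by total cell count, then grid index, so the
    result is invariant to input row order.  Curves are centered moving
    averages of each phenotype's fraction, window = ``window_frac`` of the
    neighborhoods (minimum 1).
    """
    if comp.normalization != "fraction":
        raise ValueError("pseudospace expects a fraction-normalized matrix")
    table = comp.table[~comp.empty_mask].reset_index(drop=True)
    if len(table) == 0:
        raise ValueError("all neighborhoods are empty")
    sign = {"immune-tumor": 1.0, "tumor-immune": -1.0}.get(key_spec)
    if sign is None:
        raise ValueError(f"unknown key_spec {key_spec!r}")
    key = sign * (table["immune"].to_numpy() - table["tumor"].to_numpy())
    # lexsort: last key is primary; descending key, ascending tie-breakers
    order = np.lexsort((table["grid_index"].to_numpy(),
                        table["total"].to_numpy(), -key))
    window = max(1, int(round(window_frac * len(table))))
    kernel = np.ones(window) / window
    curves = {}
    for p in comp.phenotypes:
        v = table[p].to_numpy(dtype=float)[order]
        curves[p] = np.convolve(v, kernel, mode="same")
    return PseudospaceOrdering(
        order=order, key=key, key_spec=key_spec,
        curves=pd.DataFrame(curves), window=window,
    )


@dataclass
class DistanceSummary:
    """Nearest-target distances per source cell and per-sample means."""

    per_cell: pd.DataFrame       # sample_id, cell_id, phenotype, distance_<t>, censored_<t>
    per_sample: pd.DataFrame     # sample_id, phenotype, target, mean_distance_um, n
    censor_radius_um: float | None
    targets: list[str]


def nearest_distances(
    cells: pd.DataFrame,
    source_phenotypes: list[str],
    tiles: TileSet | None = None,
    target_phenotypes: dict[str, str] | None = None,
    censor_radius_um: float | None = None,
    phenotype_col: str = "phenotype",
) -> DistanceSummary:
    """Euclidean nearest-neighbor distance from each source cell to each
    target class, per sample.

    Target classes default to immune cells, tumor cells and (when a TileSet
    is given) vessel tile centroids.  Distances beyond ``censor_radius_um``
    are flagged censored (never zeroed); per-sample means are over
    uncensored values only.  A sample with no targets of a class gets
    all-censored distances and a warning.
    """
    if phenotype_col not in cells.columns:
        raise ValueError("cell table is not phenotyped")
    target_phenotypes = target_phenotypes or {"immune": "immune", "tumor": "tumor"}
    targets = list(target_phenotypes)
    if tiles is not None:
        targets.append("vessel")

    frames = []
    for sample, sub in cells.groupby("sample_id", observed=True):
        src = sub[sub[phenotype_col].isin(source_phenotypes)]
        if len(src) == 0:
            continue
        sxy = src[["x_um", "y_um"]].to_numpy(dtype=float)
        rec = {
            "sample_id": sample,
            "cell_id": src["cell_id"].to_numpy(),
            "phenotype": src[phenotype_col].to_numpy(),
        }
        for t in targets:
            if t == "vessel":
                txy = tiles.centroids
            else:
                txy = sub.loc[sub[phenotype_col] == target_phenotypes[t],
                              ["x_um", "y_um"]].to_numpy(dtype=float)
            if len(txy) == 0:
                log.warning("sample %s: no %s targets; distances censored",
                            sample, t)
                d = np.full(len(src), np.inf)
            else:
                d, _ = cKDTree(txy).query(sxy, k=1)
            censored = ~np.isfinite(d)
            if censor_radius_um is not None:
                censored |= d > censor_radius_um
            rec[f"distance_{t}"] = d
            rec[f"censored_{t}"] = censored
        frames.append(pd.DataFrame(rec))
    per_cell = (pd.concat(frames, ignore_index=True) if frames
                else pd.DataFrame(columns=["sample_id", "cell_id", "phenotype"]))

    rows = []
    for (sample, phen), sub in per_cell.groupby(["sample_id", "phenotype"],
                                                observed=True):
        for t in targets:
            ok = ~sub[f"censored_{t}"]
            if ok.any():
                rows.append((sample, phen, t,
                             float(sub.loc[ok, f"distance_{t}"].mean()),
                             int(ok.sum())))
    per_sample = pd.DataFrame(
        rows, columns=["sample_id", "phenotype", "target",
                       "mean_distance_um", "n"])
    return DistanceSummary(per_cell=per_cell, per_sample=per_sample,
                           censor_radius_um=censor_radius_um, targets=targets)


def composition_summary(cells: pd.DataFrame,
                        phenotype_col: str = "phenotype") -> pd.DataFrame:
    """Per-sample phenotype percentages among classified cells.

    Returns a tidy table (sample_id, stage, phenotype, percent, n_cells);
    unclassified cells are excluded from the denominator, and samples with
    zero classified cells are dropped with a warning.
    """
    if phenotype_col not in cells.columns:
        raise ValueError("cell table is not phenotyped")
    keep = cells[cells[phenotype_col] != UNCLASSIFIED]
    rows = []
    for sample, sub in cells.groupby("sample_id", observed=True):
        classified = sub[sub[phenotype_col] != UNCLASSIFIED]
        if len(classified) == 0:
            log.warning("sample %s has zero classified cells; excluded", sample)
            continue
        stage = sub["stage"].iloc[0] if "stage" in sub.columns else ""
        counts = classified[phenotype_col].value_counts()
        for phen, n in counts.items():
            rows.append((sample, stage, phen, 100.0 * n / len(classified), int(n)))
    return pd.DataFrame(rows, columns=["sample_id", "stage", "phenotype",
                                       "percent", "n_cells"])


def significance_stars(p: float) -> str:
    """Conventional star bands: * <=0.05, ** <=0.01, *** <=0.001, **** <=0.0001."""
    for stars, band in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p <= band:
            return stars
    return "ns"


@dataclass
class GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of two groups of sample values."""

    a: np.ndarray
    b: np.ndarray
    rank_sum: float              # rank sum of group a
    p_value: float
    stars: str
    method: str


def wilcoxon_compare(a, b) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution for small untied samples
    (n_total < 50), the tie-corrected normal approximation otherwise.  The
    reported statistic is the rank sum of group ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (not has_ties and len(a) + len(b) < 50) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    rank_sum = float(res.statistic) + len(a) * (len(a) + 1) / 2.0
    p = float(min(res.pvalue, 1.0))
    return GroupComparison(a=a, b=b, rank_sum=rank_sum, p_value=p,
                           stars=significance_stars(p), method=method)
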