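"""Region interactions: shared borders on the label raster.

A boundary edge is an 8-connected pair of lattice points with differing
non-background region labels.  The directed interaction matrix P gives, for
each region A, the percentage of A's boundary edges shared with each other
region B; thresholding max(P[A,B], P[B,A]) yields the undirected
niche-adjacency graph that chord/network plots summarize.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cafmap.regions import BACKGROUND

__all__ = ["InteractionGraph", "boundary_edges", "interaction_matrix",
           "threshold_graph", "average_over_samples"]


@dataclass
class InteractionGraph:
    """Directed shared-border percentages plus the thresholded edge set."""

    P: pd.DataFrame           # index/columns: region labels; percentages
    cutoff: float
    edges: pd.DataFrame       # regionA, regionB, pctAB, pctBA, retained


_SHIFTS_8 = [(0, 1), (1, 0), (1, 1), (1, -1)]
_SHIFTS_4 = [(0, 1), (1, 0)]


def boundary_edges(raster: np.ndarray, connectivity: int = 8) -> list[tuple]:
    """All lattice pairs with differing non-background labels.

    Returns tuples ``((i0, j0), (i1, j1), labelA, labelB)``; each unordered
    pair of lattice points appears once.  Background never contributes.
    """
    raster = np.asarray(raster)
    if raster.ndim != 2:
        raise ValueError("raster must be 2-D")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    shifts = _SHIFTS_8 if connectivity == 8 else _SHIFTS_4
    edges = []
    ny, nx = raster.shape
    for di, dj in shifts:
        a = raster[max(0, -di):ny - max(0, di), max(0, -dj):nx - max(0, dj)]
        b = raster[max(0, di):ny + min(0, di) or ny, max(0, dj):nx + min(0, dj) or nx]
        ii, jj = np.nonzero((a != b) & (a != BACKGROUND) & (b != BACKGROUND))
        i0 = ii + max(0, -di)
        j0 = jj + max(0, -dj)
        i1 = i0 + di
        j1 = j0 + dj
        for k in range(len(ii)):
            edges.append(((int(i0[k]), int(j0[k])), (int(i1[k]), int(j1[k])),
                          int(raster[i0[k], j0[k]]), int(raster[i1[k], j1[k]])))
    return edges


def interaction_matrix(edges: list[tuple], labels=None) -> pd.DataFrame:
    """Directed percentage matrix P[A, B] of A's boundary edges touching B.

    Rows for regions with zero boundary edges are all-zero (flagged via the
    ``attrs['zero_rows']`` list on the returned frame).
    """
    if labels is None:
        labels = sorted({e[2] for e in edges} | {e[3] for e in edges})
    labels = list(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=float)
    for _, _, a, b in edges:
        if a in idx and b in idx:
            counts[idx[a], idx[b]] += 1
            counts[idx[b], idx[a]] += 1
    totals = counts.sum(axis=1)
    P = np.zeros_like(counts)
    nz = totals > 0
    P[nz] = 100.0 * counts[nz] / totals[nz, None]
    out = pd.DataFrame(P, index=labels, columns=labels)
    out.attrs["zero_rows"] = [lab for lab, t in zip(labels, totals) if t == 0]
    return out


def threshold_graph(P: pd.DataFrame, cutoff: float = 10.0) -> InteractionGraph:
    """Retain undirected edges {A, B} with max(P[A,B], P[B,A]) >= cutoff."""
    if not 0 < cutoff <= 100:
        raise ValueError(f"cutoff must be in (0, 100], got {cutoff}")
    labels = list(P.index)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            pab, pba = float(P.loc[a, b]), float(P.loc[b, a])
            rows.append((a, b, pab, pba, max(pab, pba) >= cutoff))
    edges = pd.DataFrame(rows, columns=["regionA", "regionB", "pctAB", "pctBA",
                                        "retained"])
    return InteractionGraph(P=P, cutoff=cutoff, edges=edges)


def average_over_samples(matrices: list[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise mean of per-sample interaction matrices.

    Matrices are aligned on the union of their labels; regions absent from
    a sample contribute flagged zero rows, and the flags propagate to the
    result's ``attrs['zero_rows']`` (region, sample-count) pairs.
    """
    if not matrices:
        raise ValueError("no matrices to average")
    labels = sorted(set().union(*[set(m.index) for m in matrices]))
    acc = np.zeros((len(labels), len(labels)))
    flags: dict = {}
    for m in matrices:
        aligned = m.reindex(index=labels, columns=labels, fill_value=0.0)
        acc += aligned.to_numpy()
        zero = set(m.attrs.get("zero_rows", [])) | (set(labels) - set(m.index))
        for lab in zero:
            flags[lab] = flags.get(lab, 0) + 1
    out = pd.DataFrame(acc / len(matrices), index=labels, columns=labels)
    out.attrs["zero_rows"] = sorted(flags.items())
    return out
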