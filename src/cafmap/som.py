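"""A compact online self-organizing map (Kohonen network).

Rectangular node lattice, Gaussian neighborhood function, linearly decaying
learning rate and neighborhood radius.  One training iteration presents a
single randomly drawn sample (the convention of the common SOM libraries),
so ``n_iter`` counts sample presentations, not full passes.  Training is
fully deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SelfOrganizingMap"]


class SelfOrganizingMap:
    """Online SOM on an ``n_rows x n_cols`` rectangular lattice.

    Parameters
    ----------
    n_rows, n_cols
        Lattice dimensions; the codebook has ``n_rows * n_cols`` nodes.
    sigma0
        Initial Gaussian neighborhood radius in lattice units; defaults to
        half the larger lattice dimension.  Decays linearly to 0.5.
    learning_rate
        Initial step size; decays linearly to 0.01.
    seed
        Seeds codebook initialization and the sample presentation order.
    """

    def __init__(self, n_rows: int, n_cols: int, sigma0: float | None = None,
                 learning_rate: float = 0.5, seed: int = 0):
        if n_rows < 1 or n_cols < 1:
            raise ValueError("lattice dimensions must be >= 1")
        self.n_rows = n_rows
        self.n_cols = n_cols
        self.sigma0 = sigma0 if sigma0 is not None else max(n_rows, n_cols) / 2.0
        self.learning_rate = learning_rate
        self.seed = seed
        rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
        self._grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        # pairwise squared lattice distances, (nodes, nodes)
        d = self._grid[:, None, :] - self._grid[None, :, :]
        self._grid_d2 = (d ** 2).sum(-1)
        self.codebook: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.n_rows * self.n_cols

    def fit(self, X: np.ndarray, n_iter: int = 2000) -> "SelfOrganizingMap":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) == 0:
            raise ValueError("X must be a non-empty 2-D array")
        rng = np.random.default_rng(self.seed)
        init_idx = rng.choice(len(X), size=self.n_nodes, replace=len(X) < self.n_nodes)
        codebook = X[init_idx].copy()
        sigma_end, lr_end = min(0.5, self.sigma0), 0.01
        order = rng.integers(0, len(X), size=n_iter)
        for t in range(n_iter):
            frac = t / max(n_iter - 1, 1)
            sigma = self.sigma0 + (sigma_end - self.sigma0) * frac
            lr = self.learning_rate + (lr_end - self.learning_rate) * frac
            x = X[order[t]]
            bmu = int(np.argmin(((codebook - x) ** 2).sum(axis=1)))
            h = np.exp(-self._grid_d2[bmu] / (2.0 * sigma * sigma))
            codebook += (lr * h)[:, None] * (x - codebook)
        self.codebook = codebook
        return self

    def bmu(self, X: np.ndarray) -> np.ndarray:
        """Best-matching unit index for each row of X."""
        if self.codebook is None:
            raise RuntimeError("SOM is not fitted")
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.codebook[None, :, :]) ** 2).sum(-1)
        return np.argmin(d2, axis=1)

    def quantization_error(self, X: np.ndarray) -> float:
        idx = self.bmu(X)
        return float(np.linalg.norm(X - self.codebook[idx], axis=1).mean())
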