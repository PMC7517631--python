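"""Hexagonal batch self-organizing map for condition-trajectory clustering.

A :class:`HexSOM` arranges ``rows x cols`` codebook vectors on an offset
hexagonal lattice and trains them in batch mode: every epoch each input row
is assigned to its best-matching unit (BMU, nearest codebook vector in
Euclidean distance) and each codebook vector moves to the neighborhood-
weighted mean of all rows, with Gaussian lattice weights
``exp(-d^2 / (2 sigma^2))``.  The neighborhood radius decays linearly over
an ordering phase, holds during a tuning phase, and a final sigma = 0 polish
performs plain k-means (Lloyd) updates.  With all radii at zero the whole
procedure IS Lloyd's algorithm, which anchors the tests.

Grid nodes are the "modules" of the downstream trajectory selection: module
ids run row-major from 1 (bottom-left) to rows*cols (top-right).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted


def hex_grid(rows: int, cols: int) -> tuple[np.ndarray, list[list[int]]]:
    """Cartesian coordinates and neighbor lists of an offset hexagonal lattice.

    Row 0 is the bottom row; odd rows are shifted right by half a cell.
    Returns ``(coords, neighbors)`` where ``coords`` is (rows*cols, 2) in
    row-major order and ``neighbors[k]`` lists the lattice indices at unit
    distance from node ``k`` (interior nodes have exactly 6).
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    rr, cc = np.divmod(np.arange(rows * cols), cols)
    coords = np.column_stack([cc + 0.5 * (rr % 2), rr * (np.sqrt(3.0) / 2.0)])
    dist = cdist(coords, coords)
    adjacency = (dist > 0) & (dist < 1.0 + 1e-9)
    neighbors = [list(np.flatnonzero(adjacency[k])) for k in range(rows * cols)]
    return coords, neighbors


@dataclass
class UMatrix:
    """Distances between lattice-adjacent codebook vectors.

    ``pair_values`` maps each adjacent 0-based index pair (i < j) to the
    Euclidean distance between their codebooks; ``module_values[k]`` is the
    mean distance from node k to its lattice neighbors.
    """

    pair_values: dict[tuple[int, int], float]
    module_values: np.ndarray


class HexSOM(ClusterMixin, BaseEstimator):
    """Batch self-organizing map on a hexagonal grid.

    Parameters
    ----------
    rows, cols : int, default 7
        Lattice shape; 7 x 7 gives the 49 modules used throughout.
    epochs_ordering : int, default 100
        Epochs over which the neighborhood radius decays linearly from
        ``radius_start`` to ``radius_end``.
    epochs_tuning : int, default 50
        Epochs at the constant final radius.
    epochs_polish : int, default 0
        Final epochs at radius 0 (hard k-means updates).  Off by default:
        the residual neighborhood keeps each data cluster's codebooks close
        to the cluster centre, which stabilizes the module means the
        downstream selection rules test; a polish sharpens Voronoi borders
        at the cost of spreading codebooks into cluster tails.
    radius_start, radius_end : float, defaults 3.0 and 2.0
        Gaussian neighborhood radii in lattice units.
    init : {"pca", "sample"}, default "pca"
        ``"pca"`` spreads the initial codebook linearly over the plane of
        the top two principal components (deterministic, like the classical
        linear SOM initialization); ``"sample"`` draws data rows without
        replacement.
    random_state : int or None
        Seed for the ``"sample"`` initialization; ``"pca"`` is seed-free.

    Attributes
    ----------
    codebook_ : ndarray of shape (rows*cols, n_features)
    grid_coords_ : ndarray of shape (rows*cols, 2)
    neighbors_ : list of neighbor index lists
    labels_ : ndarray, 0-based BMU index of each training row
    quantization_errors_ : list of per-epoch mean BMU distances
    quantization_error_ : float, final mean BMU distance
    """

    def __init__(
        self,
        rows: int = 7,
        cols: int = 7,
        epochs_ordering: int = 100,
        epochs_tuning: int = 50,
        epochs_polish: int = 0,
        radius_start: float = 3.0,
        radius_end: float = 2.0,
        init: str = "pca",
        random_state: int | None = None,
    ):
        self.rows = rows
        self.cols = cols
        self.epochs_ordering = epochs_ordering
        self.epochs_tuning = epochs_tuning
        self.epochs_polish = epochs_polish
        self.radius_start = radius_start
        self.radius_end = radius_end
        self.init = init
        self.random_state = random_state

    @property
    def n_modules(self) -> int:
        return self.rows * self.cols

    def _init_codebook(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.init == "pca":
            codebook = self._pca_init(X)
            if codebook is not None:
                return codebook
        elif self.init != "sample":
            raise ValueError(f"unknown init {self.init!r}; use 'pca' or 'sample'")
        return self._sample_init(X, rng)

    def _pca_init(self, X: np.ndarray) -> np.ndarray | None:
        """Spread the lattice linearly over the top-2 principal plane (+-2 sd).

        Returns None (fallback to sampling) when the data are degenerate:
        fewer than 2 rows or no variance.
        """
        if X.shape[0] < 2:
            return None
        center = X.mean(axis=0)
        _, svals, vt = np.linalg.svd(X - center, full_matrices=False)
        sd = svals / np.sqrt(X.shape[0])
        if sd[0] <= 0:
            return None
        rr, cc = np.divmod(np.arange(self.n_modules), self.cols)
        u = 2.0 * cc / (self.cols - 1) - 1.0 if self.cols > 1 else np.zeros(self.n_modules)
        v = 2.0 * rr / (self.rows - 1) - 1.0 if self.rows > 1 else np.zeros(self.n_modules)
        codebook = center + np.outer(u * 2.0 * sd[0], vt[0])
        if len(sd) > 1 and sd[1] > 0:
            codebook = codebook + np.outer(v * 2.0 * sd[1], vt[1])
        return codebook

    def _sample_init(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Sample data rows without replacement; jitter around the mean when short."""
        n, k = X.shape[0], self.n_modules
        if n >= k:
            idx = rng.choice(n, size=k, replace=False)
            return X[idx].astype(float).copy()
        codebook = np.empty((k, X.shape[1]))
        codebook[:n] = X
        center = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        codebook[n:] = center + 0.01 * scale * rng.standard_normal((k - n, X.shape[1]))
        return codebook

    def _sigma_schedule(self) -> np.ndarray:
        if self.radius_start < self.radius_end or self.radius_end < 0:
            raise ValueError("need radius_start >= radius_end >= 0")
        ordering = np.linspace(self.radius_start, self.radius_end, self.epochs_ordering)
        tuning = np.full(self.epochs_tuning, float(self.radius_end))
        polish = np.zeros(self.epochs_polish)
        return np.concatenate([ordering, tuning, polish])

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=1)
        if self.n_modules < 1:
            raise ValueError("grid must contain at least one module")
        rng = np.random.default_rng(self.random_state)
        self.grid_coords_, self.neighbors_ = hex_grid(self.rows, self.cols)
        lattice_d2 = cdist(self.grid_coords_, self.grid_coords_) ** 2
        codebook = self._init_codebook(X, rng)
        k = self.n_modules
        self.quantization_errors_ = []
        for sigma in self._sigma_schedule():
            dist = cdist(X, codebook)
            bmu = dist.argmin(axis=1)  # argmin ties -> lowest module index
            self.quantization_errors_.append(float(dist[np.arange(len(X)), bmu].mean()))
            sums = np.zeros_like(codebook)
            np.add.at(sums, bmu, X)
            counts = np.bincount(bmu, minlength=k).astype(float)
            if sigma > 0:
                h = np.exp(-lattice_d2 / (2.0 * sigma * sigma))
            else:
                h = np.eye(k)
            numer = h @ sums
            denom = h @ counts
            updatable = denom > 0
            codebook[updatable] = numer[updatable] / denom[updatable, None]
        self.codebook_ = codebook
        final_dist = cdist(X, codebook)
        self.labels_ = final_dist.argmin(axis=1)
        self.quantization_error_ = float(
            final_dist[np.arange(len(X)), self.labels_].mean()
        )
        self.n_iter_ = len(self.quantization_errors_)
        return self

    def predict(self, X) -> np.ndarray:
        """0-based BMU index per row (ties broken toward the lowest index)."""
        check_is_fitted(self, "codebook_")
        X = check_array(X, dtype=float)
        return cdist(X, self.codebook_).argmin(axis=1)

    def transform(self, X) -> np.ndarray:
        """Distances from each row to every codebook vector."""
        check_is_fitted(self, "codebook_")
        X = check_array(X, dtype=float)
        return cdist(X, self.codebook_)

    def quantization_error(self, X) -> float:
        """Mean Euclidean distance of rows to their BMU codebook."""
        return float(self.transform(X).min(axis=1).mean())

    def module_sizes(self, X) -> np.ndarray:
        return np.bincount(self.predict(X), minlength=self.n_modules)

    def u_matrix(self) -> UMatrix:
        return compute_umatrix(self)


def assign_modules(model: HexSOM, X, feature_ids: list[str]) -> dict[str, int]:
    """Map each feature id to its 1-based module id (row-major from bottom-left)."""
    labels = model.predict(X)
    if len(labels) != len(feature_ids):
        raise ValueError("feature_ids length does not match data rows")
    return {fid: int(lab) + 1 for fid, lab in zip(feature_ids, labels)}


def compute_umatrix(model: HexSOM) -> UMatrix:
    """Codebook distances between lattice-adjacent modules."""
    check_is_fitted(model, "codebook_")
    pair_values: dict[tuple[int, int], float] = {}
    k = model.n_modules
    module_values = np.zeros(k)
    for i in range(k):
        dists = []
        for j in model.neighbors_[i]:
            d = float(np.linalg.norm(model.codebook_[i] - model.codebook_[j]))
            dists.append(d)
            if i < j:
                pair_values[(i, j)] = d
        module_values[i] = float(np.mean(dists)) if dists else 0.0
    return UMatrix(pair_values=pair_values, module_values=module_values)
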