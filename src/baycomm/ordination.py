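"""Dissimilarity matrices, nonmetric multidimensional scaling, centroids.

Compositional dissimilarity between presence/absence samples uses the
Jaccard index, d = 1 - |A ∩ B| / |A ∪ B| over species presence sets.
NMDS embeds a dissimilarity matrix in k dimensions by minimizing Kruskal's
stress-1 with a monotone (isotonic) regression of configuration distances
on the input dissimilarities, iterated via the Guttman transform (SMACOF
with nonmetric disparities). Multiple restarts guard against local minima;
the first restart starts from classical (metric) scaling, later ones from
classical scaling plus random jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_random_state

from .data_model import CommunityMatrix

__all__ = [
    "jaccard_matrix",
    "euclidean_matrix",
    "NMDS",
    "nmds",
    "Ordination",
    "centroid_distance",
]


def jaccard_matrix(matrix: CommunityMatrix, on_empty_union: str = "error") -> DistanceMatrix:
    """Pairwise Jaccard dissimilarities of a binary community matrix.

    Parameters
    ----------
    matrix:
        Binary samples x species matrix.
    on_empty_union:
        What to do for a pair of samples with no species in either:
        ``"error"`` (default) or ``"zero"`` (define d = 0).
    """
    if on_empty_union not in ("error", "zero"):
        raise ValueError("on_empty_union must be 'error' or 'zero'")
    X = matrix.values().astype(bool)
    rich = X.sum(axis=1)
    if on_empty_union == "error" and (rich == 0).sum() >= 2:
        empty = [matrix.sample_ids[i] for i in np.flatnonzero(rich == 0)]
        raise ValueError(
            f"samples with empty species sets form pairs with empty union: {empty[:5]}; "
            "pass on_empty_union='zero' to define their dissimilarity as 0"
        )
    inter = (X.astype(np.int32) @ X.astype(np.int32).T).astype(float)
    union = rich[:, None] + rich[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    d[union == 0] = 0.0  # empty-union pairs (only reachable with on_empty_union='zero')
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=matrix.sample_ids)


def euclidean_matrix(env_matrix: pd.DataFrame, standardize: bool = True) -> DistanceMatrix:
    """Pairwise Euclidean distances, optionally after per-variable
    standardization (centering and unit-variance scaling)."""
    X = env_matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values in matrix")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            const = [env_matrix.columns[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant column(s) cannot be standardized: {const}")
        X = (X - X.mean(axis=0)) / sd
    d = squareform(pdist(X, metric="euclidean"))
    return DistanceMatrix(d, ids=[str(i) for i in env_matrix.index])


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson classical scaling: principal coordinates of -0.5 J d^2 J."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(vals)


def _stress1(config_d: np.ndarray, disparities: np.ndarray) -> float:
    denom = (config_d**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((config_d - disparities) ** 2).sum() / denom))


class NMDS(BaseEstimator):
    """Nonmetric multidimensional scaling of a dissimilarity matrix.

    Minimizes Kruskal's stress-1,
    ``sqrt(sum((d_ij - dhat_ij)^2) / sum(d_ij^2))``,
    where ``d_ij`` are configuration distances and ``dhat_ij`` the
    disparities obtained by isotonic regression of configuration distances
    on the input dissimilarities (ties averaged). The best of
    ``n_restarts`` initializations is kept.

    Parameters
    ----------
    n_components:
        Embedding dimensionality k.
    n_restarts:
        Number of initializations; the first is classical scaling of the
        input, the rest add random jitter to it.
    max_iter, tol:
        Per-restart iteration cap and relative stress-change convergence
        tolerance.
    random_state:
        Seed for the jittered restarts.

    Attributes
    ----------
    embedding_ : ndarray of shape (n_samples, n_components)
        Coordinates, centered at the origin.
    stress_ : float
        Kruskal stress-1 of the returned configuration.
    converged_ : bool
        Whether the best restart met the tolerance within ``max_iter``.
    """

    def __init__(
        self,
        n_components: int = 3,
        n_restarts: int = 20,
        max_iter: int = 500,
        tol: float = 1e-6,
        random_state=None,
    ):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit the embedding. X is a skbio DistanceMatrix or square array."""
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if isinstance(X, DistanceMatrix):
            d = X.data.astype(float)
            self.ids_ = list(X.ids)
        else:
            d = np.asarray(X, dtype=float)
            if d.ndim != 2 or d.shape[0] != d.shape[1]:
                raise ValueError("expected a square dissimilarity matrix")
            if not np.allclose(d, d.T):
                raise ValueError("dissimilarity matrix must be symmetric")
            self.ids_ = [str(i) for i in range(d.shape[0])]
        n = d.shape[0]
        iu = np.triu_indices(n, 1)
        diss = d[iu]
        # tie blocks of the sorted dissimilarities, precomputed once: the
        # isotonic fit averages configuration distances within each block
        order = np.argsort(diss, kind="stable")
        sorted_diss = diss[order]
        starts = np.r_[0, np.flatnonzero(np.diff(sorted_diss)) + 1]
        sizes = np.diff(np.r_[starts, len(sorted_diss)]).astype(float)
        rng = check_random_state(self.random_state)
        base = _classical_scaling(d, self.n_components)
        scale = max(base.std(), 1e-6)

        best = None
        for r in range(self.n_restarts):
            coords = base.copy()
            if r > 0:
                coords = coords + rng.normal(scale=0.25 * scale, size=coords.shape)
            coords, stress, converged = self._smacof(coords, order, starts, sizes)
            if best is None or stress < best[1]:
                best = (coords, stress, converged)
        coords, stress, converged = best
        coords = coords - coords.mean(axis=0)
        # deterministic scale convention: configuration distances match the
        # input dissimilarities in total squared magnitude (stress-1 is
        # scale-invariant, but centroid distances are not)
        cd = pdist(coords)
        ssd = (cd**2).sum()
        if ssd > 0:
            coords = coords * np.sqrt((diss**2).sum() / ssd)
        self.embedding_ = coords
        self.stress_ = stress
        self.converged_ = converged
        self.n_restarts_ = self.n_restarts
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_

    def _smacof(self, coords, order, starts, sizes):
        n = coords.shape[0]
        last_stress = np.inf
        converged = False
        stress = np.inf
        disparities = np.empty(len(order))
        for _ in range(self.max_iter):
            cd_flat = pdist(coords)
            # monotone regression of configuration distances on the input
            # dissimilarities: pool-adjacent-violators over tie-block means
            block_means = np.add.reduceat(cd_flat[order], starts.astype(int)) / sizes
            fitted = isotonic_regression(block_means, weights=sizes, increasing=True).x
            disparities[order] = np.repeat(fitted, sizes.astype(int))
            # rescale disparities to the configuration's overall size so the
            # Guttman step is well-conditioned
            denom = (disparities**2).sum()
            if denom > 0:
                disparities = disparities * np.sqrt((cd_flat**2).sum() / denom)
            stress = _stress1(cd_flat, disparities)
            if last_stress - stress < self.tol * max(last_stress, 1e-12):
                converged = True
                break
            last_stress = stress
            # Guttman transform
            dm = squareform(cd_flat)
            ratio = np.zeros_like(dm)
            nz = dm > 0
            dispm = squareform(disparities)
            ratio[nz] = dispm[nz] / dm[nz]
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            coords = b @ coords / n
        return coords, stress, converged


@dataclass
class Ordination:
    """NMDS result: coordinates with sample ids, stress and diagnostics."""

    coordinates: pd.DataFrame
    stress: float
    k: int
    converged: bool
    n_restarts: int


def nmds(
    distance_matrix: DistanceMatrix,
    k: int = 3,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
) -> Ordination:
    """Functional wrapper over the :class:`NMDS` estimator."""
    est = NMDS(n_components=k, n_restarts=n_restarts, max_iter=max_iter, tol=tol, random_state=seed)
    est.fit(distance_matrix)
    coords = pd.DataFrame(
        est.embedding_, index=est.ids_, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return Ordination(
        coordinates=coords,
        stress=est.stress_,
        k=k,
        converged=est.converged_,
        n_restarts=n_restarts,
    )


def centroid_distance(
    ordination: Ordination,
    sample_groups: pd.Series,
    group_a,
    group_b,
    dims: int | None = None,
) -> float:
    """Euclidean distance between two groups' centroid coordinates.

    ``sample_groups`` maps sample id -> group label; ``dims`` restricts to
    the first so-many ordination axes (default: all).
    """
    coords = ordination.coordinates
    dims = ordination.k if dims is None else dims
    groups = sample_groups.reindex(coords.index)
    a = coords.loc[groups == group_a].iloc[:, :dims]
    b = coords.loc[groups == group_b].iloc[:, :dims]
    if a.empty or b.empty:
        raise ValueError(f"empty group: {group_a if a.empty else group_b}")
    return float(np.linalg.norm(a.mean(axis=0).to_numpy() - b.mean(axis=0).to_numpy()))
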