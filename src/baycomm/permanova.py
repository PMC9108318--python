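"""Permutational multivariate ANOVA (PERMANOVA) on a distance matrix.

The total sum of squares of a distance matrix D is partitioned among model
terms via the Gower-centered inner-product matrix

    G = -1/2 · C D∘D C,   C = I - 11'/n,

whose trace equals the total SS. For an ordered sequence of model terms,
sequential (Type I) sums of squares are tr((H_j - H_{j-1}) G) where H_j is
the orthogonal projector onto the column space of the model matrix through
term j. Pseudo-F for each term uses the residual from the full model, and
p-values come from free permutation of sample labels (rows/columns of D).

This supports crossed factors, continuous covariates and interaction
terms, which one-way implementations do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from ._design import build_design

__all__ = ["DesignSpec", "PermanovaResult", "permanova"]


@dataclass
class DesignSpec:
    """Ordered model terms plus per-sample predictor values.

    Term order matters: sums of squares are sequential. ``data`` must be
    indexed/ordered consistently with the distance matrix ids.
    """

    terms: list[str]
    data: pd.DataFrame
    n_permutations: int = 999
    seed: int | None = None


@dataclass
class PermanovaResult:
    """ANOVA-style table of the distance partitioning.

    ``table`` has one row per term plus Residual and Total, with columns
    df, sum_sq, pseudo_F, R2, p_value.
    """

    table: pd.DataFrame
    n_permutations: int
    total_ss: float = field(init=False)

    def __post_init__(self):
        self.total_ss = float(self.table.loc["Total", "sum_sq"])

    def __str__(self) -> str:  # pragma: no cover
        return self.table.to_string(float_format=lambda v: f"{v:.4g}")


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d**2
    return a - a.mean(axis=0, keepdims=True) - a.mean(axis=1, keepdims=True) + a.mean()


def _projector(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    q = q[:, keep]
    return q @ q.T


def permanova(
    distance_matrix: DistanceMatrix | np.ndarray,
    design: DesignSpec,
) -> PermanovaResult:
    """Sequential PERMANOVA of ``distance_matrix`` on ``design``.

    The permutation p-value for each term is
    ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)`` under free
    permutation of sample labels.
    """
    if isinstance(distance_matrix, DistanceMatrix):
        d = distance_matrix.data.astype(float)
    else:
        d = np.asarray(distance_matrix, dtype=float)
    n = d.shape[0]
    if len(design.data) != n:
        raise ValueError("design rows do not align with the distance matrix")
    if design.n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    X, names, counts = build_design(design.data, design.terms)
    g = _gower_center(d)

    # sequential projectors; rank bookkeeping detects aliased terms
    h_prev = _projector(X[:, :1])
    rank_prev = 1
    term_projectors = []
    dfs = []
    col = 1
    for term, k in zip(design.terms, counts):
        col += k
        x_cum = X[:, :col]
        rank = np.linalg.matrix_rank(x_cum)
        df = rank - rank_prev
        if df < k:
            raise ValueError(f"model is rank deficient: term '{term}' is aliased with earlier terms")
        h = _projector(x_cum)
        term_projectors.append(h - h_prev)
        dfs.append(df)
        h_prev, rank_prev = h, rank
    resid_projector = np.eye(n) - h_prev
    df_res = n - rank_prev
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def partition(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.array([np.sum(p * gmat) for p in term_projectors])
        ss_res = float(np.sum(resid_projector * gmat))
        return ss_terms, ss_res

    ss_terms, ss_res = partition(g)
    ss_total = float(np.trace(g))
    dfs_arr = np.array(dfs, dtype=float)
    f_obs = (ss_terms / dfs_arr) / (ss_res / df_res)

    rng = np.random.default_rng(design.seed)
    exceed = np.zeros(len(design.terms))
    for _ in range(design.n_permutations):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_res_p = partition(gp)
        f_p = (ss_p / dfs_arr) / (ss_res_p / df_res)
        exceed += f_p >= f_obs
    p_values = (1.0 + exceed) / (1.0 + design.n_permutations)

    rows = []
    for term, df, ss, f, p in zip(design.terms, dfs, ss_terms, f_obs, p_values):
        rows.append((term, df, ss, f, ss / ss_total, p))
    rows.append(("Residual", df_res, ss_res, np.nan, ss_res / ss_total, np.nan))
    rows.append(("Total", n - 1, ss_total, np.nan, 1.0, np.nan))
    table = pd.DataFrame(
        rows, columns=["term", "df", "sum_sq", "pseudo_F", "R2", "p_value"]
    ).set_index("term")
    return PermanovaResult(table=table, n_permutations=design.n_permutations)
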