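"""Fixed-fixed swap randomization and pairwise null-quantile statistics.

The null model randomizes species occurrences within each month's
sample x species submatrix while holding each sample's richness (row sums)
and each species' occurrence total (column sums) fixed. Randomization uses
checkerboard trial swaps: pick two samples and two species at random; if
the 2x2 submatrix is a checkerboard ([[1,0],[0,1]] or [[0,1],[1,0]]), flip
it. A single sequential chain per month is burned in and thinned to yield
the null draws.

For every unordered pair of same-month samples, the observed Jaccard
dissimilarity is located within its null distribution as a mid-rank
quantile. Quantiles near 0 mean the pair is compositionally more similar
than expected after removing sampling effects of alpha and gamma
diversity; near 1, more dissimilar. The season contrast compares hypoxia
vs normoxia pair quantiles by a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CommunityMatrix
from .environment import SeasonLabeling

logger = logging.getLogger(__name__)

__all__ = [
    "NullModelConfig",
    "SeasonComparison",
    "swap_randomize",
    "pairwise_null_quantiles",
    "compare_quantiles_by_season",
]


@dataclass(frozen=True)
class NullModelConfig:
    """Tuning of the per-month swap chain and quantile bounds.

    ``burn_in_swaps``/``swaps_between_draws`` default to 10x and 1x the
    number of presences in the month's submatrix when left as None.
    """

    n_null: int = 999
    burn_in_swaps: int | None = None
    swaps_between_draws: int | None = None
    seed: int = 0
    min_samples_per_month: int = 3
    quantile_bounds: tuple[float, float] = (0.10, 0.90)

    def __post_init__(self):
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        lo, hi = self.quantile_bounds
        if not 0 <= lo < hi <= 1:
            raise ValueError("quantile_bounds must be ordered within [0, 1]")


def _trial_swaps(rows: list[list[int]], r1, r2, c1, c2) -> None:
    """Apply checkerboard trial swaps in place on a list-of-lists matrix."""
    for i1, i2, j1, j2 in zip(r1.tolist(), r2.tolist(), c1.tolist(), c2.tolist()):
        row1 = rows[i1]
        a = row1[j1]
        b = row1[j2]
        if a != b:
            row2 = rows[i2]
            if row2[j2] == a and row2[j1] == b:
                row1[j1] = b
                row1[j2] = a
                row2[j1] = a
                row2[j2] = b


def _random_pairs(rng: np.random.Generator, n: int, size: int) -> tuple[np.ndarray, np.ndarray]:
    first = rng.integers(0, n, size)
    second = (first + 1 + rng.integers(0, n - 1, size)) % n
    return first, second


def swap_randomize(matrix: np.ndarray, n_swaps: int, rng: np.random.Generator) -> np.ndarray:
    """Return a copy of a binary matrix after ``n_swaps`` trial swaps.

    Row and column sums are preserved exactly; matrices with no
    checkerboard 2x2 submatrix (e.g. perfectly nested ones) pass through
    unchanged.
    """
    m = np.asarray(matrix)
    if m.ndim != 2:
        raise ValueError("expected a 2-d binary matrix")
    if m.size and not np.isin(m, (0, 1)).all():
        raise ValueError("matrix entries must be 0 or 1")
    n_rows, n_cols = m.shape
    if n_rows < 2 or n_cols < 2 or n_swaps < 1:
        return m.copy()
    rows = [list(map(int, r)) for r in m]
    r1, r2 = _random_pairs(rng, n_rows, n_swaps)
    c1, c2 = _random_pairs(rng, n_cols, n_swaps)
    _trial_swaps(rows, r1, r2, c1, c2)
    return np.array(rows, dtype=m.dtype)


def _pairwise_jaccard(m: np.ndarray, iu: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Condensed Jaccard dissimilarities for the given upper-triangle index.

    Pairs with an empty union get d = 0 (both samples empty; row sums are
    fixed across null draws so this affects observed and null identically).
    """
    mi = m.astype(np.int32)
    inter = mi @ mi.T
    rich = mi.sum(axis=1)
    union = rich[:, None] + rich[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return d[iu]


@dataclass
class NullModelResult:
    """Per-pair observed Jaccard and its null-quantile position.

    ``pairs`` columns: month, sample_a, sample_b, observed_jaccard,
    quantile (mid-rank position of the observed value in the null
    distribution), null_q_low, null_q_high, within_bounds.
    """

    pairs: pd.DataFrame
    config: NullModelConfig
    skipped_months: list[int] = field(default_factory=list)


def pairwise_null_quantiles(
    matrix: CommunityMatrix,
    seasons: SeasonLabeling,
    config: NullModelConfig = NullModelConfig(),
) -> NullModelResult:
    """Null-quantile statistics for every unordered same-month sample pair.

    Randomization runs separately for each month (the unit sharing a
    regional species pool); months with fewer than
    ``config.min_samples_per_month`` samples are skipped. The quantile is
    ``(#null < obs + 0.5 * #null == obs) / n_null``.
    """
    records = []
    skipped = []
    months = sorted(matrix.metadata["month"].unique())
    for month in months:
        ids = matrix.metadata.index[matrix.metadata["month"] == month]
        if len(ids) < config.min_samples_per_month:
            logger.info("month %d skipped: %d sample(s) below minimum %d",
                        month, len(ids), config.min_samples_per_month)
            skipped.append(int(month))
            continue
        sub = matrix.occupancy.loc[ids].to_numpy()
        n = sub.shape[0]
        iu = np.triu_indices(n, 1)
        observed = _pairwise_jaccard(sub, iu)

        fill = int(sub.sum())
        burn = config.burn_in_swaps if config.burn_in_swaps is not None else 10 * fill
        thin = config.swaps_between_draws if config.swaps_between_draws is not None else max(fill, 1)
        rng = np.random.default_rng([config.seed, int(month)])

        null = np.empty((config.n_null, len(observed)))
        if fill == 0 or n < 2 or sub.shape[1] < 2:
            null[:] = observed  # degenerate month: chain cannot move
        else:
            total = burn + config.n_null * thin
            r1, r2 = _random_pairs(rng, n, total)
            c1, c2 = _random_pairs(rng, sub.shape[1], total)
            state = [list(map(int, r)) for r in sub]
            _trial_swaps(state, r1[:burn], r2[:burn], c1[:burn], c2[:burn])
            pos = burn
            for k in range(config.n_null):
                _trial_swaps(
                    state, r1[pos:pos + thin], r2[pos:pos + thin],
                    c1[pos:pos + thin], c2[pos:pos + thin],
                )
                pos += thin
                null[k] = _pairwise_jaccard(np.asarray(state), iu)

        less = (null < observed).sum(axis=0)
        equal = (null == observed).sum(axis=0)
        quantile = (less + 0.5 * equal) / config.n_null
        lo, hi = config.quantile_bounds
        q_low = np.quantile(null, lo, axis=0)
        q_high = np.quantile(null, hi, axis=0)
        within = (observed >= q_low) & (observed <= q_high)
        null_sd = null.std(axis=0, ddof=1) if config.n_null > 1 else np.zeros_like(observed)
        with np.errstate(invalid="ignore", divide="ignore"):
            ses = np.where(null_sd > 0, (observed - null.mean(axis=0)) / null_sd, 0.0)

        ia, ib = iu
        id_arr = np.asarray(ids)
        records.append(pd.DataFrame({
            "month": int(month),
            "sample_a": id_arr[ia],
            "sample_b": id_arr[ib],
            "observed_jaccard": observed,
            "quantile": quantile,
            "null_q_low": q_low,
            "null_q_high": q_high,
            "within_bounds": within,
            "ses": ses,  # standardized effect size, a convenience output
        }))
    if not records:
        raise ValueError("no month passed the sample-size minimum")
    pairs = pd.concat(records, ignore_index=True)
    return NullModelResult(pairs=pairs, config=config, skipped_months=skipped)


@dataclass
class SeasonComparison:
    """Rank-sum comparison of pair null quantiles between seasons."""

    quantiles_hypoxia: np.ndarray
    quantiles_normoxia: np.ndarray
    rank_sum_statistic: float
    p_value: float
    method: str

    @property
    def n_pairs_hypoxia(self) -> int:
        return len(self.quantiles_hypoxia)

    @property
    def n_pairs_normoxia(self) -> int:
        return len(self.quantiles_normoxia)


def compare_quantiles_by_season(
    result: NullModelResult | pd.DataFrame,
    seasons: SeasonLabeling,
) -> SeasonComparison:
    """Two-sided Wilcoxon rank-sum test of hypoxia vs normoxia quantiles.

    Uses exact enumeration when both groups have at most 12 pairs and no
    ties span the groups; otherwise the tie-corrected normal approximation
    with continuity correction.
    """
    pairs = result.pairs if isinstance(result, NullModelResult) else result
    season_of = pairs["month"].map(seasons.labels)
    x = pairs.loc[season_of == "hypoxia", "quantile"].to_numpy()
    y = pairs.loc[season_of == "normoxia", "quantile"].to_numpy()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("a season has no sample pairs")
    exact_ok = len(x) <= 12 and len(y) <= 12 and len(np.unique(np.r_[x, y])) == len(x) + len(y)
    method = "exact" if exact_ok else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return SeasonComparison(
        quantiles_hypoxia=x,
        quantiles_normoxia=y,
        rank_sum_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=method,
    )
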