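import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from baycomm.data_model import CommunityMatrix
from baycomm.environment import SeasonLabeling
from baycomm.nullmodel import (
    NullModelConfig,
    compare_quantiles_by_season,
    pairwise_null_quantiles,
    swap_randomize,
)
from conftest import (
    STUDY_MONTHLY_SIZES,
    metadata_with_monthly_sizes,
    random_community,
    study_season_labeling,
)


class TestSwapRandomize:
    @given(arrays(np.int8, (6, 8), elements=st.integers(0, 1)), st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_margins_preserved(self, m, seed):
        out = swap_randomize(m, 200, np.random.default_rng(seed))
        np.testing.assert_array_equal(out.sum(axis=0), m.sum(axis=0))
        np.testing.assert_array_equal(out.sum(axis=1), m.sum(axis=1))
        assert np.isin(out, (0, 1)).all()

    def test_checkerboard_flips_to_other_checkerboard(self):
        m = np.array([[1, 0], [0, 1]], dtype=np.int8)
        # enough trials that at least one valid swap happens
        out = swap_randomize(m, 50, np.random.default_rng(0))
        assert out.tolist() in ([[1, 0], [0, 1]], [[0, 1], [1, 0]])
        # find a seed where it flipped (chain is irreducible on 2 states)
        flipped = any(
            swap_randomize(m, 1, np.random.default_rng(s)).tolist() == [[0, 1], [1, 0]]
            for s in range(50)
        )
        assert flipped

    def test_nested_matrix_is_invariant(self):
        """A perfectly nested matrix contains no checkerboard, so no trial
        swap can ever succeed."""
        m = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]], dtype=np.int8)
        out = swap_randomize(m, 10_000, np.random.default_rng(1))
        np.testing.assert_array_equal(out, m)

    def test_chain_visits_multiple_configurations(self):
        m = np.eye(4, dtype=np.int8)
        rng = np.random.default_rng(2)
        seen = set()
        state = m
        for _ in range(60):
            state = swap_randomize(state, 5, rng)
            seen.add(state.tobytes())
        assert len(seen) > 1

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            swap_randomize(np.array([[2, 0], [0, 1]]), 5, np.random.default_rng(0))


def community_with_months(sizes=STUDY_MONTHLY_SIZES, n_species=40, seed=0):
    meta = metadata_with_monthly_sizes(sizes)
    return random_community(meta, n_species, seed, occupancy=0.2)


class TestPairwiseNullQuantiles:
    def test_study_month_sizes_give_printed_pair_counts(self):
        """Monthly sample sizes 23..22 with June-September hypoxia and the
        n=2 month skipped enumerate 743 + 1451 = 2194 same-month pairs."""
        matrix = community_with_months()
        seasons = study_season_labeling()
        res = pairwise_null_quantiles(
            matrix, seasons, NullModelConfig(n_null=1, seed=0)
        )
        season_of = res.pairs["month"].map(seasons.labels)
        assert (season_of == "hypoxia").sum() == 743
        assert (season_of == "normoxia").sum() == 1451
        assert len(res.pairs) == 2194
        assert res.skipped_months == [10]

    def test_degenerate_chain_gives_midrank_half(self):
        """When every null draw equals the observed value (no checkerboard
        exists), the mid-rank quantile is exactly 0.5."""
        meta = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "site_id": ["s1", "s2", "s3"],
                "month": 1,
                "layer": "surface",
                "site_depth": 10.0,
            }
        )
        occ = pd.DataFrame(
            [[1, 1, 1], [1, 1, 0], [1, 0, 0]],
            index=pd.Index(meta["sample_id"], name="sample_id"),
            columns=["x", "y", "z"],
        )
        matrix = CommunityMatrix(occ, meta.set_index("sample_id"))
        seasons = SeasonLabeling(labels={1: "normoxia"}, threshold=2.0)
        res = pairwise_null_quantiles(matrix, seasons, NullModelConfig(n_null=49, seed=0))
        assert (res.pairs["quantile"] == 0.5).all()

    def test_quantiles_uniform_under_self_null(self):
        """Data generated by the null itself (a swap-randomized matrix) have
        approximately uniform quantiles and ~80% coverage of the 10-90% band."""
        rng = np.random.default_rng(5)
        meta = metadata_with_monthly_sizes((21, 21) + (0,) * 10)
        matrix = random_community(meta, 60, seed=5, occupancy=0.2)
        # replace the observation with a draw from the null ensemble
        shuffled = matrix.occupancy.copy()
        for month in (1, 2):
            ids = matrix.metadata.index[matrix.metadata["month"] == month]
            sub = matrix.occupancy.loc[ids].to_numpy()
            shuffled.loc[ids] = swap_randomize(sub, 20 * int(sub.sum()), rng)
        matrix = CommunityMatrix(shuffled, matrix.metadata)
        seasons = SeasonLabeling(labels={1: "normoxia", 2: "hypoxia"}, threshold=2.0)
        res = pairwise_null_quantiles(matrix, seasons, NullModelConfig(n_null=199, seed=6))
        assert len(res.pairs) == 2 * 210
        assert res.pairs["quantile"].mean() == pytest.approx(0.5, abs=0.05)
        # ties at the band endpoints inflate inclusive coverage above 80%,
        # so check the calibrated one-sided exceedances instead
        assert 0.78 <= res.pairs["within_bounds"].mean() <= 0.97
        assert (res.pairs["observed_jaccard"] < res.pairs["null_q_low"]).mean() <= 0.13
        assert (res.pairs["observed_jaccard"] > res.pairs["null_q_high"]).mean() <= 0.13

    def test_month_below_minimum_is_skipped(self):
        matrix = community_with_months((5, 2) + (0,) * 10)
        seasons = SeasonLabeling(labels={1: "normoxia", 2: "normoxia"}, threshold=2.0)
        res = pairwise_null_quantiles(matrix, seasons, NullModelConfig(n_null=9, seed=0))
        assert res.skipped_months == [2]
        assert set(res.pairs["month"]) == {1}


class TestSeasonComparison:
    def make_result(self, hyp_values, norm_values):
        pairs = pd.DataFrame(
            {
                "month": [6] * len(hyp_values) + [1] * len(norm_values),
                "sample_a": "a",
                "sample_b": "b",
                "observed_jaccard": 0.5,
                "quantile": list(hyp_values) + list(norm_values),
                "within_bounds": True,
            }
        )
        return pairs

    def seasons(self):
        return SeasonLabeling(labels={1: "normoxia", 6: "hypoxia"}, threshold=2.0)

    def test_identical_samples_p_one(self):
        pairs = self.make_result([0.2, 0.4, 0.6], [0.2, 0.4, 0.6])
        cmp_ = compare_quantiles_by_season(pairs, self.seasons())
        assert cmp_.p_value == pytest.approx(1.0)

    def test_exact_enumeration_most_extreme(self):
        """{1,2,3} vs {4,5,6}: the most extreme of C(6,3)=20 rank splits in
        either direction gives two-sided p = 2/20 = 0.1."""
        pairs = self.make_result([1, 2, 3], [4, 5, 6])
        cmp_ = compare_quantiles_by_season(pairs, self.seasons())
        assert cmp_.method == "exact"
        assert cmp_.p_value == pytest.approx(0.1)

    def test_large_shift_detected_and_statistic_matches_brute_force(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.3, 0.1, 200)
        y = rng.normal(0.6, 0.1, 300)
        pairs = self.make_result(x, y)
        cmp_ = compare_quantiles_by_season(pairs, self.seasons())
        assert cmp_.p_value < 1e-3
        # brute-force U statistic by explicit ranking
        pooled = np.r_[x, y]
        ranks = stats.rankdata(pooled)
        u_x = ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2
        assert cmp_.rank_sum_statistic == pytest.approx(u_x)

    def test_invariant_to_pair_ordering(self):
        rng = np.random.default_rng(1)
        pairs = self.make_result(rng.random(30), rng.random(40))
        shuffled = pairs.sample(frac=1.0, random_state=2).reset_index(drop=True)
        a = compare_quantiles_by_season(pairs, self.seasons())
        b = compare_quantiles_by_season(shuffled, self.seasons())
        assert a.p_value == pytest.approx(b.p_value)
        assert a.rank_sum_statistic == pytest.approx(b.rank_sum_statistic)

    def test_season_without_pairs_raises(self):
        pairs = self.make_result([], [0.1, 0.2])
        with pytest.raises(ValueError, match="season"):
            compare_quantiles_by_season(pairs, self.seasons())
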