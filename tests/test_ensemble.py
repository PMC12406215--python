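"""Predictor correlation, clustering, and quadratic-mean p-value merging."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from hrsig import cluster_predictors, correlate_nonconformity, ensemble_decide, merge_pvalues
from hrsig.ensemble import MergedScore, arithmetic_mean_merge, merge_pvalues_matrix


class TestCorrelateNonconformity:
    def test_identical_columns_correlate_perfectly(self, rng):
        x = rng.uniform(size=50)
        C = correlate_nonconformity(np.column_stack([x, x]))
        assert C[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_negated_column_anticorrelates(self, rng):
        x = rng.uniform(size=50)
        C = correlate_nonconformity(np.column_stack([x, -x]))
        assert C[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_naive_covariance_loop(self, rng):
        S = rng.uniform(size=(50, 4))
        C = correlate_nonconformity(S)
        for i in range(4):
            for j in range(4):
                a, b = S[:, i], S[:, j]
                expected = np.mean((a - a.mean()) * (b - b.mean())) / (a.std() * b.std())
                assert C[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_column_zeroed_with_warning(self, rng):
        S = np.column_stack([rng.uniform(size=10), np.full(10, 0.5)])
        with pytest.warns(UserWarning, match="constant"):
            C = correlate_nonconformity(S)
        assert C[0, 1] == 0.0 and C[1, 1] == 1.0

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError, match="3 individuals"):
            correlate_nonconformity(np.ones((2, 3)))


class TestClusterPredictors:
    def test_recovers_two_perfect_blocks(self):
        C = np.eye(6)
        C[:3, :3] = 1.0
        C[3:, 3:] = 1.0
        assert cluster_predictors(C, 2) == [[0, 1, 2], [3, 4, 5]]

    def test_k_equals_n_gives_singletons(self, rng):
        C = correlate_nonconformity(rng.uniform(size=(20, 5)))
        assert cluster_predictors(C, 5) == [[i] for i in range(5)]

    def test_recovers_three_noisy_planted_blocks(self, rng):
        """Within-block r >= 0.8, between <= 0.1 -> planted partition (ARI=1)."""
        truth = np.repeat([0, 1, 2], 2)
        shared = rng.normal(size=(200, 3))
        S = shared[:, truth] * 0.95 + 0.3 * rng.normal(size=(200, 6))
        C = correlate_nonconformity(S)
        assert (C[np.eye(6) == 0].max() < 1.0) and C[0, 1] > 0.8
        groups = cluster_predictors(C, 3)
        labels = np.empty(6, int)
        for g, members in enumerate(groups):
            labels[members] = g
        assert adjusted_rand_score(truth, labels) == 1.0

    @pytest.mark.parametrize("k", [0, 7])
    def test_invalid_k_rejected(self, k):
        with pytest.raises(ValueError, match="k"):
            cluster_predictors(np.eye(6), k)

    def test_asymmetric_matrix_rejected(self):
        C = np.eye(3)
        C[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            cluster_predictors(C, 2)


class TestMergePvalues:
    def test_all_ones_capped_at_one(self):
        assert merge_pvalues([1.0, 1.0, 1.0]).p_merged == 1.0

    def test_closed_form_on_equal_inputs(self):
        # sqrt(3) * 0.1 for any number of copies of 0.1
        for k in (1, 2, 5):
            assert merge_pvalues([0.1] * k).p_merged == pytest.approx(
                np.sqrt(3) * 0.1, abs=1e-12
            )

    def test_singleton_merge_is_inflated_not_identity(self):
        assert merge_pvalues([0.1]).p_merged == pytest.approx(np.sqrt(3) * 0.1)

    def test_agrees_with_arithmetic_mean_variant_on_equal_inputs(self):
        """On equal inputs RMS = mean, so the rules differ only in the factor."""
        q = merge_pvalues([0.2, 0.2]).p_merged
        a = arithmetic_mean_merge([0.2, 0.2])
        assert q == pytest.approx(np.sqrt(3) * 0.2) and a == pytest.approx(0.4)

    @pytest.mark.parametrize("bad", [[], [-0.1], [1.2], [np.nan]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            merge_pvalues(bad)

    @given(
        p=st.lists(st.floats(0, 1), min_size=1, max_size=8),
        idx=st.integers(0, 7),
        delta=st.floats(0, 1),
    )
    def test_monotone_in_each_input(self, p, idx, delta):
        idx = idx % len(p)
        raised = list(p)
        raised[idx] = min(1.0, raised[idx] + delta)
        assert merge_pvalues(raised).p_merged >= merge_pvalues(p).p_merged - 1e-12

    @given(p=st.lists(st.floats(0, 1), min_size=2, max_size=8), seed=st.integers(0, 100))
    def test_permutation_invariant(self, p, seed):
        perm = np.random.default_rng(seed).permutation(len(p))
        assert merge_pvalues(list(np.asarray(p)[perm])).p_merged == pytest.approx(
            merge_pvalues(p).p_merged
        )

    def test_monte_carlo_validity_independent_and_dependent(self):
        """P(p_merged <= alpha) <= alpha under both dependence extremes."""
        rng = np.random.default_rng(123)
        reps, K = 20000, 9
        u_ind = rng.uniform(size=(reps, K))
        merged_ind = merge_pvalues_matrix(u_ind)
        u_dep = np.repeat(rng.uniform(size=(reps, 1)), K, axis=1)
        merged_dep = merge_pvalues_matrix(u_dep)
        for alpha in (0.01, 0.05, 0.2):
            se = np.sqrt(alpha * (1 - alpha) / reps)
            assert (merged_ind <= alpha).mean() <= alpha + 3 * se
            assert (merged_dep <= alpha).mean() <= alpha + 3 * se


class TestEnsembleDecide:
    def test_clear_case_flags(self):
        asd = MergedScore(0.5, [1, 2])
        ntc = MergedScore(0.1, [1, 2])
        assert ensemble_decide(asd, ntc, 0.2) == "ASD"

    def test_both_rejected_abstains(self):
        assert ensemble_decide(MergedScore(0.15, [1]), MergedScore(0.1, [1]), 0.2) == "abstain"

    def test_member_mismatch_rejected(self):
        with pytest.raises(ValueError, match="member"):
            ensemble_decide(MergedScore(0.5, [1]), MergedScore(0.1, [2]))

    def test_singleton_group_equals_member_decision_at_adjusted_threshold(self):
        """A single-network group decides like the network itself at alpha=0.2,
        up to the sqrt(3) inflation of its scores."""
        from hrsig import decide

        p_asd, p_ntc = 0.5, 0.05
        merged = ensemble_decide(
            merge_pvalues([p_asd]), merge_pvalues([p_ntc]), 0.2
        )
        direct = decide(min(1, np.sqrt(3) * p_asd), min(1, np.sqrt(3) * p_ntc), 0.2)
        assert merged == direct == "ASD"
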