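"""Filter selectors: univariate ranking, correlation clustering, the five
base rankers, and majority-vote hybrid selection."""

import numpy as np
import pytest

from blendeeg import FeatureMatrix, base_selector_rank, fcct_select, hfs_mvs_select, univariate_rank
from blendeeg.filter_selection import BASE_SELECTOR_METHODS, FeatureMask
from conftest import benchmark_matrix


def fm(X, y):
    X = np.asarray(X, dtype=float)
    return FeatureMatrix(
        X=X, y=np.asarray(y, dtype=int),
        feature_names=[f"f{i}" for i in range(X.shape[1])],
        subject_ids=np.array([f"s{i}" for i in range(len(y))], dtype=object),
    )


class TestUnivariateRank:
    def test_f_statistic_closed_form(self):
        """Two groups [1,2,3] vs [7,8,9]: SSB/df1 / (SSW/df2) = 54."""
        F = fm(np.array([[1], [2], [3], [7], [8], [9]]), [0, 0, 0, 1, 1, 1])
        ranked, _ = univariate_rank(F, "f_test")
        assert np.isclose(ranked.scores[0], 54.0, atol=1e-10)

    def test_f_test_matches_brute_force_anova(self):
        """Closed-form one-way ANOVA on random small inputs, 1e-10."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 6))
        y = np.array([0, 1, 2] * 10)
        ranked, _ = univariate_rank(fm(X, y), "f_test")
        for j in range(6):
            groups = [X[y == c, j] for c in (0, 1, 2)]
            grand = X[:, j].mean()
            ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
            ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
            f_expect = (ssb / 2) / (ssw / (30 - 3))
            assert np.isclose(ranked.scores[j], f_expect, atol=1e-10)

    def test_pcc_feature_equal_to_label(self):
        y = np.array([0, 1, 2] * 5)
        X = np.column_stack([y.astype(float), np.random.default_rng(1).standard_normal(15)])
        ranked, _ = univariate_rank(fm(X, y), "pcc")
        assert np.isclose(ranked.scores[0], 1.0)
        assert ranked.order[0] == 0

    def test_mi_independent_feature_near_zero(self):
        rng = np.random.default_rng(2)
        y = np.array([0, 1, 2] * 334)[:1000]
        X = rng.standard_normal((1000, 1))
        ranked, _ = univariate_rank(fm(X, y), "mi")
        assert ranked.scores[0] < 0.02  # nats

    def test_constant_feature_scores_zero(self):
        y = np.array([0, 1] * 10)
        X = np.column_stack([np.ones(20), y.astype(float)])
        for method in ("f_test", "pcc", "mi"):
            ranked, _ = univariate_rank(fm(X, y), method)
            assert ranked.scores[0] == 0.0

    def test_top_k_mask_and_bad_k(self):
        F, _ = benchmark_matrix(n_samples=60, n_features=10, seed=1)
        ranked, mask = univariate_rank(F, "f_test", k=3)
        assert mask.selected_count == 3
        assert set(mask.indices) == set(ranked.order[:3])
        with pytest.raises(ValueError):
            ranked.top_k(0)

    def test_tie_break_ascending_index(self):
        X = np.column_stack([np.ones(10), np.ones(10), np.arange(10.0)])
        y = np.array([0, 1] * 5)
        ranked, _ = univariate_rank(fm(X, y), "f_test")
        tied = [i for i in ranked.order if ranked.scores[i] == 0.0]
        assert tied == sorted(tied)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 6))
        y = np.array([0, 1, 2, 0] * 10)
        perm = rng.permutation(6)
        r1, _ = univariate_rank(fm(X, y), "f_test")
        r2, _ = univariate_rank(fm(X[:, perm], y), "f_test")
        assert np.allclose(r2.scores, r1.scores[perm])


class TestFCCT:
    def test_duplicate_feature_deduplicated(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(60)
        X = np.column_stack([x, x, rng.standard_normal(60)])
        y = np.array([0, 1, 2] * 20)
        mask = fcct_select(fm(X, y), corr_threshold=0.5)
        assert mask.bits[0] + mask.bits[1] == 1
        assert mask.bits[2] == 1

    def test_planted_blocks_one_representative_each(self):
        """Three blocks of near-duplicate features collapse to exactly 3."""
        rng = np.random.default_rng(5)
        y = np.array([0, 1, 2] * 30)
        base = rng.standard_normal((90, 3))
        cols = []
        for b in range(3):
            for _ in range(4):
                cols.append(base[:, b] + rng.normal(0, 0.01, 90))
        X = np.column_stack(cols)
        mask = fcct_select(fm(X, y), corr_threshold=0.5)
        assert mask.selected_count == 3
        # exactly one per block
        for b in range(3):
            assert mask.bits[4 * b : 4 * b + 4].sum() == 1

    def test_retained_features_below_cut_on_block_data(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(6)
        y = np.array([0, 1, 2] * 20)
        base = rng.standard_normal((60, 4))
        X = np.column_stack([base[:, b // 3] + rng.normal(0, 0.01, 60) for b in range(12)])
        threshold = 0.5
        mask = fcct_select(fm(X, y), corr_threshold=threshold)
        kept = mask.indices
        rho = np.abs(spearmanr(X[:, kept]).statistic)
        rho = np.atleast_2d(rho)
        np.fill_diagonal(rho, 0.0)
        assert rho.max() < 1.0 - threshold + 1e-9

    def test_tiny_threshold_keeps_all(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((50, 8))
        y = np.array([0, 1] * 25)
        mask = fcct_select(fm(X, y), corr_threshold=0.01)
        assert mask.selected_count == 8

    def test_threshold_out_of_range(self):
        F, _ = benchmark_matrix(n_samples=30, n_features=4, n_informative=2, seed=0)
        for t in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                fcct_select(F, corr_threshold=t)


class TestBaseSelectors:
    def test_relieff_hand_traced_points(self):
        """Four 1-D points in two tight pairs: the informative coordinate
        gets positive weight, a constant feature gets zero."""
        X = np.column_stack([[0.0, 0.1, 1.0, 1.1], np.ones(4)])
        y = np.array([0, 0, 1, 1])
        ranked = base_selector_rank(fm(X, y), "relieff")
        assert ranked.scores[0] > 0
        assert ranked.scores[1] == 0.0
        assert ranked.order[0] == 0

    def test_cfs_top_ranks_label_feature(self):
        rng = np.random.default_rng(8)
        y = np.array([0, 1, 2] * 20)
        X = np.column_stack([y.astype(float), rng.standard_normal((60, 5))])
        ranked = base_selector_rank(fm(X, y), "cfs")
        assert ranked.order[0] == 0

    def test_single_class_rejected(self):
        X = np.random.default_rng(9).standard_normal((10, 3))
        with pytest.raises(ValueError):
            base_selector_rank(fm(X, np.zeros(10)), "cfs")

    def test_unknown_method_rejected(self):
        F, _ = benchmark_matrix(n_samples=30, n_features=4, n_informative=2, seed=0)
        with pytest.raises(ValueError):
            base_selector_rank(F, "chi2")

    @pytest.mark.parametrize("method", BASE_SELECTOR_METHODS)
    def test_informative_ranked_above_noise(self, method):
        """On the planted benchmark every base ranker puts the informative
        features above the noise features in median rank (10 seeds)."""
        wins = 0
        for seed in range(10):
            F, informative = benchmark_matrix(
                n_samples=150, n_features=20, n_informative=5, class_sep=2.0, seed=seed
            )
            ranked = base_selector_rank(F, method, k=5, seed=seed)
            pos = np.empty(20, dtype=int)
            pos[ranked.order] = np.arange(20)
            inf_median = np.median(pos[informative])
            noise = np.setdiff1d(np.arange(20), informative)
            if inf_median < np.median(pos[noise]):
                wins += 1
        assert wins >= 8  # median over seeds clearly favours informative


class TestHFSMVS:
    def test_unanimous_feature_always_selected(self):
        F, informative = benchmark_matrix(
            n_samples=150, n_features=15, n_informative=3, class_sep=3.0, seed=2
        )
        nominations = {
            m: set(base_selector_rank(F, m, k=5, seed=2).order[:5])
            for m in BASE_SELECTOR_METHODS
        }
        unanimous = set.intersection(*nominations.values())
        if unanimous:
            for thr in (1, 3, 5):
                mask = hfs_mvs_select(F, k=5, vote_threshold=thr, seed=2)
                assert unanimous <= set(mask.indices)

    def test_selection_subset_of_union_of_topk(self):
        F, _ = benchmark_matrix(n_samples=120, n_features=15, seed=4)
        union = set()
        for m in BASE_SELECTOR_METHODS:
            union |= set(base_selector_rank(F, m, k=4, seed=0).order[:4])
        mask = hfs_mvs_select(F, k=4, vote_threshold=3, seed=0)
        assert set(mask.indices) <= union

    def test_fallback_never_empty(self):
        F, _ = benchmark_matrix(n_samples=60, n_features=12, n_informative=0,
                                class_sep=0.0, seed=5)
        mask = hfs_mvs_select(F, k=2, vote_threshold=5, seed=5)
        assert mask.selected_count >= 1

    def test_vote_threshold_validated(self):
        F, _ = benchmark_matrix(n_samples=30, n_features=5, n_informative=2, seed=0)
        for thr in (0, 6):
            with pytest.raises(ValueError):
                hfs_mvs_select(F, k=2, vote_threshold=thr)

    def test_planted_recovery(self):
        """k=10, threshold 3: at least 4 of 5 informative features are
        recovered in median over 10 seeds."""
        recalls = []
        for seed in range(10):
            F, informative = benchmark_matrix(
                n_samples=200, n_features=30, n_informative=5, class_sep=2.0, seed=seed
            )
            mask = hfs_mvs_select(F, k=10, vote_threshold=3, seed=seed)
            recalls.append(len(set(mask.indices) & set(informative)) / 5)
        assert np.median(recalls) >= 0.8


def test_feature_mask_invariants():
    m = FeatureMask(bits=np.array([0, 1, 1, 0]))
    assert m.selected_count == 2
    assert list(m.indices) == [1, 2]
    with pytest.raises(ValueError):
        FeatureMask(bits=np.zeros(3))
    with pytest.raises(ValueError):
        FeatureMask(bits=np.array([0, 2]))
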