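import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kmcdce import stats as stx
from kmcdce.io_core import DataError


def _pair_count_auc(scores, labels):
    """Exhaustive pair-counting oracle for the ROC area."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_reference_example(self):
        assert stx.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == \
            pytest.approx(0.75)

    def test_perfect_separation(self):
        assert stx.roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_tied_is_half(self):
        assert stx.roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_pair_counting_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 60))
        scores = np.round(r.normal(size=n), 1)   # induce ties
        labels = r.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert stx.roc_auc(scores, labels) == pytest.approx(
            _pair_count_auc(scores, labels))

    def test_complement_identity_tie_free(self, rng):
        scores = rng.permutation(20).astype(float)
        labels = np.r_[np.zeros(10), np.ones(10)].astype(int)
        a = stx.roc_auc(scores, labels)
        b = stx.roc_auc(scores, 1 - labels)
        assert a + b == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        scores = r.normal(size=12)
        labels = np.r_[np.zeros(6), np.ones(6)].astype(int)
        a = stx.roc_auc(scores, labels)
        b = stx.roc_auc(np.exp(3 * scores), labels)
        assert a == pytest.approx(b)


class TestGroupTests:
    def test_wilcoxon_exact_small_sample(self):
        _, p = stx.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)     # 2/20 arrangements as extreme

    def test_chi_square_balanced_table(self):
        stat, p = stx.chi_square([[10, 10], [10, 10]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_identical_groups_p_one(self):
        _, p = stx.wilcoxon_rank_sum([2, 2, 2], [2, 2, 2])
        assert p == 1.0

    def test_compare_groups_continuous(self):
        df = pd.DataFrame({"f": [1.0, 2, 3, 4, 10, 11, 12, 13],
                           "outcome": [0, 0, 0, 0, 1, 1, 1, 1]})
        c = stx.compare_groups(df, "f", n_boot=50, seed=0)
        assert c.test == "wilcoxon-rank-sum"
        assert c.p_value < 0.05
        assert c.auc == 1.0

    def test_compare_groups_categorical(self):
        df = pd.DataFrame({"f": [0, 1] * 10, "outcome": [0] * 10 + [1] * 10})
        c = stx.compare_groups(df, "f", categorical=True)
        assert c.test == "chi-square"

    def test_constant_feature_flagged(self):
        df = pd.DataFrame({"f": np.ones(10),
                           "outcome": [0] * 5 + [1] * 5})
        c = stx.compare_groups(df, "f", categorical=False)
        assert c.degenerate


class TestYouden:
    def test_perfect_separation(self):
        thr, sens, spec, acc = stx.youden_operating_point(
            [0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert sens == 1.0 and spec == 1.0 and acc == 1.0

    def test_reference_example_vs_sweep_oracle(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        thr, sens, spec, acc = stx.youden_operating_point(scores, labels)
        assert thr == pytest.approx(0.35)
        assert sens == 1.0 and spec == 0.5
        # exhaustive sweep oracle
        best_j = max(
            np.mean([s >= t for s, l in zip(scores, labels) if l == 1])
            + np.mean([s < t for s, l in zip(scores, labels) if l == 0]) - 1
            for t in scores)
        assert sens + spec - 1 == pytest.approx(best_j)

    def test_inverted_labels_give_nonpositive_j(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        thr, sens, spec, _ = stx.youden_operating_point(scores, [1, 1, 0, 0])
        assert sens + spec - 1 <= 0


class TestLogistic:
    def test_separating_feature_reaches_auc_one(self):
        df = pd.DataFrame({"f": [0., 0, 0, 1, 1, 1],
                           "outcome": [0, 0, 0, 1, 1, 1]})
        _, probs = stx.fit_logistic(df, ("f",))
        assert stx.roc_auc(probs, df["outcome"].to_numpy()) == 1.0

    def test_null_feature_auc_near_half(self):
        r = np.random.default_rng(0)
        df = pd.DataFrame({"f": r.normal(size=2000),
                           "outcome": r.integers(0, 2, 2000)})
        _, probs = stx.fit_logistic(df, ("f",))
        assert stx.roc_auc(probs, df["outcome"].to_numpy()) == \
            pytest.approx(0.5, abs=0.05)

    def test_deterministic(self, small_cohort):
        m1, p1 = stx.fit_logistic(small_cohort, ("kBPE_Ktrans_IC", "kT_A"))
        m2, p2 = stx.fit_logistic(small_cohort, ("kBPE_Ktrans_IC", "kT_A"))
        np.testing.assert_array_equal(m1.coef_, m2.coef_)
        np.testing.assert_array_equal(p1, p2)

    def test_collinear_features_rejected(self):
        df = pd.DataFrame({"a": [1., 2, 3, 4], "b": [2., 4, 6, 8],
                           "outcome": [0, 0, 1, 1]})
        with pytest.raises(DataError):
            stx.fit_logistic(df, ("a", "b"))

    def test_matches_sklearn_mle(self, small_cohort):
        """Cross-check: with a vanishing ridge the coefficients agree with
        scikit-learn's logistic regression on standardized features."""
        from sklearn.linear_model import LogisticRegression
        feats = ("kBPE_Ktrans_IC", "kT_alpha")
        X = small_cohort[list(feats)].to_numpy()
        y = small_cohort["outcome"].to_numpy()
        Z = (X - X.mean(0)) / X.std(0)
        sk = LogisticRegression(C=1e8, tol=1e-10).fit(Z, y)
        ours = stx.LogisticModel(feats, ridge=1e-8).fit(X, y)
        np.testing.assert_allclose(ours.coef_[1:], sk.coef_.ravel(),
                                   rtol=1e-4, atol=1e-5)


class TestExhaustiveSearch:
    def test_pool_of_five_fits_25_models(self, rng):
        n = 60
        df = pd.DataFrame({f"kT_f{i}": rng.normal(size=n) for i in range(5)})
        df["outcome"] = rng.integers(0, 2, n)
        report = stx.exhaustive_model_search(
            df, {"kT": [f"kT_f{i}" for i in range(5)]}, "ii", n_boot=20,
            seed=0)
        assert len(report.leaderboard) == 25     # C(5,1)+C(5,2)+C(5,3)

    def test_informative_feature_selected(self, rng):
        n = 80
        y = rng.integers(0, 2, n)
        df = pd.DataFrame({f"kT_n{i}": rng.normal(size=n) for i in range(4)})
        df["kT_signal"] = y * 3.0 + rng.normal(scale=0.3, size=n)
        df["outcome"] = y
        report = stx.exhaustive_model_search(
            df, {"kT": list(df.columns[:-1])}, "ii", n_boot=20, seed=0)
        assert "kT_signal" in report.features

    def test_duplicate_features_tie_breaks_lexicographic(self, rng):
        n = 40
        y = rng.integers(0, 2, n)
        sig = y + rng.normal(scale=0.5, size=n)
        df = pd.DataFrame({"kT_a_sig": sig, "kT_b_sig": sig.copy(),
                           "outcome": y})
        report = stx.exhaustive_model_search(
            df, {"kT": ["kT_a_sig", "kT_b_sig"]}, "ii", n_boot=20, seed=0)
        assert report.features == ("kT_a_sig",)

    def test_multi_pool_family_requires_each_pool(self, rng):
        pools = {"clinical": ["age", "HER2"], "kT": ["kT_A"]}
        subsets = stx.enumerate_subsets(pools, "iv")
        assert all(any(f in pools["clinical"] for f in s)
                   and any(f in pools["kT"] for f in s) for s in subsets)
        assert ("age", "kT_A") in subsets and ("age", "HER2") not in subsets


class TestBootstrap:
    def test_fixed_seed_reproducible(self, small_cohort):
        ci1, a1 = stx.bootstrap_auc_ci(small_cohort, ("kBPE_Ktrans_IC",),
                                       n_boot=200, seed=42)
        ci2, a2 = stx.bootstrap_auc_ci(small_cohort, ("kBPE_Ktrans_IC",),
                                       n_boot=200, seed=42)
        assert ci1 == ci2
        np.testing.assert_array_equal(a1, a2)

    def test_perfect_separation_ci_is_unit(self):
        df = pd.DataFrame({"f": np.r_[np.zeros(15), np.ones(15)],
                           "outcome": np.r_[np.zeros(15), np.ones(15)]
                           .astype(int)})
        (lo, hi), _ = stx.bootstrap_auc_ci(df, ("f",), n_boot=100, seed=0)
        assert lo == 1.0 and hi == 1.0

    def test_model_vs_itself_p_one(self, small_cohort):
        _, aucs = stx.bootstrap_auc_ci(small_cohort, ("kBPE_Ktrans_IC",),
                                       n_boot=100, seed=0)
        z, p = stx.compare_models_z(aucs, aucs)
        assert z == 0.0 and p == 1.0

    def test_z_matches_hand_formula(self, rng):
        a = rng.normal(0.8, 0.03, 500)
        b = a - rng.normal(0.05, 0.02, 500)
        z, p = stx.compare_models_z(a, b)
        d = a - b
        expect = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert z == pytest.approx(expect, rel=1e-12)

    def test_constant_nonzero_difference_p_zero(self):
        a = np.full(50, 0.8)
        b = np.full(50, 0.75)
        z, p = stx.compare_models_z(a, b)
        assert p == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            stx.compare_models_z(np.ones(5), np.ones(6))
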