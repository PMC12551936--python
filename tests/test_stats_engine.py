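"""Permutation test, 1-D GMM, agreement statistics, ROC analysis.

Each stochastic operation is checked against an independent oracle:
full enumeration for the permutation test, sample moments and sklearn's
mixture EM for the GMM, sklearn's kappa for agreement, and the
pairwise-concordance statistic for ROC AUC.
"""

import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score
from sklearn.mixture import GaussianMixture

from convoscreen import (
    agreement,
    fit_gmm_1d,
    permutation_test_mean_diff,
    roc_analysis,
    select_gmm_components,
)


def _enumerate_null(x, y):
    """Oracle: mean differences over all distinct relabelings of the pool."""
    pooled = list(x) + list(y)
    nx = len(x)
    diffs = []
    for idx in itertools.combinations(range(len(pooled)), nx):
        gx = [pooled[i] for i in idx]
        gy = [pooled[i] for i in range(len(pooled)) if i not in idx]
        diffs.append(np.mean(gx) - np.mean(gy))
    return np.array(diffs)


class TestPermutationTest:
    def test_identical_groups_pvalue_near_one(self):
        r = permutation_test_mean_diff([1, 2, 3], [1, 2, 3], 9999, seed=0)
        assert r.p_value >= 0.99

    def test_exhaustive_hand_enumeration(self):
        r = permutation_test_mean_diff([0, 0], [1, 1], 1000, seed=0)
        assert r.exhaustive
        assert r.observed_diff == pytest.approx(-1.0)
        assert r.p_value == pytest.approx(2 / 6)

    def test_power_under_large_shift(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 50)
        y = rng.normal(2, 1, 50)
        r = permutation_test_mean_diff(x, y, 999, seed=1)
        assert r.p_value <= 0.01
        assert not r.exhaustive

    @pytest.mark.parametrize("alternative", ["two_sided", "greater", "less"])
    def test_exhaustive_matches_enumeration_oracle(self, alternative):
        rng = np.random.default_rng(21)
        for trial in range(10):
            nx = int(rng.integers(2, 6))
            ny = int(rng.integers(2, 6))
            if nx + ny > 10:
                continue
            x = rng.normal(0, 1, nx)
            y = rng.normal(0.5, 1, ny)
            r = permutation_test_mean_diff(x, y, 10**6, seed=0, alternative=alternative)
            assert r.exhaustive
            null = _enumerate_null(x, y)
            obs = x.mean() - y.mean()
            if alternative == "two_sided":
                expected = np.mean(np.abs(null) >= abs(obs) - 1e-12)
            elif alternative == "greater":
                expected = np.mean(null >= obs - 1e-12)
            else:
                expected = np.mean(null <= obs + 1e-12)
            assert r.p_value == pytest.approx(expected)

    def test_type_i_error_calibration(self):
        """Under a true null, rejection at alpha=.05 happens ~5% of the time."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 500
        for i in range(n_rep):
            x = rng.normal(0, 1, 20)
            y = rng.normal(0, 1, 20)
            r = permutation_test_mean_diff(x, y, 999, seed=i)
            rejections += r.p_value <= 0.05
        rate = rejections / n_rep
        assert 0.025 <= rate <= 0.075

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_test_mean_diff([], [1.0], 99, seed=0)

    def test_random_path_pvalue_floor(self):
        rng = np.random.default_rng(5)
        r = permutation_test_mean_diff(rng.normal(0, 1, 40), rng.normal(9, 1, 40), 999, seed=0)
        assert r.p_value >= 1 / (999 + 1)


class TestGMM:
    def test_k1_closed_form_moments(self):
        x = np.random.default_rng(0).normal(5.0, 2.0, 100)
        f = fit_gmm_1d(x, k=1, seed=0)
        assert f.weights[0] == pytest.approx(1.0)
        assert f.means[0] == pytest.approx(x.mean())
        assert f.variances[0] == pytest.approx(x.var())  # ML variance
        # p = 3k - 1 = 2
        assert f.aic == pytest.approx(2 * 2 - 2 * f.loglik)
        assert f.bic == pytest.approx(2 * math.log(100) - 2 * f.loglik)

    def test_three_component_recovery(self):
        rng = np.random.default_rng(42)
        truth = [(600, 100), (3000, 400), (6000, 600)]
        x = np.concatenate([rng.normal(m, s, 200) for m, s in truth])
        f = fit_gmm_1d(x, k=3, seed=0)
        recovered = np.sort(f.means)
        for (m, _), hat in zip(truth, recovered):
            assert abs(hat - m) / m < 0.10

    def test_bic_selects_three_components(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([
            rng.normal(600, 100, 200), rng.normal(3000, 400, 200), rng.normal(6000, 600, 200)
        ])
        best_k, fits = select_gmm_components(x, [1, 2, 3, 4], criterion="bic", seed=0)
        assert best_k == 3
        assert [f.k for f in fits] == [1, 2, 3, 4]

    def test_bic_prefers_single_gaussian_when_true(self):
        x = np.random.default_rng(11).normal(0, 1, 300)
        best_k, _ = select_gmm_components(x, [1, 2, 3], criterion="bic", seed=0)
        assert best_k == 1

    def test_weights_form_simplex(self):
        x = np.random.default_rng(3).normal(0, 1, 200)
        f = fit_gmm_1d(x, k=3, seed=1)
        assert f.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert (f.variances > 0).all()

    def test_loglik_close_to_sklearn(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(-3, 1, 150), rng.normal(3, 1, 150)])
        ours = fit_gmm_1d(x, k=2, seed=0)
        sk = GaussianMixture(2, covariance_type="full", random_state=0, n_init=3).fit(
            x.reshape(-1, 1)
        )
        sk_loglik = sk.score(x.reshape(-1, 1)) * x.size
        assert ours.loglik == pytest.approx(sk_loglik, rel=1e-3)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_gmm_1d([1.0, 2.0, 3.0, 4.0, 5.0], k=2, seed=0)


class TestAgreement:
    def test_identical_vectors(self):
        rep = agreement(["a", "b", "a"], ["a", "b", "a"])
        assert rep.kappa == pytest.approx(1.0)
        assert rep.percent_agreement == pytest.approx(1.0)

    def test_printed_contingency_table(self):
        # model-vs-raters table: yes/yes 26, yes/no 7, no/yes 2, no/no 9
        a = ["yes"] * 33 + ["no"] * 11
        b = ["yes"] * 26 + ["no"] * 7 + ["yes"] * 2 + ["no"] * 9
        rep = agreement(a, b)
        assert rep.percent_agreement == pytest.approx(35 / 44)
        assert rep.kappa == pytest.approx(0.5264, abs=5e-4)

    def test_forty_four_of_fifty_one(self):
        a = ["s"] * 44 + ["s"] * 7
        b = ["s"] * 44 + ["n"] * 7
        rep = agreement(a, b)
        assert rep.percent_agreement == pytest.approx(44 / 51, abs=1e-9)
        assert round(100 * rep.percent_agreement, 1) == 86.3

    def test_matches_sklearn_kappa(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            a = rng.choice(["x", "y", "z"], size=40)
            b = rng.choice(["x", "y", "z"], size=40)
            assert agreement(a, b).kappa == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12
            )

    def test_invariant_to_label_renaming(self):
        a = ["s", "n", "s", "s", "n"]
        b = ["s", "s", "s", "n", "n"]
        renamed = {"s": "alpha", "n": "beta"}
        rep1 = agreement(a, b)
        rep2 = agreement([renamed[v] for v in a], [renamed[v] for v in b])
        assert rep1.kappa == pytest.approx(rep2.kappa)
        assert rep1.percent_agreement == pytest.approx(rep2.percent_agreement)

    def test_chance_level_kappa_zero_closed_form(self):
        # marginals engineered so observed agreement equals chance agreement:
        # p_o = 0.5, p_e = 0.5 -> kappa = 0
        a = ["x", "x", "y", "y"]
        b = ["x", "y", "x", "y"]
        assert agreement(a, b).kappa == pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            agreement(["a"], ["a", "b"])


def _concordance_auc(scores, labels):
    """Oracle: P(score+ > score-) + 0.5 P(tie) over all pos/neg pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAnalysis:
    def test_perfect_separation(self):
        r = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.roc_auc == pytest.approx(1.0)
        assert r.precision_at_best == pytest.approx(1.0)
        assert r.recall_at_best == pytest.approx(1.0)

    def test_uninformative_scores(self):
        r = roc_analysis([5, 5, 5, 5], [0, 1, 0, 1])
        assert r.roc_auc == pytest.approx(0.5)

    def test_hand_computed_concordance(self):
        r = roc_analysis([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert r.roc_auc == pytest.approx(0.75)

    def test_matches_concordance_oracle_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = int(rng.integers(4, 51))
            scores = np.round(rng.normal(0, 1, n), 1)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            r = roc_analysis(scores, labels)
            assert r.roc_auc == pytest.approx(_concordance_auc(scores, labels))

    def test_positive_is_low_mirrors(self):
        scores = [1.0, 2.0, 3.0, 4.0]
        labels = [1, 1, 0, 0]  # positives have LOW scores
        r = roc_analysis(scores, labels, positive_is_high=False)
        assert r.roc_auc == pytest.approx(1.0)
        assert r.precision_at_best == pytest.approx(1.0)

    def test_tie_break_prefers_lowest_threshold(self):
        # two thresholds reach the same tpr-fpr; the lower one is reported
        r = roc_analysis([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert r.best_threshold == pytest.approx(0.35)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2], [1, 1])
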