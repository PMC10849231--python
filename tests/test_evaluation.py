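"""AUC estimator against exhaustive pair enumeration, tradeoff OLS against
closed-form arithmetic, and the paired permutation comparison against exact
enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splitaudit import auc, compare_models, evaluate_split, fit_final, tradeoff_analysis
from splitaudit.evaluation import SplitResult
from splitaudit.exceptions import DegenerateLabelsError, PairingError


def pair_enumeration_auc(scores, labels):
    """O(n^2) oracle: fraction of positive/negative pairs won, ties at 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (pos.size * neg.size)


class TestAUC:
    def test_worked_example(self):
        # pairs: (0.35>0.1), (0.35<0.4), (0.8>0.1), (0.8>0.4) -> 3/4
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_all_ties_is_chance(self):
        assert auc([1.0] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_perfect_separation(self):
        assert auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_pair_enumeration_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(4, 50)
            scores = rng.choice(np.round(rng.standard_normal(6), 2), size=n)
            labels = np.zeros(n, int)
            labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            assert auc(scores, labels) == pytest.approx(
                pair_enumeration_auc(scores, labels), abs=1e-12
            )

    def test_complement_identity_tie_free(self):
        rng = np.random.default_rng(5)
        scores = rng.standard_normal(40)
        labels = (rng.random(40) < 0.4).astype(int)
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)

    @given(st.floats(min_value=0.1, max_value=5.0))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_invariant_under_increasing_transform(self, scale):
        rng = np.random.default_rng(8)
        scores = rng.standard_normal(30)
        labels = np.array([0, 1] * 15)
        assert auc(np.exp(scale * scores), labels) == pytest.approx(auc(scores, labels))


class TestEvaluateSplit:
    def test_duplicating_cases_leaves_auc_unchanged(self, small_cohort):
        model = fit_final(small_cohort, {"C": 1.0})
        idx = np.arange(small_cohort.n_cases)
        a = evaluate_split(model, small_cohort, idx)
        b = evaluate_split(model, small_cohort, np.concatenate([idx, idx]))
        assert a == pytest.approx(b)

    def test_permuted_labels_center_on_chance(self, small_cohort):
        model = fit_final(small_cohort, {"C": 1.0})
        idx = np.arange(small_cohort.n_cases)
        scores = model.score(small_cohort, idx)
        rng = np.random.default_rng(0)
        labels = small_cohort.labels
        aucs = [auc(scores, rng.permutation(labels)) for _ in range(500)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_resubstitution_beats_null(self, small_cohort):
        model = fit_final(small_cohort, {"C": 1.0})
        idx = np.arange(small_cohort.n_cases)
        assert evaluate_split(model, small_cohort, idx) >= 0.5


def _results(train, test, label="m"):
    return [SplitResult(i, label, tr, te) for i, (tr, te) in enumerate(zip(train, test))]


class TestTradeoffAnalysis:
    def test_perfect_anti_diagonal(self):
        train = np.linspace(0.55, 0.75, 10)
        summary = tradeoff_analysis(_results(train, 1.3 - train))
        assert summary.slope == pytest.approx(-1.0)
        assert summary.intercept == pytest.approx(1.3)
        assert summary.r_squared == pytest.approx(1.0)
        assert summary.pearson_r == pytest.approx(-1.0)

    def test_three_point_closed_form(self):
        # hand OLS: x = {.60,.65,.70}, y = {.70,.66,.61}
        x = np.array([0.60, 0.65, 0.70])
        y = np.array([0.70, 0.66, 0.61])
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        r2 = sxy**2 / (sxx * ((y - y.mean()) ** 2).sum())
        summary = tradeoff_analysis(_results(x, y))
        assert slope == pytest.approx(-0.9)
        assert summary.slope == pytest.approx(slope)
        assert summary.r_squared == pytest.approx(r2)
        assert summary.r_squared == pytest.approx(0.998, abs=5e-3)
        assert summary.r_squared == pytest.approx(summary.pearson_r**2, abs=1e-10)

    def test_affine_shift_invariance(self):
        rng = np.random.default_rng(2)
        train = 0.6 + 0.05 * rng.standard_normal(20)
        test = 0.65 - 0.5 * (train - 0.6) + 0.01 * rng.standard_normal(20)
        a = tradeoff_analysis(_results(train, test))
        b = tradeoff_analysis(_results(train + 0.1, test + 0.1))
        assert a.slope == pytest.approx(b.slope)
        assert a.r_squared == pytest.approx(b.r_squared)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            tradeoff_analysis(_results([0.6, 0.7], [0.7, 0.6]))
        with pytest.raises(ValueError):
            tradeoff_analysis(_results([0.6] * 5, [0.7, 0.6, 0.5, 0.4, 0.3]))


class TestCompareModels:
    def test_self_comparison_is_null(self):
        a = _results(np.full(20, 0.6), np.linspace(0.5, 0.7, 20))
        res = compare_models(a, a)
        assert res.mean_difference == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_constant_difference_is_significant(self):
        base = np.linspace(0.55, 0.65, 50)
        a = _results(base, base + 0.05)
        b = _results(base, base)
        res = compare_models(a, b)
        assert res.mean_difference == pytest.approx(0.05)
        assert res.p_value <= 2e-4

    def test_matches_exact_enumeration_on_ten_pairs(self):
        rng = np.random.default_rng(0)
        diffs = rng.normal(0.01, 0.03, 10)
        base = np.full(10, 0.6)
        a = _results(base, base + diffs)
        b = _results(base, base)
        approx = compare_models(a, b, n_permutations=10_000, seed=1).p_value
        # oracle: all 2^10 sign assignments
        obs = abs(diffs.mean())
        count = sum(
            abs(np.array(signs) @ diffs) / 10 >= obs - 1e-15
            for signs in itertools.product([-1, 1], repeat=10)
        )
        exact = count / 2**10
        assert approx == pytest.approx(exact, abs=0.02)

    def test_mismatched_ids_rejected(self):
        a = _results([0.6, 0.7, 0.65], [0.6, 0.7, 0.65])
        b = list(reversed(a))
        with pytest.raises(PairingError):
            compare_models(a, b)
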