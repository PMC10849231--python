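"""Classifier contracts (penalty limits, MLE agreement with an independent
optimizer), the nested-CV engine, and modal selection arithmetic."""

from collections import Counter

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from splitaudit import (
    CVConfig,
    CVOutcome,
    FittedModelSpec,
    GeneratorParams,
    fit_final,
    generate_cohort,
    modal_selection,
    oracle_auc,
    repeated_nested_cv,
    train_classifier,
)
from splitaudit.exceptions import ConfigurationError, DegenerateLabelsError


class TestTrainClassifier:
    def test_infinite_penalty_limit(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((60, 5))
        y = (rng.random(60) < 0.4).astype(int)
        model = train_classifier(x, y, "logistic_l2", {"C": 1e-12})
        assert np.linalg.norm(model.coef) < 1e-6

    def test_mirror_symmetry_zeroes_intercept(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((40, 3))
        data = np.vstack([x, -x])
        labels = np.concatenate([np.ones(40, int), np.zeros(40, int)])
        model = train_classifier(data, labels, "logistic_l2", {"C": 1.0})
        assert abs(model.intercept) < 1e-6

    def test_matches_independent_unpenalized_mle(self):
        # 1-D data: {(-1,0),(+1,1)} x20 plus one overlapping pair
        x = np.concatenate([[-1.0] * 20, [1.0] * 20, [-1.0, 1.0]])[:, None]
        y = np.concatenate([np.zeros(20), np.ones(20), [1.0, 0.0]]).astype(int)
        model = train_classifier(x, y, "logistic_l2", {"C": 1e10}, tol=1e-10)

        def nll(w):
            z = x[:, 0] * w[0] + w[1]
            return np.sum(np.logaddexp(0.0, z) - y * z)

        ref = minimize(nll, np.zeros(2), method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
        assert model.coef[0] == pytest.approx(ref.x[0], abs=1e-3)
        assert model.intercept == pytest.approx(ref.x[1], abs=1e-3)

    def test_penalty_monotone_in_weight_norm(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((80, 6))
        y = (expit(x @ rng.standard_normal(6)) > rng.random(80)).astype(int)
        norms = [
            np.linalg.norm(train_classifier(x, y, "logistic_l2", {"C": c}).coef)
            for c in [1e-4, 1e-2, 1.0, 1e2]
        ]
        assert all(a <= b + 1e-8 for a, b in zip(norms, norms[1:]))

    def test_degenerate_labels_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            train_classifier(np.ones((5, 2)), np.ones(5, int))

    def test_non_finite_rejected(self):
        x = np.ones((4, 2))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_classifier(x, np.array([0, 1, 0, 1]))

    @pytest.mark.parametrize("cfg", [{"kernel": "linear", "C": 1.0},
                                     {"kernel": "rbf", "C": 1.0, "gamma": 0.1}])
    def test_svm_serialization_preserves_scores(self, cfg):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((50, 4))
        y = (x[:, 0] + 0.5 * rng.standard_normal(50) > 0).astype(int)
        model = train_classifier(x, y, "svm", cfg)
        clone = type(model).from_dict(model.to_dict())
        assert np.allclose(model.decision(x), clone.decision(x), atol=1e-12)


class TestRepeatedNestedCV:
    def test_pure_noise_stays_near_chance(self):
        cfg = CVConfig(k_folds=5, n_repeats=10, inner_folds=3, seed=0)
        for seed in (0, 1, 2):
            params = GeneratorParams(
                n_cases=200, prevalence=0.25, n_radiomic=10, n_clinical=2,
                n_informative_radiomic=1, n_informative_clinical=0,
                target_population_auc=0.5, seed=seed,
            )
            cohort = generate_cohort(params)
            out = repeated_nested_cv(cohort, cfg)
            assert 0.40 <= out.mean_validation_auc <= 0.60

    def test_separable_labels_reach_high_auc(self):
        params = GeneratorParams(
            n_cases=80, prevalence=0.3, n_radiomic=4, n_clinical=1,
            n_informative_radiomic=1, n_informative_clinical=0, seed=1,
        )
        cohort = generate_cohort(params)
        cohort.data["f_001"] = cohort.labels + 1e-3 * np.random.default_rng(0).standard_normal(80)
        out = repeated_nested_cv(cohort, CVConfig(n_repeats=2, seed=0))
        assert out.mean_validation_auc > 0.99

    def test_bit_identical_under_equal_seeds(self, small_cohort):
        cfg = CVConfig(n_repeats=3, seed=5)
        a = repeated_nested_cv(small_cohort, cfg)
        b = repeated_nested_cv(small_cohort, cfg)
        assert a.mean_validation_auc == b.mean_validation_auc
        assert np.array_equal(a.repeat_aucs, b.repeat_aucs)
        assert np.array_equal(a.selection_counts, b.selection_counts)
        assert a.feature_counts == b.feature_counts

    def test_case_order_invariance_distributional(self, small_cohort):
        """The mandated reshuffle makes row order irrelevant on average."""
        cfg = CVConfig(n_repeats=2)
        perm = np.random.default_rng(9).permutation(small_cohort.n_cases)
        shuffled = small_cohort.subset(perm)
        a = [repeated_nested_cv(small_cohort, cfg.replace(seed=s)).mean_validation_auc
             for s in range(8)]
        b = [repeated_nested_cv(shuffled, cfg.replace(seed=s)).mean_validation_auc
             for s in range(8)]
        assert abs(np.mean(a) - np.mean(b)) < 0.05

    def test_stability_selection_tallies_features(self, small_cohort):
        cfg = CVConfig(n_repeats=2, feature_selection="stability", n_selected_features=3, seed=0)
        out = repeated_nested_cv(small_cohort, cfg)
        assert sum(out.feature_counts.values()) == 3 * out.n_events
        hp, feats = modal_selection(out, cfg.stability_threshold)
        assert feats is not None and set(feats) <= set(small_cohort.feature_names)


def _outcome(counts, feature_counts, n_events, configs=None, names=None):
    configs = configs or [{"C": c} for c in (0.1, 1.0, 10.0)]
    return CVOutcome(
        mean_validation_auc=0.6,
        repeat_aucs=np.array([0.6]),
        grid_configs=configs,
        selection_counts=np.asarray(counts),
        feature_counts=Counter(feature_counts),
        n_events=n_events,
        feature_names=names or ["f1", "f2", "f3", "f7"],
    )


class TestModalSelection:
    def test_counting_oracle(self):
        # tallies C=0.1:1, C=1:7, C=10:2; f3 in 6/10 events, f7 in 4/10
        out = _outcome([1, 7, 2], {"f3": 6, "f7": 4}, 10)
        hp, feats = modal_selection(out, stability_threshold=0.5)
        assert hp == {"C": 1.0}
        assert feats == ["f3"]

    def test_unanimous(self):
        out = _outcome([0, 0, 5], {}, 5)
        hp, feats = modal_selection(out)
        assert hp == {"C": 10.0}
        assert feats is None

    def test_tie_prefers_stronger_regularization(self):
        out = _outcome([4, 4, 2], {}, 10)
        hp, _ = modal_selection(out)
        assert hp == {"C": 0.1}

    def test_empty_tallies_rejected(self):
        out = _outcome([0, 0, 0], {}, 0)
        with pytest.raises(ValueError):
            modal_selection(out)

    def test_frequencies_must_sum_to_events(self):
        with pytest.raises(ConfigurationError):
            _outcome([1, 1, 1], {}, 5)


class TestFitFinal:
    def test_scores_match_train_classifier(self, small_cohort):
        from splitaudit import fit_standardizer

        model = fit_final(small_cohort, {"C": 1.0})
        std = fit_standardizer(small_cohort)
        z = std.transform_matrix(small_cohort.feature_matrix(), small_cohort.vendors)
        direct = train_classifier(z, small_cohort.labels, "logistic_l2", {"C": 1.0})
        assert np.allclose(
            model.score(small_cohort), direct.decision(z), atol=1e-8
        )

    def test_serialization_roundtrip(self, small_cohort):
        model = fit_final(small_cohort, {"C": 0.1})
        clone = FittedModelSpec.from_json(model.to_json())
        assert np.abs(model.score(small_cohort) - clone.score(small_cohort)).max() < 1e-12
        assert clone.train_fingerprint == model.train_fingerprint

    def test_unknown_feature_rejected(self, small_cohort):
        with pytest.raises(ConfigurationError):
            fit_final(small_cohort, {"C": 1.0}, ["f_999"])

    def test_large_sample_consistency_approaches_population_auc(self):
        """With 10k training cases the fitted linear model nears the oracle."""
        from splitaudit import evaluate_split

        params = GeneratorParams(n_cases=10_000, target_population_auc=0.70, seed=21)
        train = generate_cohort(params)
        model = fit_final(train, {"C": 1.0})
        fresh_params = GeneratorParams(n_cases=100_000, target_population_auc=0.70, seed=22)
        fresh = generate_cohort(fresh_params)
        test_auc = evaluate_split(model, fresh, np.arange(fresh.n_cases))
        assert test_auc == pytest.approx(0.70, abs=0.03)
        assert oracle_auc(fresh, fresh_params) == pytest.approx(0.70, abs=0.01)
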