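"""Repeated nested cross-validation with modal hyperparameter/feature selection.

Training on one arm of a shuffle-split proceeds as:

1. ``n_repeats`` times (default 200): reshuffle the training arm and form
   ``k_folds`` stratified folds.  For every outer fold, an inner stratified
   CV over the hyperparameter grid picks the configuration with the best
   inner validation AUC; the outer-fold model is refit with that
   configuration on the outer-training portion and scored on the held-out
   fold.  The repeat's validation AUC is the mean over its outer folds, and
   the training result is the mean over repeats.
2. Every inner-selection event (one per outer fold per repeat) is tallied;
   ``modal_selection`` picks the most frequently winning hyperparameter value
   (and, under stability selection, the features chosen in at least a
   threshold fraction of events).
3. ``fit_final`` fits the standardizer and classifier once, on the entire
   training arm, with that modal configuration — one fixed model for testing.

Per-vendor standardization is refit inside each outer-training portion, so no
statistic of a held-out fold (let alone the test arm) leaks into any fit.

For the L2-regularized logistic classifier the inner grid is evaluated as a
warm-started regularization path (coefficients carried from one C to the
next), which keeps the 21-decade grid affordable at hundreds of repeats.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

try:  # fast warm-started C-path used by LogisticRegressionCV internally
    import inspect

    from sklearn.linear_model._logistic import _logistic_regression_path as _sk_path

    _HAVE_SK_PATH = "classes" in inspect.signature(_sk_path).parameters
except Exception:  # pragma: no cover - depends on sklearn version
    _HAVE_SK_PATH = False

from .cohort import Cohort
from .exceptions import ConfigurationError, DegenerateLabelsError, InfeasibleSplitError
from .preprocessing import VendorStandardizer, apply_vendor_stats, fit_standardizer, vendor_stats

__all__ = [
    "HyperparamGrid",
    "CVConfig",
    "CVOutcome",
    "FittedClassifier",
    "FittedModelSpec",
    "train_classifier",
    "repeated_nested_cv",
    "modal_selection",
    "fit_final",
]

_SEED_MOD = 2**31


def _decades(lo: int, hi: int) -> tuple[float, ...]:
    return tuple(float(10.0**e) for e in range(lo, hi + 1))


@dataclass(frozen=True)
class HyperparamGrid:
    """Hyperparameter grid, ordered from most to least regularized.

    For ``logistic_l2`` only ``c_values`` applies (default one point per
    decade across 10^-10..10^10).  For ``svm`` the grid is the cross product
    of kernels, C and (for rbf) the kernel coefficient gamma.
    """

    c_values: tuple[float, ...] = _decades(-10, 10)
    kernels: tuple[str, ...] = ("linear", "rbf")
    svm_c_values: tuple[float, ...] = _decades(-3, 3)
    gamma_values: tuple[float, ...] = _decades(-3, 1)

    def __post_init__(self) -> None:
        for c in self.c_values + self.svm_c_values:
            if c <= 0:
                raise ConfigurationError("all C values must be positive")
        if not self.c_values or not self.svm_c_values:
            raise ConfigurationError("grid must be non-empty")
        bad = set(self.kernels) - {"linear", "rbf"}
        if bad:
            raise ConfigurationError(f"unsupported kernels: {sorted(bad)}")

    def configs(self, classifier_kind: str) -> list[dict]:
        """Grid points in tie-break preference order (simpler/stronger first)."""
        if classifier_kind == "logistic_l2":
            return [{"C": c} for c in sorted(self.c_values)]
        if classifier_kind == "svm":
            out: list[dict] = []
            for kernel in self.kernels:  # linear preferred before rbf
                if kernel == "linear":
                    out.extend({"kernel": "linear", "C": c} for c in sorted(self.svm_c_values))
                else:
                    out.extend(
                        {"kernel": "rbf", "C": c, "gamma": g}
                        for c in sorted(self.svm_c_values)
                        for g in sorted(self.gamma_values)
                    )
            return out
        raise ConfigurationError(f"unknown classifier kind {classifier_kind!r}")


@dataclass(frozen=True)
class CVConfig:
    """Configuration of the repeated nested cross-validation."""

    k_folds: int = 5
    n_repeats: int = 200
    classifier_kind: str = "logistic_l2"
    grid: HyperparamGrid = field(default_factory=HyperparamGrid)
    feature_selection: str = "none"  # {"none", "stability"}
    stability_threshold: float = 0.5
    n_selected_features: int = 20  # features kept per selection event
    inner_folds: int = 3
    tol: float = 1e-4  # optimizer tolerance inside the CV loop
    max_iter: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2 or self.inner_folds < 2:
            raise ConfigurationError("k_folds and inner_folds must be >= 2")
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")
        if self.classifier_kind not in ("logistic_l2", "svm"):
            raise ConfigurationError(f"unknown classifier kind {self.classifier_kind!r}")
        if self.feature_selection not in ("none", "stability"):
            raise ConfigurationError(f"unknown feature_selection {self.feature_selection!r}")
        if not (0.0 < self.stability_threshold <= 1.0):
            raise ConfigurationError("stability_threshold must lie in (0, 1]")
        if self.feature_selection == "stability" and self.classifier_kind != "logistic_l2":
            raise ConfigurationError("stability selection requires logistic_l2")

    def replace(self, **kw) -> "CVConfig":
        from dataclasses import replace

        return replace(self, **kw)


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------


@dataclass
class FittedClassifier:
    """A fitted scoring rule: maps a feature matrix to real decision scores.

    Logistic models store dense weights; SVMs store the support expansion so
    scoring after deserialization is bit-for-bit the same as in memory.
    """

    kind: str
    hyperparams: dict
    coef: np.ndarray | None = None  # (p,) for logistic / linear svm
    intercept: float = 0.0
    support_vectors: np.ndarray | None = None  # svm rbf expansion
    dual_coef: np.ndarray | None = None

    def decision(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        if self.kind == "logistic_l2" or self.hyperparams.get("kernel") == "linear":
            return x @ self.coef + self.intercept
        k = rbf_kernel(x, self.support_vectors, gamma=self.hyperparams["gamma"])
        return k @ self.dual_coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "hyperparams": self.hyperparams,
            "coef": None if self.coef is None else self.coef.tolist(),
            "intercept": self.intercept,
            "support_vectors": None
            if self.support_vectors is None
            else self.support_vectors.tolist(),
            "dual_coef": None if self.dual_coef is None else self.dual_coef.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedClassifier":
        arr = lambda v: None if v is None else np.asarray(v, float)
        return cls(
            kind=d["kind"],
            hyperparams=dict(d["hyperparams"]),
            coef=arr(d["coef"]),
            intercept=float(d["intercept"]),
            support_vectors=arr(d["support_vectors"]),
            dual_coef=arr(d["dual_coef"]),
        )


def _check_training_inputs(x: np.ndarray, y: np.ndarray) -> None:
    if not np.isfinite(x).all():
        raise ValueError("feature matrix contains non-finite values")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("training labels contain a single class")


def train_classifier(
    x: np.ndarray,
    y: np.ndarray,
    kind: str = "logistic_l2",
    hyperparams: Mapping | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> FittedClassifier:
    """Fit one classifier at one grid point and return its scoring rule.

    ``logistic_l2`` minimizes the L2-penalized negative log-likelihood with
    penalty strength 1/C (convex, hence a reproducible optimum); ``svm``
    solves the soft-margin problem for the stated kernel.  Scores are
    decision values, not probabilities — AUC is rank-based, so calibration
    is irrelevant.
    """
    x = np.asarray(x, float)
    y = np.asarray(y)
    _check_training_inputs(x, y)
    hp = dict(hyperparams or {})
    if kind == "logistic_l2":
        clf = LogisticRegression(
            C=float(hp.get("C", 1.0)), solver="lbfgs", tol=tol, max_iter=max_iter
        ).fit(x, y)
        return FittedClassifier(
            kind=kind, hyperparams={"C": float(hp.get("C", 1.0))},
            coef=clf.coef_[0].copy(), intercept=float(clf.intercept_[0]),
        )
    if kind == "svm":
        kernel = hp.get("kernel", "linear")
        svc = SVC(
            kernel=kernel,
            C=float(hp.get("C", 1.0)),
            gamma=float(hp.get("gamma", 1.0)) if kernel == "rbf" else "scale",
            tol=tol if tol >= 1e-5 else 1e-5,
        ).fit(x, y)
        if kernel == "linear":
            return FittedClassifier(
                kind=kind, hyperparams={"kernel": "linear", "C": float(hp.get("C", 1.0))},
                coef=svc.coef_[0].copy(), intercept=float(svc.intercept_[0]),
            )
        return FittedClassifier(
            kind=kind,
            hyperparams={
                "kernel": "rbf",
                "C": float(hp.get("C", 1.0)),
                "gamma": float(hp.get("gamma", 1.0)),
            },
            support_vectors=svc.support_vectors_.copy(),
            dual_coef=svc.dual_coef_[0].copy(),
            intercept=float(svc.intercept_[0]),
        )
    raise ConfigurationError(f"unknown classifier kind {kind!r}")


# ---------------------------------------------------------------------------
# nested CV engine
# ---------------------------------------------------------------------------


@dataclass
class CVOutcome:
    """Tallied result of one repeated nested cross-validation."""

    mean_validation_auc: float
    repeat_aucs: np.ndarray  # one per repeat
    grid_configs: list[dict]  # preference order (ties resolve to lower index)
    selection_counts: np.ndarray  # wins per grid config
    feature_counts: Counter  # feature name -> selection-event count
    n_events: int
    feature_names: list[str]
    # one (grid config index, selected features or None) per selection event,
    # in the order the events occurred
    events: list[tuple[int, tuple[str, ...] | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if int(self.selection_counts.sum()) != self.n_events:
            raise ConfigurationError("selection frequencies must sum to the event count")
        if not (0.0 <= self.mean_validation_auc <= 1.0):
            raise ConfigurationError("mean validation AUC must lie in [0, 1]")


def _rank_auc(scores: np.ndarray, pos_mask: np.ndarray, n_pos: int, n_neg: int) -> float:
    """Mann–Whitney AUC via midranks; equals :func:`splitaudit.evaluation.auc`
    but without per-call validation overhead (hot loop only)."""
    r = rankdata(scores)
    return float((r[pos_mask].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _fit_logistic_path(
    x_tr: np.ndarray, y_tr: np.ndarray, c_values: Sequence[float], tol: float, max_iter: int
) -> np.ndarray:
    """Coefficients (n_C, p+1; intercept last) along the warm-started C path."""
    if _HAVE_SK_PATH:
        coefs, _, _ = _sk_path(
            np.ascontiguousarray(x_tr),
            y_tr,
            classes=np.array([0, 1]),
            Cs=np.asarray(c_values, float),
            fit_intercept=True,
            solver="lbfgs",
            tol=tol,
            max_iter=max_iter,
            check_input=False,
        )
        return np.asarray(coefs)
    clf = LogisticRegression(solver="lbfgs", tol=tol, max_iter=max_iter, warm_start=True)
    out = np.empty((len(c_values), x_tr.shape[1] + 1))
    for i, c in enumerate(c_values):
        clf.C = c
        clf.fit(x_tr, y_tr)
        out[i, :-1] = clf.coef_[0]
        out[i, -1] = clf.intercept_[0]
    return out


def _logistic_path_val_aucs(
    x_tr: np.ndarray,
    y_tr: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    c_values: Sequence[float],
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Validation AUC at every C, fit as one warm-started path (ascending C)."""
    coefs = _fit_logistic_path(x_tr, y_tr, c_values, tol, max_iter)
    scores = x_val @ coefs[:, :-1].T + coefs[:, -1]  # (n_val, n_C)
    pos = y_val == 1
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    return np.array([_rank_auc(scores[:, i], pos, n_pos, n_neg) for i in range(len(c_values))])


def _svm_val_aucs(
    x_tr: np.ndarray,
    y_tr: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    configs: Sequence[dict],
    tol: float,
) -> np.ndarray:
    pos = y_val == 1
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    out = np.empty(len(configs))
    for i, cfg in enumerate(configs):
        model = train_classifier(x_tr, y_tr, "svm", cfg, tol=max(tol, 1e-4))
        out[i] = _rank_auc(model.decision(x_val), pos, n_pos, n_neg)
    return out


def _stability_event_features(
    coef: np.ndarray, feature_names: Sequence[str], n_keep: int
) -> tuple[str, ...]:
    """Features kept by one selection event: top-|coefficient| on the
    standardized scale (ties broken by feature order for determinism)."""
    order = np.argsort(-np.abs(coef), kind="stable")[: min(n_keep, coef.size)]
    return tuple(feature_names[i] for i in sorted(order))


def repeated_nested_cv(
    train_cohort: Cohort,
    config: CVConfig,
    feature_names: Sequence[str] | None = None,
) -> CVOutcome:
    """Run the repeated nested CV on a training arm and tally selections.

    Only the training arm is ever passed in; the held-out test arm of the
    surrounding shuffle-split cannot enter any fit or selection by interface.
    Identical cohort, feature list and config (incl. seed) give a
    bit-identical outcome.
    """
    names = list(feature_names) if feature_names is not None else train_cohort.feature_names
    x = train_cohort.feature_matrix(names)
    y = train_cohort.labels
    vendors = train_cohort.vendors
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if min(n_pos, n_neg) < config.k_folds:
        raise InfeasibleSplitError(
            f"cannot form {config.k_folds} stratified folds with class counts "
            f"({n_pos}, {n_neg})"
        )

    configs = config.grid.configs(config.classifier_kind)
    c_values = [cfg["C"] for cfg in configs] if config.classifier_kind == "logistic_l2" else None
    counts = np.zeros(len(configs), dtype=int)
    feature_counts: Counter = Counter()
    events: list[tuple[int, tuple[str, ...] | None]] = []
    n_events = 0
    repeat_aucs = np.empty(config.n_repeats)

    for rep in range(config.n_repeats):
        rep_seed = (config.seed + rep) % _SEED_MOD
        outer = StratifiedKFold(config.k_folds, shuffle=True, random_state=rep_seed)
        fold_aucs = []
        for fold_i, (tr, te) in enumerate(outer.split(x, y)):
            stats = vendor_stats(x[tr], vendors[tr])
            xs_tr = apply_vendor_stats(x[tr], vendors[tr], stats)
            xs_te = apply_vendor_stats(x[te], vendors[te], stats)
            y_tr, y_te = y[tr], y[te]

            inner_seed = (rep_seed + 104_729 * (fold_i + 1)) % _SEED_MOD
            inner = StratifiedKFold(config.inner_folds, shuffle=True, random_state=inner_seed)
            val_aucs = np.zeros(len(configs))
            n_inner = 0
            for itr, ite in inner.split(xs_tr, y_tr):
                if config.classifier_kind == "logistic_l2":
                    val_aucs += _logistic_path_val_aucs(
                        xs_tr[itr], y_tr[itr], xs_tr[ite], y_tr[ite],
                        c_values, config.tol, config.max_iter,
                    )
                else:
                    val_aucs += _svm_val_aucs(
                        xs_tr[itr], y_tr[itr], xs_tr[ite], y_tr[ite], configs, config.tol
                    )
                n_inner += 1
            val_aucs /= n_inner
            best = int(np.argmax(val_aucs))  # ties -> lower index = stronger regularization
            counts[best] += 1
            n_events += 1

            model = train_classifier(
                xs_tr, y_tr, config.classifier_kind, configs[best],
                tol=config.tol, max_iter=config.max_iter,
            )
            selected: tuple[str, ...] | None = None
            if config.feature_selection == "stability":
                selected = _stability_event_features(
                    model.coef, names, config.n_selected_features
                )
                feature_counts.update(selected)
                cols = [names.index(f) for f in selected]
                model = train_classifier(
                    xs_tr[:, cols], y_tr, config.classifier_kind, configs[best],
                    tol=config.tol, max_iter=config.max_iter,
                )
                scores = model.decision(xs_te[:, cols])
            else:
                scores = model.decision(xs_te)
            events.append((best, selected))
            pos_te = y_te == 1
            n_pos_te = int(pos_te.sum())
            fold_aucs.append(_rank_auc(scores, pos_te, n_pos_te, pos_te.size - n_pos_te))
        repeat_aucs[rep] = float(np.mean(fold_aucs))

    return CVOutcome(
        mean_validation_auc=float(repeat_aucs.mean()),
        repeat_aucs=repeat_aucs,
        grid_configs=configs,
        selection_counts=counts,
        feature_counts=feature_counts,
        n_events=n_events,
        feature_names=names,
        events=events,
    )


def modal_selection(
    outcome: CVOutcome, stability_threshold: float = 0.5
) -> tuple[dict, list[str] | None]:
    """Most frequently selected configuration, plus the stable feature set.

    Hyperparameter ties go to the lower grid index, i.e. the stronger
    regularization / simpler kernel.  Features selected in at least
    ``stability_threshold`` of the selection events are kept; returns ``None``
    for the features when no feature tallies exist (selection was off).
    """
    if outcome.n_events < 1:
        raise ValueError("no selection events tallied")
    best = int(np.argmax(outcome.selection_counts))
    chosen = dict(outcome.grid_configs[best])
    if not outcome.feature_counts:
        return chosen, None
    stable = [
        f
        for f in outcome.feature_names
        if outcome.feature_counts.get(f, 0) / outcome.n_events >= stability_threshold
    ]
    return chosen, stable


# ---------------------------------------------------------------------------
# the fixed final model
# ---------------------------------------------------------------------------


@dataclass
class FittedModelSpec:
    """One fixed model: everything needed to score new cases with no refitting."""

    classifier_kind: str
    hyperparams: dict
    feature_names: list[str]
    standardizer: VendorStandardizer
    classifier: FittedClassifier
    train_fingerprint: str

    def score(self, cohort: Cohort, indices: Sequence[int] | None = None) -> np.ndarray:
        idx = (
            np.arange(cohort.n_cases) if indices is None else np.asarray(indices, dtype=int)
        )
        x = cohort.feature_matrix(self.feature_names)[idx]
        z = self.standardizer.transform_matrix(x, cohort.vendors[idx])
        return self.classifier.decision(z)

    def to_json(self) -> str:
        return json.dumps(
            {
                "classifier_kind": self.classifier_kind,
                "hyperparams": self.hyperparams,
                "feature_names": self.feature_names,
                "standardizer": self.standardizer.to_dict(),
                "classifier": self.classifier.to_dict(),
                "train_fingerprint": self.train_fingerprint,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "FittedModelSpec":
        d = json.loads(s)
        return cls(
            classifier_kind=d["classifier_kind"],
            hyperparams=dict(d["hyperparams"]),
            feature_names=list(d["feature_names"]),
            standardizer=VendorStandardizer.from_dict(d["standardizer"]),
            classifier=FittedClassifier.from_dict(d["classifier"]),
            train_fingerprint=d["train_fingerprint"],
        )


def _fingerprint(cohort: Cohort) -> str:
    h = hashlib.sha256()
    h.update(",".join(cohort.data["case_id"].astype(str)).encode())
    h.update(cohort.labels.tobytes())
    return h.hexdigest()[:16]


def fit_final(
    train_cohort: Cohort,
    hyperparams: Mapping,
    feature_names: Sequence[str] | None = None,
    classifier_kind: str = "logistic_l2",
    tol: float = 1e-8,
) -> FittedModelSpec:
    """Fit the one fixed model: standardizer + classifier on the full training
    arm, restricted to the chosen features, at the chosen grid point."""
    names = list(feature_names) if feature_names is not None else train_cohort.feature_names
    std = fit_standardizer(train_cohort, feature_names=names)
    z = std.transform_matrix(train_cohort.feature_matrix(names), train_cohort.vendors)
    clf = train_classifier(z, train_cohort.labels, classifier_kind, hyperparams, tol=tol)
    return FittedModelSpec(
        classifier_kind=classifier_kind,
        hyperparams=dict(hyperparams),
        feature_names=names,
        standardizer=std,
        classifier=clf,
        train_fingerprint=_fingerprint(train_cohort),
    )
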