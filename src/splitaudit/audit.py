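"""The top-level modelling objects: shuffle-split audits and learning curves.

`TrainTestAudit` is the whole resampling/evaluation loop as one fit-able
object: build it from a cohort, call :meth:`~TrainTestAudit.fit`, and the
returned :class:`AuditResults` carries every per-split train/test AUC pair,
the covariate balance reports, the anti-diagonal tradeoff regression per
model variant, and paired model comparisons, with ``summary()`` printing the
audit table.  :class:`LearningCurveStudy` is the incremental-cohort
experiment in the same shape.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, generate_cohort
from .evaluation import (
    ComparisonResult,
    SplitResult,
    TradeoffSummary,
    compare_models,
    evaluate_split,
    results_to_frame,
    tradeoff_analysis,
)
from .io import AuditConfig, ModelPlan, default_model_plans, read_cohort, save_config, write_cohort
from .learning_curve import (
    ConvergenceReport,
    LearningCurvePoint,
    convergence_check,
    curve_to_frame,
    cv_at_sizes,
    nested_cohorts,
)
from .model_training import CVConfig, fit_final, modal_selection, repeated_nested_cv
from .resampling import balance_check, shuffle_split, splits_to_frame

__all__ = [
    "TrainTestAudit",
    "AuditResults",
    "LearningCurveStudy",
    "LearningCurveResults",
    "run_audit",
]

_SEED_MOD = 2**31
_FLOAT_FMT = "%.12g"


class TrainTestAudit:
    """Repeated shuffle-split audit of train-vs-test performance bias.

    Parameters
    ----------
    cohort
        The case pool every split partitions.
    models
        Model variants to audit; defaults to the four standard ones
        (clinical, radiomics, radiomics+clinical, radiomics+selection).
    n_train, n_splits, master_seed
        Shuffle-split design: training-arm size, number of repeated splits,
        and the seed from which per-split seeds are derived.
    cv_config
        Nested-CV settings shared by all variants (classifier kind and
        feature-selection mode are overridden per variant).
    alpha, covariates
        Per-split covariate balance monitoring (Welch t-tests, uncorrected).
    """

    def __init__(
        self,
        cohort: Cohort,
        models: Sequence[ModelPlan] | None = None,
        n_train: int = 400,
        n_splits: int = 50,
        master_seed: int = 0,
        cv_config: CVConfig | None = None,
        alpha: float = 0.05,
        covariates: Sequence[str] = ("age", "lesion_size"),
    ) -> None:
        self.cohort = cohort
        self.models = list(models) if models is not None else default_model_plans()
        self.n_train = int(n_train)
        self.n_splits = int(n_splits)
        self.master_seed = int(master_seed)
        self.cv_config = cv_config if cv_config is not None else CVConfig()
        self.alpha = float(alpha)
        self.covariates = tuple(covariates)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "TrainTestAudit":
        return cls(read_cohort(path), **kwargs)

    def _cv_for(self, plan: ModelPlan, split_id: int) -> CVConfig:
        # per-split CV seed keeps splits independent yet individually re-creatable
        seed = (self.cv_config.seed + 7919 * split_id) % _SEED_MOD
        return self.cv_config.replace(
            classifier_kind=plan.classifier_kind,
            feature_selection=plan.feature_selection,
            seed=seed,
        )

    def fit(self, progress: bool = False) -> "AuditResults":
        """Run every split x model variant and collect the results ledger."""
        splits = shuffle_split(self.cohort, self.n_train, self.n_splits, self.master_seed)
        results: list[SplitResult] = []
        timings: list[str] = []
        for split in splits:
            t0 = time.perf_counter()
            balance = balance_check(self.cohort, split, self.covariates, self.alpha)
            train_cohort = self.cohort.subset(split.train_indices)
            for plan in self.models:
                try:
                    features = plan.resolve_features(self.cohort)
                    cfg = self._cv_for(plan, split.split_id)
                    outcome = repeated_nested_cv(train_cohort, cfg, features)
                    hyperparams, stable = modal_selection(outcome, cfg.stability_threshold)
                    final_features = stable if stable else features
                    model = fit_final(
                        train_cohort, hyperparams, final_features, plan.classifier_kind
                    )
                    test_auc = evaluate_split(model, self.cohort, split.test_indices)
                except Exception as exc:
                    raise type(exc)(
                        f"split {split.split_id}, model {plan.label!r}: {exc}"
                    ) from exc
                results.append(
                    SplitResult(
                        split_id=split.split_id,
                        model_label=plan.label,
                        train_auc=outcome.mean_validation_auc,
                        test_auc=test_auc,
                        balance=balance,
                        model=model,
                    )
                )
            timings.append(
                f"split {split.split_id}: {time.perf_counter() - t0:.2f}s "
                f"({len(self.models)} models)"
            )
            if progress:
                print(timings[-1])
        return AuditResults(audit=self, splits=splits, results=results, timings=timings)


@dataclass
class AuditResults:
    """Results ledger of one fitted :class:`TrainTestAudit`."""

    audit: TrainTestAudit
    splits: list
    results: list[SplitResult]
    timings: list[str] = field(default_factory=list)

    @property
    def model_labels(self) -> list[str]:
        return [m.label for m in self.audit.models]

    def for_model(self, label: str) -> list[SplitResult]:
        out = [r for r in self.results if r.model_label == label]
        if not out:
            raise KeyError(f"no results for model {label!r}")
        return out

    def tradeoff(self, label: str) -> TradeoffSummary:
        """Anti-diagonal OLS of test on train AUC for one model variant."""
        return tradeoff_analysis(self.for_model(label))

    def tradeoffs(self) -> dict[str, TradeoffSummary]:
        return {label: self.tradeoff(label) for label in self.model_labels}

    def compare(
        self, label_a: str, label_b: str, n_permutations: int = 10_000, seed: int = 0
    ) -> ComparisonResult:
        """Paired sign-flip permutation test between two variants."""
        return compare_models(
            self.for_model(label_a), self.for_model(label_b), n_permutations, seed
        )

    def balance_flag_rate(self) -> float:
        """Fraction of (split, covariate) Welch tests significant at alpha."""
        flags = [
            bool(f)
            for r in self.for_model(self.model_labels[0])
            if r.balance is not None
            for f in r.balance.flags
        ]
        return float(np.mean(flags))

    def to_frame(self) -> pd.DataFrame:
        return results_to_frame(self.results)

    def summary(self) -> str:
        """Plain-text audit table, one block per model variant."""
        lines = [
            "Train/test performance-bias audit",
            f"  cohort: n={self.audit.cohort.n_cases}, "
            f"prevalence={self.audit.cohort.prevalence:.3f}; "
            f"splits: {self.audit.n_splits} x ({self.audit.n_train}/"
            f"{self.audit.cohort.n_cases - self.audit.n_train})",
            "",
            f"{'model':<22}{'train AUC (range)':<24}{'test AUC (range)':<24}"
            f"{'slope':>8}{'R^2':>8}{'p':>10}",
        ]
        for label in self.model_labels:
            rs = self.for_model(label)
            tr = np.array([r.train_auc for r in rs])
            te = np.array([r.test_auc for r in rs])
            t = self.tradeoff(label)
            lines.append(
                f"{label:<22}"
                f"{tr.mean():.3f} ({tr.min():.2f}-{tr.max():.2f})      "
                f"{te.mean():.3f} ({te.min():.2f}-{te.max():.2f})      "
                f"{t.slope:>8.3f}{t.r_squared:>8.3f}{t.p_value:>10.2g}"
            )
        n_flagged = sum(
            r.balance.any_significant
            for r in self.for_model(self.model_labels[0])
            if r.balance is not None
        )
        lines += [
            "",
            f"splits with significant age/lesion-size imbalance "
            f"(alpha={self.audit.alpha}): {n_flagged}/{self.audit.n_splits}",
        ]
        return "\n".join(lines)

    def plot_tradeoff(self, labels: Sequence[str] | None = None, path: str | None = None):
        """Scatter of test vs train AUC per split with the identity diagonal."""
        import matplotlib.pyplot as plt

        labels = list(labels) if labels else self.model_labels
        fig, ax = plt.subplots(figsize=(5, 5))
        for label in labels:
            rs = self.for_model(label)
            ax.scatter(
                [r.train_auc for r in rs], [r.test_auc for r in rs], s=14, label=label
            )
        lo, hi = ax.get_xlim()[0], ax.get_xlim()[1]
        lim = (min(lo, ax.get_ylim()[0]), max(hi, ax.get_ylim()[1]))
        ax.plot(lim, lim, "k--", lw=0.8)
        ax.set_xlabel("training AUC (mean cross-validated)")
        ax.set_ylabel("test AUC")
        ax.legend(fontsize=7)
        if path:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return ax

    def write(self, outdir: str | Path) -> None:
        """Write the ledgers: splits.csv, results.csv, tradeoff.json."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        splits_to_frame(self.audit.cohort, self.splits).to_csv(
            out / "splits.csv", index=False
        )
        self.to_frame().to_csv(out / "results.csv", index=False, float_format=_FLOAT_FMT)
        trade = {
            label: vars(t).copy() for label, t in self.tradeoffs().items()
        }
        (out / "tradeoff.json").write_text(json.dumps(trade, indent=2, sort_keys=True))
        (out / "log.txt").write_text("\n".join(self.timings) + "\n")


class LearningCurveStudy:
    """Incremental-cohort CV experiment: how does the CV AUC estimate
    stabilise as the available cohort grows?"""

    def __init__(
        self,
        cohort: Cohort,
        cv_config: CVConfig | None = None,
        step: int = 100,
        n_cohorts: int = 20,
        seed: int = 0,
        feature_names: Sequence[str] | None = None,
        mode: str = "nested",
    ) -> None:
        self.cohort = cohort
        self.cv_config = cv_config if cv_config is not None else CVConfig()
        self.step = int(step)
        self.n_cohorts = int(n_cohorts)
        self.seed = int(seed)
        self.feature_names = list(feature_names) if feature_names is not None else None
        self.mode = mode

    def fit(self) -> "LearningCurveResults":
        chains = nested_cohorts(self.cohort, self.step, self.n_cohorts, self.seed, self.mode)
        points = cv_at_sizes(self.cohort, chains, self.cv_config, self.feature_names)
        return LearningCurveResults(study=self, points=points)


@dataclass
class LearningCurveResults:
    study: LearningCurveStudy
    points: list[LearningCurvePoint]

    def convergence(self) -> ConvergenceReport:
        return convergence_check(self.points)

    def to_frame(self) -> pd.DataFrame:
        return curve_to_frame(self.points)

    def summary(self) -> str:
        conv = self.convergence()
        lines = [
            "Incremental-cohort cross-validation learning curve",
            f"  {self.study.n_cohorts} random cohorts, step {self.study.step}",
            "",
            f"{'n_cases':>8}{'q1':>8}{'median':>8}{'q3':>8}{'IQR':>8}",
        ]
        for p in self.points:
            q1, med, q3 = p.quartiles
            lines.append(f"{p.n_cases:>8}{q1:>8.3f}{med:>8.3f}{q3:>8.3f}{p.iqr:>8.3f}")
        lines += ["", f"converged at n = {conv.converged_at}"]
        return "\n".join(lines)

    def plot(self, path: str | None = None):
        """Boxplot of CV AUCs per cohort size."""
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.boxplot(
            [p.auc_values for p in self.points],
            tick_labels=[str(p.n_cases) for p in self.points],
        )
        ax.set_xlabel("number of cases")
        ax.set_ylabel("cross-validated AUC")
        if path:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return ax

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "learning_curve.csv", index=False, float_format=_FLOAT_FMT)
        conv = self.convergence()
        payload = {
            "converged_at": conv.converged_at,
            "pairs": conv.table.to_dict(orient="records"),
        }
        (out / "convergence.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def run_audit(config: AuditConfig, outdir: str | Path) -> AuditResults:
    """Run the full configured audit and write the results bundle.

    The bundle directory holds a copy of the config, the cohort (if
    generated), the split/result ledgers, tradeoff summaries and pairwise
    model comparisons.  Re-running with the same config reproduces every
    file byte for byte.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")
    if config.generator is not None:
        cohort = generate_cohort(config.generator)
        write_cohort(cohort, out / "cohort.csv")
    else:
        cohort = read_cohort(config.cohort_path)
    audit = TrainTestAudit(
        cohort,
        models=config.models,
        n_train=config.n_train,
        n_splits=config.n_splits,
        master_seed=config.master_seed,
        cv_config=config.cv,
        alpha=config.alpha,
    )
    res = audit.fit()
    res.write(out)
    comparisons = {}
    labels = res.model_labels
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            c = res.compare(a, b, config.n_permutations, seed=config.master_seed)
            comparisons[f"{a} vs {b}"] = vars(c).copy()
    (out / "comparisons.json").write_text(json.dumps(comparisons, indent=2, sort_keys=True))
    (out / "summary.txt").write_text(res.summary() + "\n")
    return res
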