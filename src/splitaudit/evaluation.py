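"""Test-set scoring, the paired train/test AUC ledger, and tradeoff analysis.

The central diagnostic: across repeated shuffle-splits of a fixed pool, plot
each split's cross-validated training AUC against its held-out test AUC.  On
limited data the points spread perpendicular to the identity diagonal — a
split whose "easy" cases land in the test arm necessarily removed them from
the training arm, so higher training AUC pairs with lower test AUC and vice
versa.  ``tradeoff_analysis`` quantifies that anti-diagonal trend by ordinary
least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .cohort import Cohort
from .exceptions import DegenerateLabelsError, PairingError
from .resampling import BalanceReport

__all__ = [
    "auc",
    "evaluate_split",
    "SplitResult",
    "TradeoffSummary",
    "tradeoff_analysis",
    "ComparisonResult",
    "compare_models",
]


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC: P(positive score > negative score) with ties at 1/2.

    Equals the trapezoidal area under the empirical ROC curve.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise DegenerateLabelsError("AUC needs at least one positive and one negative")
    return float(roc_auc_score(labels, scores))


def evaluate_split(model, cohort: Cohort, test_indices: Sequence[int]) -> float:
    """Held-out AUC of a fixed, fully fitted model on the test arm only.

    ``model`` is a :class:`~splitaudit.model_training.FittedModelSpec`; its
    stored standardizer and weights are applied with zero refitting.
    """
    idx = np.asarray(test_indices, dtype=int)
    scores = model.score(cohort, idx)
    return auc(scores, cohort.labels[idx])


@dataclass
class SplitResult:
    """Paired train/test performance for one split of one model variant."""

    split_id: int
    model_label: str
    train_auc: float  # mean cross-validated validation AUC on the train arm
    test_auc: float
    balance: BalanceReport | None = None
    model: object | None = None  # FittedModelSpec


@dataclass(frozen=True)
class TradeoffSummary:
    """OLS of test AUC on train AUC across splits (the anti-diagonal trend)."""

    n_points: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-sided, zero-slope null
    pearson_r: float


def tradeoff_analysis(results: Sequence[SplitResult]) -> TradeoffSummary:
    """Fit test_auc ~ train_auc by least squares over the split results.

    ``pearson_r`` carries the sign of the tradeoff (negative = anti-diagonal);
    ``r_squared`` is its square and is direction-invariant.
    """
    train = np.array([r.train_auc for r in results], float)
    test = np.array([r.test_auc for r in results], float)
    if train.size < 3:
        raise ValueError(f"need >= 3 split results, got {train.size}")
    if np.ptp(train) == 0.0:
        raise ValueError("train AUCs are all identical; tradeoff slope undefined")
    fit = stats.linregress(train, test)
    return TradeoffSummary(
        n_points=int(train.size),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        pearson_r=float(fit.rvalue),
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Paired comparison of two model variants across the same splits."""

    mean_difference: float  # mean over splits of (test_auc_a - test_auc_b)
    p_value: float
    n_pairs: int
    n_permutations: int


def compare_models(
    results_a: Sequence[SplitResult],
    results_b: Sequence[SplitResult],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> ComparisonResult:
    """Paired sign-flip permutation test on per-split test-AUC differences.

    Two-sided; p uses the add-one convention ``(1 + #{|perm| >= |obs|}) /
    (1 + n_permutations)`` so it is never exactly zero.
    """
    ids_a = [r.split_id for r in results_a]
    ids_b = [r.split_id for r in results_b]
    if ids_a != ids_b or len(ids_a) == 0:
        raise PairingError("result lists must share identical, non-empty split_id order")
    diffs = np.array(
        [a.test_auc - b.test_auc for a, b in zip(results_a, results_b)], float
    )
    obs = abs(diffs.mean())
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(int(n_permutations), diffs.size))
    perm = np.abs((flips * diffs).mean(axis=1))
    p = (1.0 + np.count_nonzero(perm >= obs - 1e-15)) / (1.0 + n_permutations)
    return ComparisonResult(
        mean_difference=float(diffs.mean()),
        p_value=float(min(p, 1.0)),
        n_pairs=diffs.size,
        n_permutations=int(n_permutations),
    )


def results_to_frame(results: Sequence[SplitResult]) -> pd.DataFrame:
    """Ledger table: one row per split x model variant."""
    rows = []
    for r in results:
        row = {
            "split_id": r.split_id,
            "model_label": r.model_label,
            "train_auc": r.train_auc,
            "test_auc": r.test_auc,
        }
        if r.balance is not None:
            row["balance_flagged"] = r.balance.any_significant
            for cov, rec in r.balance.table.iterrows():
                row[f"p_{cov}"] = rec["p_value"]
        rows.append(row)
    return pd.DataFrame(rows)
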