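"""Prevalence-balanced repeated shuffle-splitting with covariate monitoring.

A shuffle-split randomly partitions a fixed cohort into complementary train
and test arms while preserving the positive-class fraction in both arms
(stratified allocation).  Because any single split defines "the test set" by
one small cohort, the audit repeats the split many times; this module also
flags, per split, whether nuisance covariates (age, lesion size) differ
significantly between arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .exceptions import InfeasibleSplitError, UndefinedTestError

__all__ = [
    "SplitSpec",
    "BalanceReport",
    "stratified_allocation",
    "shuffle_split",
    "balance_check",
    "splits_to_frame",
]

_SEED_MOD = 2**31


def proportional_count(n_class: int, n_arm: int, n_total: int) -> int:
    """round-to-nearest of n_class * n_arm / n_total, ties rounded down.

    Exact integer arithmetic, no float rounding surprises.
    """
    num = n_class * n_arm
    q, r = divmod(num, n_total)
    return q + (1 if 2 * r > n_total else 0)


def stratified_allocation(
    n_pos: int, n_neg: int, n_train: int
) -> tuple[int, int, int, int]:
    """Per-arm class counts for a prevalence-balanced train/test partition.

    Returns ``(train_pos, train_neg, test_pos, test_neg)``.  The train-arm
    positive count is the round-to-nearest (ties down) of the proportional
    share; e.g. a 700-case pool with 114 positives split 400/300 yields
    (65, 335, 49, 251).
    """
    if n_pos < 1 or n_neg < 1:
        raise InfeasibleSplitError("need at least one case per class")
    n_total = n_pos + n_neg
    if not (0 < n_train < n_total):
        raise InfeasibleSplitError(
            f"n_train must lie strictly between 0 and {n_total}, got {n_train}"
        )
    train_pos = proportional_count(n_pos, n_train, n_total)
    train_neg = n_train - train_pos
    test_pos = n_pos - train_pos
    test_neg = n_neg - train_neg
    counts = (train_pos, train_neg, test_pos, test_neg)
    if min(counts) < 1:
        raise InfeasibleSplitError(
            f"allocation {counts} would empty a class in one arm"
        )
    return counts


@dataclass(frozen=True)
class SplitSpec:
    """One prevalence-balanced train/test partition of a cohort."""

    split_id: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    counts: tuple[int, int, int, int]  # (train_pos, train_neg, test_pos, test_neg)

    def validate(self, labels: np.ndarray) -> None:
        """Assert the partition property and the stratified counts."""
        train = np.sort(self.train_indices)
        test = np.sort(self.test_indices)
        n = labels.size
        union = np.concatenate([train, test])
        if union.size != n or not np.array_equal(np.sort(union), np.arange(n)):
            raise InfeasibleSplitError("train/test arms do not partition the cohort")
        tp = int(labels[train].sum())
        sp = int(labels[test].sum())
        expect = (tp, train.size - tp, sp, test.size - sp)
        if expect != tuple(self.counts):
            raise InfeasibleSplitError(f"counts {self.counts} != observed {expect}")


def _per_split_seed(master_seed: int, split_id: int) -> int:
    # documented counter scheme so any single split is re-creatable alone
    return (int(master_seed) + int(split_id)) % _SEED_MOD


def shuffle_split(
    cohort: Cohort, n_train: int, n_splits: int, master_seed: int = 0
) -> list[SplitSpec]:
    """Repeat the prevalence-balanced shuffle-split ``n_splits`` times.

    Positives and negatives are permuted separately with a per-split seed of
    ``(master_seed + split_id) mod 2^31``, so each split is an independent
    uniform stratified draw and re-creatable in isolation.
    """
    if n_splits < 1:
        raise ValueError(f"n_splits must be >= 1, got {n_splits}")
    labels = cohort.labels
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    counts = stratified_allocation(pos_idx.size, neg_idx.size, n_train)
    train_pos, train_neg = counts[0], counts[1]

    specs: list[SplitSpec] = []
    for split_id in range(n_splits):
        seed = _per_split_seed(master_seed, split_id)
        rng = np.random.default_rng(seed)
        pos_perm = pos_idx[rng.permutation(pos_idx.size)]
        neg_perm = neg_idx[rng.permutation(neg_idx.size)]
        train = np.sort(np.concatenate([pos_perm[:train_pos], neg_perm[:train_neg]]))
        test = np.sort(np.concatenate([pos_perm[train_pos:], neg_perm[train_neg:]]))
        spec = SplitSpec(split_id, train, test, seed, counts)
        spec.validate(labels)
        specs.append(spec)
    return specs


@dataclass
class BalanceReport:
    """Welch t-test per covariate between the two arms of one split."""

    table: pd.DataFrame  # index: covariate; columns: train_mean, test_mean, t, p_value
    alpha: float

    @property
    def any_significant(self) -> bool:
        return bool((self.table["p_value"] < self.alpha).any())

    @property
    def flags(self) -> pd.Series:
        """Per-covariate significance flags at ``alpha``."""
        return self.table["p_value"] < self.alpha


def balance_check(
    cohort: Cohort,
    split: SplitSpec,
    covariates: Sequence[str] = ("age", "lesion_size"),
    alpha: float = 0.05,
) -> BalanceReport:
    """Two-sided Welch t-tests of each covariate between train and test arms.

    No multiplicity correction is applied: each split is flagged on its own,
    matching how per-split imbalance is monitored in practice.
    """
    rows = {}
    for cov in covariates:
        if cov not in cohort.data.columns:
            raise KeyError(f"covariate {cov!r} not in cohort")
        a = cohort.data[cov].to_numpy(float)[split.train_indices]
        b = cohort.data[cov].to_numpy(float)[split.test_indices]
        if a.size == 0 or b.size == 0:
            raise UndefinedTestError("both arms must be non-empty")
        if np.var(a) == 0.0 and np.var(b) == 0.0:
            if a.mean() == b.mean():
                # identical constants: no evidence of imbalance by convention
                t, p = 0.0, 1.0
            else:
                raise UndefinedTestError(
                    f"covariate {cov!r} has zero variance in both arms"
                )
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows[cov] = {
            "train_mean": float(a.mean()),
            "test_mean": float(b.mean()),
            "t": float(t),
            "p_value": float(p),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return BalanceReport(table=table, alpha=alpha)


def splits_to_frame(cohort: Cohort, splits: Sequence[SplitSpec]) -> pd.DataFrame:
    """Long-format audit table: one row per (split_id, case_id, arm)."""
    ids = cohort.data["case_id"].to_numpy()
    frames = []
    for s in splits:
        frames.append(
            pd.DataFrame(
                {
                    "split_id": s.split_id,
                    "case_id": np.concatenate([ids[s.train_indices], ids[s.test_indices]]),
                    "arm": ["train"] * s.train_indices.size + ["test"] * s.test_indices.size,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
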