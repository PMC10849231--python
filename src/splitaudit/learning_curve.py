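"""Incremental-cohort cross-validation learning curves.

How large must the cohort be before a cross-validated AUC is a stable
estimate?  Starting from a random prevalence-preserving subset, cases are
added in fixed increments (without replacement) until the whole pool is used;
at every size the repeated nested CV is run, and this is replicated over
several independent random chains.  The spread (IQR) of the CV AUCs across
chains at each size is the instability of the estimate at that cohort size;
the curve has converged once the median stops moving by more than that
spread.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .exceptions import InfeasibleSplitError
from .model_training import CVConfig, repeated_nested_cv
from .resampling import proportional_count

__all__ = [
    "nested_cohorts",
    "cv_at_sizes",
    "LearningCurvePoint",
    "ConvergenceReport",
    "convergence_check",
    "curve_to_frame",
]

_SEED_MOD = 2**31


def nested_cohorts(
    cohort: Cohort,
    step: int = 100,
    n_cohorts: int = 20,
    seed: int = 0,
    mode: str = "nested",
) -> list[list[np.ndarray]]:
    """Chains of growing prevalence-preserving index sets.

    Each of the ``n_cohorts`` chains contains index sets of sizes
    ``step, 2*step, ..., n``; in ``nested`` mode (default) each set contains
    the previous one (growth without replacement), so the full-size set is
    always the entire cohort.  ``independent`` mode redraws every size
    freshly.  The positive count at every size follows the same proportional
    rounding as the shuffle-split allocation.
    """
    n = cohort.n_cases
    if step < 1 or n % step != 0 or n // step < 2:
        raise ValueError(f"step must divide the cohort size at least twice (n={n}, step={step})")
    if mode not in ("nested", "independent"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = cohort.labels
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    n_pos = pos_idx.size
    sizes = list(range(step, n + 1, step))
    pos_at = [proportional_count(n_pos, s, n) for s in sizes]
    if pos_at[0] < 1 or sizes[0] - pos_at[0] < 1:
        raise InfeasibleSplitError(
            f"prevalence infeasible at the smallest size {sizes[0]}"
        )

    chains: list[list[np.ndarray]] = []
    for c in range(n_cohorts):
        chain_seed = (seed + c) % _SEED_MOD
        rng = np.random.default_rng(chain_seed)
        chain: list[np.ndarray] = []
        if mode == "nested":
            pos_perm = pos_idx[rng.permutation(n_pos)]
            neg_perm = neg_idx[rng.permutation(neg_idx.size)]
            for s, p in zip(sizes, pos_at):
                chain.append(np.sort(np.concatenate([pos_perm[:p], neg_perm[: s - p]])))
        else:
            for s, p in zip(sizes, pos_at):
                pp = rng.permutation(n_pos)[:p]
                np_ = rng.permutation(neg_idx.size)[: s - p]
                chain.append(np.sort(np.concatenate([pos_idx[pp], neg_idx[np_]])))
        chains.append(chain)
    return chains


@dataclass
class LearningCurvePoint:
    """Distribution of CV AUCs at one cohort size across the random chains."""

    n_cases: int
    auc_values: np.ndarray

    @property
    def quartiles(self) -> tuple[float, float, float]:
        # linear-interpolation quantile convention, fixed for reproducibility
        q1, med, q3 = np.percentile(self.auc_values, [25, 50, 75])
        return float(q1), float(med), float(q3)

    @property
    def median(self) -> float:
        return self.quartiles[1]

    @property
    def iqr(self) -> float:
        q1, _, q3 = self.quartiles
        return q3 - q1


def cv_at_sizes(
    cohort: Cohort,
    chains: Sequence[Sequence[np.ndarray]],
    cv_config: CVConfig,
    feature_names: Sequence[str] | None = None,
) -> list[LearningCurvePoint]:
    """Run the repeated nested CV at every size of every chain.

    Index sets are canonicalised (sorted) before subsetting and the CV seed
    depends only on ``cv_config``, so identical index sets — in particular
    every chain's full-size set — give identical AUCs (the zero-spread final
    boxplot point).
    """
    n_sizes = len(chains[0])
    points: list[LearningCurvePoint] = []
    for i in range(n_sizes):
        aucs = []
        for chain in chains:
            idx = np.sort(np.asarray(chain[i], dtype=int))
            sub = cohort.subset(idx)
            outcome = repeated_nested_cv(sub, cv_config, feature_names)
            aucs.append(outcome.mean_validation_auc)
        points.append(LearningCurvePoint(n_cases=int(chains[0][i].size), auc_values=np.array(aucs)))
    return points


@dataclass
class ConvergenceReport:
    """Median-shift vs IQR comparison across consecutive cohort sizes.

    A size pair is "stable" when the shift in median AUC from the smaller to
    the larger size is no bigger than the IQR at the larger size.
    ``converged_at`` is the smallest evaluated size from which every later
    pair is stable (the smallest size overall if all pairs are), or ``None``
    if the last pair is still unstable.
    """

    table: pd.DataFrame  # columns: size_from, size_to, delta_median, iqr_at_to, stable
    converged_at: int | None


def convergence_check(points: Sequence[LearningCurvePoint]) -> ConvergenceReport:
    """Apply the |median shift| <= IQR convergence rule to a learning curve."""
    sizes = [p.n_cases for p in points]
    if len(sizes) < 3:
        raise ValueError(f"need at least 3 sizes, got {len(sizes)}")
    if sizes != sorted(set(sizes)):
        raise ValueError("sizes must be strictly increasing and unique")
    rows = []
    last_bad = -1  # pair index = index of the larger size - 1
    for i in range(1, len(points)):
        delta = abs(points[i].median - points[i - 1].median)
        iqr = points[i].iqr
        if iqr == 0.0:
            # the exhausted full-size point has zero spread by construction
            # (every chain is the whole cohort); its IQR measures nothing, so
            # the pair is judged against the smaller size's spread instead
            iqr = points[i - 1].iqr
        stable = delta <= iqr
        if not stable:
            last_bad = i - 1
        rows.append(
            {
                "size_from": sizes[i - 1],
                "size_to": sizes[i],
                "delta_median": delta,
                "iqr_at_to": iqr,
                "stable": stable,
            }
        )
    if last_bad == len(points) - 2:
        converged: int | None = None
    elif last_bad < 0:
        converged = sizes[0]
    else:
        converged = sizes[last_bad + 2]
    return ConvergenceReport(table=pd.DataFrame(rows), converged_at=converged)


def curve_to_frame(points: Sequence[LearningCurvePoint]) -> pd.DataFrame:
    """Long-format export: one row per (size, cohort replicate)."""
    rows = []
    for p in points:
        for cohort_id, a in enumerate(p.auc_values):
            rows.append({"n_cases": p.n_cases, "cohort_id": cohort_id, "auc": a})
    return pd.DataFrame(rows)
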