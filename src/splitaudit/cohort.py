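"""Synthetic cohort generation with analytically known discriminability.

The generator emulates a small single-institution case–control style cohort:
``n_cases`` patients, a binary outcome with fixed prevalence (default 16.3%,
i.e. 114 of 700 positive), two imaging-vendor strata, two nuisance covariates
(age in years, lesion size in mm) whose means differ by outcome class, and a
block of continuous "radiomic" plus "clinical" features.

Features are class-conditional multivariate Gaussians sharing one
equicorrelated covariance.  Under that binormal model the population AUC of
the optimal (oracle) linear discriminant is available in closed form,

    AUC = Phi(d / sqrt(2)),

where ``d`` is the Mahalanobis distance between the class means and ``Phi``
the standard normal CDF.  The class-mean difference is rescaled so that ``d``
hits any requested target AUC exactly, which makes every downstream stage of
the audit testable against a known ground truth.

Vendor membership is independent of the outcome; each non-reference vendor
applies a fixed location/scale offset to all features, so per-vendor
standardization genuinely matters but never carries label information.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ConfigurationError

__all__ = [
    "GeneratorParams",
    "Cohort",
    "population_auc_from_separation",
    "separation_for_target_auc",
    "generate_cohort",
    "oracle_scores",
    "oracle_auc",
]

#: column order of the canonical cohort CSV, before the feature block
META_COLUMNS = ["case_id", "vendor", "label", "age", "lesion_size"]


def population_auc_from_separation(mahalanobis_distance: float) -> float:
    """Population AUC of the oracle discriminant at class separation ``d``.

    For two Gaussian classes sharing a covariance and separated by
    Mahalanobis distance ``d``, the optimal linear score is itself binormal
    with unit-variance classes ``d`` apart, so AUC = Phi(d / sqrt(2)).
    """
    d = float(mahalanobis_distance)
    if not np.isfinite(d) or d < 0:
        raise ValueError(f"Mahalanobis distance must be >= 0, got {mahalanobis_distance!r}")
    return float(norm.cdf(d / np.sqrt(2.0)))


def separation_for_target_auc(target_auc: float) -> float:
    """Mahalanobis separation achieving ``target_auc``; inverse of the above."""
    a = float(target_auc)
    if not (0.5 <= a < 1.0):
        raise ValueError(f"target AUC must lie in [0.5, 1), got {target_auc!r}")
    return float(np.sqrt(2.0) * norm.ppf(a))


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the study conditions of the audited design: 700 cases
    at 16.3% prevalence, 109 radiomic + 4 clinical features, two vendors in
    equal proportion, and a population AUC of 0.70 for the oracle linear
    discriminant.
    """

    n_cases: int = 700
    prevalence: float = 0.163
    n_radiomic: int = 109
    n_clinical: int = 4
    target_population_auc: float = 0.70
    feature_correlation: float = 0.3
    n_informative_radiomic: int = 20
    n_informative_clinical: int = 3
    vendor_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"GE": 0.5, "Hologic": 0.5}
    )
    # (additive location, multiplicative scale) applied to every feature of a
    # vendor's cases; the reference vendor must map to (0, 1)
    vendor_offsets: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"GE": (0.0, 1.0), "Hologic": (0.3, 1.15)}
    )
    age_mean_by_class: tuple[float, float] = (62.0, 66.0)  # (negative, positive), years
    age_sd: float = 10.0
    lesion_size_mean_by_class: tuple[float, float] = (12.0, 16.0)  # mm
    lesion_size_sd: tuple[float, float] = (6.0, 8.0)  # (negative, positive)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0:
            raise ConfigurationError("n_cases must be positive")
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigurationError("prevalence must lie in (0, 1)")
        if self.n_positive < 1 or self.n_positive >= self.n_cases:
            raise ConfigurationError(
                "prevalence x n_cases must round to a positive count below n_cases"
            )
        if not (0.5 <= self.target_population_auc < 1.0):
            raise ConfigurationError("target_population_auc must lie in [0.5, 1)")
        if not (0.0 <= self.feature_correlation < 1.0):
            raise ConfigurationError(
                "feature_correlation must lie in [0, 1) to keep the covariance positive definite"
            )
        if self.n_radiomic < 1 or self.n_clinical < 0:
            raise ConfigurationError("need at least one radiomic feature")
        if not (1 <= self.n_informative_radiomic <= self.n_radiomic):
            raise ConfigurationError("n_informative_radiomic out of range")
        if not (0 <= self.n_informative_clinical <= self.n_clinical):
            raise ConfigurationError("n_informative_clinical out of range")
        total = sum(self.vendor_fractions.values())
        if abs(total - 1.0) > 1e-9 or any(v <= 0 for v in self.vendor_fractions.values()):
            raise ConfigurationError("vendor_fractions must be positive and sum to 1")
        for v in self.vendor_fractions:
            if v not in self.vendor_offsets:
                raise ConfigurationError(f"no vendor offset declared for vendor {v!r}")
        for v, (_, scale) in self.vendor_offsets.items():
            if scale <= 0:
                raise ConfigurationError(f"vendor scale for {v!r} must be positive")

    @property
    def n_positive(self) -> int:
        # round half up; 0.163 * 700 = 114.1 -> 114
        return int(np.floor(self.prevalence * self.n_cases + 0.5))

    @property
    def n_features(self) -> int:
        return self.n_radiomic + self.n_clinical

    @property
    def radiomic_names(self) -> list[str]:
        return [f"f_{i + 1:03d}" for i in range(self.n_radiomic)]

    @property
    def clinical_names(self) -> list[str]:
        return [f"c_{i + 1:03d}" for i in range(self.n_clinical)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["vendor_fractions"] = dict(self.vendor_fractions)
        d["vendor_offsets"] = {k: list(v) for k, v in self.vendor_offsets.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorParams":
        d = dict(d)
        if "vendor_offsets" in d:
            d["vendor_offsets"] = {k: tuple(v) for k, v in d["vendor_offsets"].items()}
        for key in ("age_mean_by_class", "lesion_size_mean_by_class", "lesion_size_sd"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Cohort:
    """A case-level table plus the names of its feature columns.

    ``data`` holds one row per case with columns ``case_id``, ``vendor``,
    ``label`` (1 = positive/upstaged), ``age``, ``lesion_size`` and the
    feature block (radiomic then clinical).
    """

    data: pd.DataFrame
    radiomic_features: list[str]
    clinical_features: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS + self.feature_names if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"cohort table missing columns: {missing}")
        labels = self.data["label"].to_numpy()
        if not np.isin(labels, [0, 1]).all():
            raise ConfigurationError("labels must be binary 0/1")
        numeric = self.data[["age", "lesion_size"] + self.feature_names]
        if numeric.isna().any().any() or not np.isfinite(numeric.to_numpy(float)).all():
            raise ConfigurationError("cohort contains missing or non-finite values")

    @property
    def feature_names(self) -> list[str]:
        return list(self.radiomic_features) + list(self.clinical_features)

    @property
    def n_cases(self) -> int:
        return len(self.data)

    @property
    def labels(self) -> np.ndarray:
        return self.data["label"].to_numpy(int)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def prevalence(self) -> float:
        return self.n_positive / self.n_cases

    @property
    def vendors(self) -> np.ndarray:
        return self.data["vendor"].to_numpy()

    def feature_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Feature block as a float array, optionally restricted to ``names``."""
        cols = self.feature_names if names is None else list(names)
        unknown = [c for c in cols if c not in self.feature_names]
        if unknown:
            raise ConfigurationError(f"unknown feature columns: {unknown}")
        return self.data[cols].to_numpy(float)

    def subset(self, indices: Sequence[int]) -> "Cohort":
        """New cohort restricted to integer row positions ``indices``."""
        sub = self.data.iloc[np.asarray(indices, dtype=int)].reset_index(drop=True)
        return Cohort(sub, list(self.radiomic_features), list(self.clinical_features))

    def copy(self) -> "Cohort":
        return Cohort(self.data.copy(), list(self.radiomic_features), list(self.clinical_features))


def _effect_direction(params: GeneratorParams) -> np.ndarray:
    """Unscaled class-mean difference: 1 on informative features, 0 elsewhere."""
    delta = np.zeros(params.n_features)
    delta[: params.n_informative_radiomic] = 1.0
    if params.n_informative_clinical:
        delta[params.n_radiomic : params.n_radiomic + params.n_informative_clinical] = 1.0
    return delta


def _equicorrelated_solve(delta: np.ndarray, rho: float) -> np.ndarray:
    """Sigma^{-1} delta for Sigma = (1-rho) I + rho 11', computed in O(p)."""
    p = delta.size
    correction = rho * delta.sum() / (1.0 + (p - 1) * rho)
    return (delta - correction) / (1.0 - rho)


def class_mean_difference(params: GeneratorParams) -> np.ndarray:
    """Class-mean difference vector scaled to the target Mahalanobis norm."""
    delta = _effect_direction(params)
    m2 = float(delta @ _equicorrelated_solve(delta, params.feature_correlation))
    d = separation_for_target_auc(params.target_population_auc)
    if d == 0.0:
        return np.zeros_like(delta)
    return delta * (d / np.sqrt(m2))


def oracle_direction(params: GeneratorParams) -> np.ndarray:
    """Optimal linear discriminant direction Sigma^{-1} (mu1 - mu0)."""
    return _equicorrelated_solve(class_mean_difference(params), params.feature_correlation)


def generate_cohort(params: GeneratorParams) -> Cohort:
    """Draw one synthetic cohort; identical params (incl. seed) => identical table.

    Exactly ``round(prevalence * n_cases)`` rows carry label 1.  Features are
    drawn on a latent standardized scale, the scaled class-mean difference is
    added to positives, and each vendor's fixed location/scale offset is then
    applied.  Vendor, age and lesion size are drawn independently of the
    features given the label.
    """
    rng = np.random.default_rng(params.seed)
    n, p = params.n_cases, params.n_features
    n_pos = params.n_positive

    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    labels = labels[rng.permutation(n)]

    rho = params.feature_correlation
    # equicorrelated draw: z = sqrt(rho) * g + sqrt(1-rho) * eps, unit marginals
    g = rng.standard_normal(n)
    eps = rng.standard_normal((n, p))
    latent = np.sqrt(rho) * g[:, None] + np.sqrt(1.0 - rho) * eps
    latent[labels == 1] += class_mean_difference(params)

    vendor_names = list(params.vendor_fractions)
    fractions = np.array([params.vendor_fractions[v] for v in vendor_names])
    vendors = rng.choice(vendor_names, size=n, p=fractions / fractions.sum())

    features = latent.copy()
    for v in vendor_names:
        loc, scale = params.vendor_offsets[v]
        mask = vendors == v
        features[mask] = loc + scale * latent[mask]

    neg_age, pos_age = params.age_mean_by_class
    age = np.where(labels == 1, pos_age, neg_age) + params.age_sd * rng.standard_normal(n)
    neg_ls, pos_ls = params.lesion_size_mean_by_class
    sd_neg, sd_pos = params.lesion_size_sd
    lesion = np.where(labels == 1, pos_ls, neg_ls) + np.where(
        labels == 1, sd_pos, sd_neg
    ) * rng.standard_normal(n)
    lesion = np.maximum(lesion, 1.0)  # physical floor, 1 mm

    width = len(str(n))
    table = pd.DataFrame(
        {
            "case_id": [f"case_{i + 1:0{width}d}" for i in range(n)],
            "vendor": vendors,
            "label": labels,
            "age": age,
            "lesion_size": lesion,
        }
    )
    feat = pd.DataFrame(features, columns=params.radiomic_names + params.clinical_names)
    table = pd.concat([table, feat], axis=1)
    return Cohort(table, params.radiomic_names, params.clinical_names)


def oracle_scores(cohort: Cohort, params: GeneratorParams) -> np.ndarray:
    """Score each case with the true (population-optimal) linear discriminant.

    Vendor offsets are removed exactly using the generator's parameters, so
    the scores are binormal with the calibrated separation by construction.
    """
    x = cohort.feature_matrix()
    latent = np.empty_like(x)
    vendors = cohort.vendors
    for v in np.unique(vendors):
        if v not in params.vendor_offsets:
            raise ConfigurationError(f"vendor {v!r} has no declared offsets")
        loc, scale = params.vendor_offsets[v]
        mask = vendors == v
        latent[mask] = (x[mask] - loc) / scale
    return latent @ oracle_direction(params)


def oracle_auc(cohort: Cohort, params: GeneratorParams) -> float:
    """Empirical AUC of the oracle discriminant on this cohort."""
    from .evaluation import auc

    return auc(oracle_scores(cohort, params), cohort.labels)
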