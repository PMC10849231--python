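"""Per-vendor feature standardization.

Features are z-scored separately within each imaging-vendor stratum, the only
preprocessing the audited design applies.  Fitting can be restricted to the
training arm (``train_only``, the default, leakage-free) or computed over the
whole table (``whole_dataset``), and uses the population variance convention
(1/n) by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import Cohort
from .exceptions import DegenerateFeatureError, MissingStratumError

__all__ = ["VendorStandardizer", "fit_standardizer", "apply_standardizer"]

_EPS = 0.0  # exact zero-variance check; degenerate features are an error, not a fudge


def vendor_stats(
    x: np.ndarray, vendors: np.ndarray, ddof: int = 0
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-vendor (mean, sd) arrays over the rows of ``x``. Array-level core
    shared by :class:`VendorStandardizer` and the nested-CV hot loop."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for v in np.unique(vendors):
        rows = x[vendors == v]
        if rows.shape[0] < 2:
            raise DegenerateFeatureError(
                f"vendor {v!r} has fewer than 2 cases on the fit set"
            )
        mean = rows.mean(axis=0)
        sd = rows.std(axis=0, ddof=ddof)
        out[str(v)] = (mean, sd)
    return out


def apply_vendor_stats(
    x: np.ndarray,
    vendors: np.ndarray,
    stats: dict[str, tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Standardize rows of ``x`` with previously fitted per-vendor stats."""
    out = np.empty_like(x, dtype=float)
    for v in np.unique(vendors):
        key = str(v)
        if key not in stats:
            raise MissingStratumError(f"vendor {key!r} was not present at fit time")
        mean, sd = stats[key]
        mask = vendors == v
        out[mask] = (x[mask] - mean) / sd
    return out


@dataclass
class VendorStandardizer:
    """Fitted per-(vendor, feature) centering/scaling parameters.

    Parameters
    ----------
    fit_scope
        ``"train_only"`` fits on the supplied index set only;
        ``"whole_dataset"`` ignores the index set and fits on every row.
    ddof
        Variance convention: 0 for population (default), 1 for sample.
    """

    fit_scope: str = "train_only"
    ddof: int = 0
    feature_names: list[str] = field(default_factory=list)
    stats_: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def fit(self, cohort: Cohort, fit_indices: Sequence[int] | None = None) -> "VendorStandardizer":
        if self.fit_scope not in ("train_only", "whole_dataset"):
            raise ValueError(f"unknown fit scope {self.fit_scope!r}")
        if self.fit_scope == "whole_dataset" or fit_indices is None:
            idx = np.arange(cohort.n_cases)
        else:
            idx = np.asarray(fit_indices, dtype=int)
        self.feature_names = (
            list(self.feature_names) if self.feature_names else cohort.feature_names
        )
        x = cohort.feature_matrix(self.feature_names)[idx]
        vendors = cohort.vendors[idx]
        stats = vendor_stats(x, vendors, ddof=self.ddof)
        for v, (_, sd) in stats.items():
            zero = np.flatnonzero(sd <= _EPS)
            if zero.size:
                name = self.feature_names[zero[0]]
                raise DegenerateFeatureError(
                    f"feature {name!r} is constant within vendor {v!r} on the fit set"
                )
        self.stats_ = stats
        return self

    def transform(self, cohort: Cohort) -> Cohort:
        """Standardized copy; labels and covariates untouched."""
        self._check_fitted()
        x = cohort.feature_matrix(self.feature_names)
        z = apply_vendor_stats(x, cohort.vendors, self.stats_)
        out = cohort.copy()
        out.data[self.feature_names] = z
        return out

    def transform_matrix(self, x: np.ndarray, vendors: np.ndarray) -> np.ndarray:
        self._check_fitted()
        return apply_vendor_stats(x, vendors, self.stats_)

    def inverse_transform(self, cohort: Cohort) -> Cohort:
        self._check_fitted()
        z = cohort.feature_matrix(self.feature_names)
        x = np.empty_like(z)
        vendors = cohort.vendors
        for v in np.unique(vendors):
            key = str(v)
            if key not in self.stats_:
                raise MissingStratumError(f"vendor {key!r} was not present at fit time")
            mean, sd = self.stats_[key]
            mask = vendors == v
            x[mask] = z[mask] * sd + mean
        out = cohort.copy()
        out.data[self.feature_names] = x
        return out

    def _check_fitted(self) -> None:
        if not self.stats_:
            raise ValueError("standardizer is not fitted")

    # -- audit serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "fit_scope": self.fit_scope,
            "ddof": self.ddof,
            "feature_names": list(self.feature_names),
            "stats": {
                v: {"mean": m.tolist(), "sd": s.tolist()} for v, (m, s) in self.stats_.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VendorStandardizer":
        obj = cls(fit_scope=d["fit_scope"], ddof=d["ddof"], feature_names=list(d["feature_names"]))
        obj.stats_ = {
            v: (np.asarray(s["mean"], float), np.asarray(s["sd"], float))
            for v, s in d["stats"].items()
        }
        return obj

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "VendorStandardizer":
        return cls.from_dict(json.loads(s))


def fit_standardizer(
    cohort: Cohort,
    fit_indices: Sequence[int] | None = None,
    scope: str = "train_only",
    ddof: int = 0,
    feature_names: Sequence[str] | None = None,
) -> VendorStandardizer:
    """Fit per-vendor z-scoring parameters on ``fit_indices`` (or all rows)."""
    std = VendorStandardizer(
        fit_scope=scope, ddof=ddof, feature_names=list(feature_names or [])
    )
    return std.fit(cohort, fit_indices)


def apply_standardizer(cohort: Cohort, params: VendorStandardizer) -> Cohort:
    """Standardized copy of ``cohort`` under previously fitted parameters."""
    return params.transform(cohort)
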