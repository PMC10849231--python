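"""Cohort CSV round-tripping and YAML audit configuration.

Cohort schema (UTF-8 CSV, header mandatory, '.' decimal separator)::

    case_id, vendor, label, age, lesion_size, f_001..f_NNN, c_001..c_NNN

``f_*`` columns are the radiomic block, ``c_*`` the clinical block; ``label``
is strictly 0/1 and ``case_id`` unique.  Violations raise
:class:`~splitaudit.exceptions.SchemaError` with the offending row/column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import META_COLUMNS, Cohort, GeneratorParams
from .exceptions import SchemaError
from .model_training import CVConfig, HyperparamGrid

__all__ = ["read_cohort", "write_cohort", "AuditConfig", "load_config", "save_config"]

_FLOAT_FMT = "%.12g"


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort table as the canonical CSV (lossless round-trip)."""
    cols = META_COLUMNS + cohort.feature_names
    cohort.data[cols].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cohort(path: str | Path) -> Cohort:
    """Read and validate a cohort CSV against the documented schema."""
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SchemaError(f"cannot parse {path}: {exc}") from exc

    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    extra = [c for c in table.columns if c not in META_COLUMNS]
    radiomic = [c for c in extra if c.startswith("f_")]
    clinical = [c for c in extra if c.startswith("c_")]
    unknown = [c for c in extra if c not in radiomic + clinical]
    if unknown:
        raise SchemaError(f"unrecognised columns (expect f_*/c_* features): {unknown}")
    if not radiomic and not clinical:
        raise SchemaError("cohort has no feature columns")

    dup = table["case_id"][table["case_id"].duplicated()]
    if not dup.empty:
        raise SchemaError(f"duplicate case_id values: {sorted(set(dup.astype(str)))[:5]}")

    labels = table["label"]
    bad = table.loc[~labels.isin([0, 1]), "case_id"]
    if not bad.empty:
        raise SchemaError(
            f"label must be 0/1; offending case_id values: {list(bad.astype(str))[:5]}"
        )

    numeric_cols = ["age", "lesion_size"] + radiomic + clinical
    for col in numeric_cols:
        values = pd.to_numeric(table[col], errors="coerce")
        if values.isna().any():
            row = int(values.index[values.isna()][0])
            raise SchemaError(f"non-numeric or missing value in column {col!r}, row {row}")
        table[col] = values.astype(float)
    if not np.isfinite(table[numeric_cols].to_numpy()).all():
        raise SchemaError("cohort contains non-finite values")
    table["label"] = table["label"].astype(int)
    table["vendor"] = table["vendor"].astype(str)
    return Cohort(table, radiomic, clinical)


@dataclass
class ModelPlan:
    """One model variant of the audit: which features, which classifier."""

    label: str
    features: str | list[str] = "all"  # "clinical" | "radiomics" | "all" | explicit list
    classifier_kind: str = "logistic_l2"
    feature_selection: str = "none"

    def resolve_features(self, cohort: Cohort) -> list[str]:
        if isinstance(self.features, str):
            if self.features == "clinical":
                return list(cohort.clinical_features)
            if self.features == "radiomics":
                return list(cohort.radiomic_features)
            if self.features == "all":
                return cohort.feature_names
            raise SchemaError(f"unknown feature selector {self.features!r}")
        unknown = [f for f in self.features if f not in cohort.feature_names]
        if unknown:
            raise SchemaError(f"model {self.label!r} references unknown features {unknown}")
        return list(self.features)


def default_model_plans() -> list[ModelPlan]:
    """The four audited variants: clinical only, radiomics only, combined,
    and radiomics with stability feature selection."""
    return [
        ModelPlan("clinical", "clinical"),
        ModelPlan("radiomics", "radiomics"),
        ModelPlan("radiomics+clinical", "all"),
        ModelPlan("radiomics+selection", "radiomics", feature_selection="stability"),
    ]


@dataclass
class AuditConfig:
    """Single source of truth for a full audit run."""

    generator: GeneratorParams | None = None
    cohort_path: str | None = None
    n_train: int = 400
    n_splits: int = 50
    master_seed: int = 0
    models: list[ModelPlan] = field(default_factory=default_model_plans)
    cv: CVConfig = field(default_factory=CVConfig)
    alpha: float = 0.05
    n_permutations: int = 10_000
    lc_step: int = 100
    lc_n_cohorts: int = 20
    lc_seed: int = 0

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.cohort_path is None):
            raise SchemaError("exactly one of generator / cohort_path must be set")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "generator": None if self.generator is None else self.generator.to_dict(),
            "cohort_path": self.cohort_path,
            "resampling": {
                "n_train": self.n_train,
                "n_splits": self.n_splits,
                "master_seed": self.master_seed,
            },
            "models": [asdict(m) for m in self.models],
            "cv": asdict(self.cv),
            "evaluation": {"alpha": self.alpha, "n_permutations": self.n_permutations},
            "learning_curve": {
                "step": self.lc_step,
                "n_cohorts": self.lc_n_cohorts,
                "seed": self.lc_seed,
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AuditConfig":
        res = d.get("resampling", {})
        ev = d.get("evaluation", {})
        lc = d.get("learning_curve", {})
        cv = dict(d.get("cv", {}))
        if "grid" in cv and isinstance(cv["grid"], Mapping):
            grid = dict(cv["grid"])
            for key in ("c_values", "kernels", "svm_c_values", "gamma_values"):
                if key in grid:
                    grid[key] = tuple(grid[key])
            cv["grid"] = HyperparamGrid(**grid)
        return cls(
            generator=(
                GeneratorParams.from_dict(d["generator"]) if d.get("generator") else None
            ),
            cohort_path=d.get("cohort_path"),
            n_train=int(res.get("n_train", 400)),
            n_splits=int(res.get("n_splits", 50)),
            master_seed=int(res.get("master_seed", 0)),
            models=[ModelPlan(**m) for m in d.get("models", [])] or default_model_plans(),
            cv=CVConfig(**cv),
            alpha=float(ev.get("alpha", 0.05)),
            n_permutations=int(ev.get("n_permutations", 10_000)),
            lc_step=int(lc.get("step", 100)),
            lc_n_cohorts=int(lc.get("n_cohorts", 20)),
            lc_seed=int(lc.get("seed", 0)),
        )


def load_config(path: str | Path) -> AuditConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return AuditConfig.from_dict(yaml.safe_load(fh))


def save_config(config: AuditConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
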