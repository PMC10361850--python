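"""Cohort CSV reading/validation and dummy encoding of the design matrix."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (
    COLUMNS,
    COVARIATES,
    FLAG_COLUMNS,
    INT_COLUMNS,
    LEVELS,
    alias_table,
    coerce_frame,
)


class SchemaError(ValueError):
    """Input violates the canonical cohort schema (missing columns etc.)."""


@dataclass
class ValidationReport:
    """Record-level validation findings collected while reading a cohort."""

    n_records: int = 0
    violations: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(vars(self), indent=2, sort_keys=True))


def _apply_aliases(series: pd.Series, var: str) -> pd.Series:
    aliases = alias_table().get(var, {})
    if not aliases:
        return series
    lowered = {str(k).lower(): v for k, v in aliases.items()}
    return series.map(lambda v: lowered.get(str(v).lower(), v))


def read_cohort(
    path: str | Path, country: str | None = None
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read a registry CSV into a validated canonical cohort frame.

    Registry spellings are mapped through the alias table; undeclared levels
    after aliasing are collected into the report (the offending rows are kept,
    with the level left as NaN in the categorical).  ``country`` overrides the
    file's country column when given.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in frame.columns and c != "country"]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    if country is not None:
        frame["country"] = country
    elif "country" not in frame.columns:
        raise SchemaError("no country column and no country argument")

    report = ValidationReport(n_records=len(frame))
    if frame.empty:
        return coerce_frame(frame.reindex(columns=COLUMNS)), report

    for var in COVARIATES:
        frame[var] = _apply_aliases(frame[var], var)
        bad = ~frame[var].isin(LEVELS[var])
        for idx in frame.index[bad]:
            report.violations.append(
                {"row": int(idx), "column": var, "value": frame.at[idx, var]}
            )
    truthy = {"true", "1", "yes", "t"}
    for col in FLAG_COLUMNS:
        frame[col] = frame[col].str.lower().isin(truthy)
    for col in INT_COLUMNS:
        frame[col] = pd.to_numeric(frame[col], errors="coerce").fillna(0)

    out = coerce_frame(frame[COLUMNS])
    # cross-field checks: warn-only for MRI-around-PST without PST
    n_orphan_mri = int((out["mri_around_pst"] & ~out["pst"]).sum())
    if n_orphan_mri:
        report.warnings.append(
            f"{n_orphan_mri} records have mri_around_pst without pst"
        )
    bad_ir = out["immediate_reconstruction"] & ~out["mastectomy"]
    for idx in out.index[bad_ir]:
        report.violations.append(
            {"row": int(idx), "column": "immediate_reconstruction",
             "value": "set without mastectomy"}
        )
    bad_ops = out["any_operation"] & (out["n_breast_operations"] < 1)
    for idx in out.index[bad_ops]:
        report.violations.append(
            {"row": int(idx), "column": "n_breast_operations",
             "value": "0 despite any_operation"}
        )
    return out, report


def write_cohort(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort frame as canonical UTF-8 comma-delimited CSV."""
    frame.reindex(columns=COLUMNS).to_csv(path, index=False)


@dataclass
class DesignMatrix:
    """Intercept + dummy-coded covariate matrix for the propensity model.

    Each categorical variable contributes (levels - 1) columns named
    ``var=level``; the first declared level is the reference.
    """

    column_names: list[str]
    values: np.ndarray
    row_index: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def encode(
    frame: pd.DataFrame,
    covariates: list[str] | None = None,
    drop_constant: bool = True,
) -> DesignMatrix:
    """Dummy-encode ``covariates`` of a cohort frame.

    With ``drop_constant`` (the default for standalone use) a covariate whose
    observed values are all identical contributes zero columns and a warning —
    its dummies would be collinear with the intercept.  Federated fits encode
    with ``drop_constant=False`` so that every node produces the same column
    set regardless of which levels it happens to contain.
    """
    if frame.empty:
        raise ValueError("cannot encode an empty cohort")
    covariates = list(covariates or COVARIATES)
    unknown = [c for c in covariates if c not in LEVELS]
    if unknown:
        raise SchemaError(f"unknown covariates: {unknown}")

    names = ["intercept"]
    cols = [np.ones(len(frame))]
    for var in covariates:
        observed = frame[var].astype(str)
        if drop_constant and observed.nunique() == 1:
            warnings.warn(
                f"covariate {var!r} is constant in this cohort; "
                "contributing no columns",
                stacklevel=2,
            )
            continue
        for level in LEVELS[var][1:]:
            names.append(f"{var}={level}")
            cols.append((observed == level).to_numpy(dtype=float))
    values = np.column_stack(cols)
    return DesignMatrix(names, values, frame.index.to_numpy())
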