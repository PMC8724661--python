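"""Long-format longitudinal data container and per-subject design matrices.

The canonical dataset holds one row per subject-visit: a subject key, visit
time in months, a continuous response (e.g. square-root CD4 count), and named
covariate columns (baseline BMI, log baseline viral load, a time-varying
antiretroviral-therapy indicator, baseline age).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray

#: term vocabulary resolved against columns by build_designs
STRUCTURAL_TERMS = ("intercept", "time", "sqrt_time")

DEFAULT_FIXED_TERMS = ("intercept", "time", "sqrt_time", "bmi", "lvl", "art", "age")
DEFAULT_RANDOM_TERMS = ("intercept", "time", "sqrt_time")


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


@dataclass
class LongitudinalDataset:
    """Long-format repeated measures, sorted by (subject, time)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject", "time", "response"}
        missing = required - set(self.frame.columns)
        if missing:
            raise SchemaError(f"missing required columns: {sorted(missing)}")
        self.frame = (
            self.frame.sort_values(["subject", "time"], kind="mergesort")
            .reset_index(drop=True)
        )

    @property
    def n_subjects(self) -> int:
        return self.frame["subject"].nunique()

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("subject", "time", "response")]

    def groups(self):
        return self.frame.groupby("subject", sort=True)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def __eq__(self, other) -> bool:  # value equality for round-trip tests
        if not isinstance(other, LongitudinalDataset):
            return NotImplemented
        return self.frame.equals(other.frame)


@dataclass
class ModelSpec:
    """Quantile level plus ordered fixed- and random-effect term lists.

    Terms are either structural (``intercept``, ``time``, ``sqrt_time``) or
    covariate column names.  An empty ``random_terms`` degenerates to a
    fixed-effects-only quantile regression.
    """

    tau: float = 0.5
    fixed_terms: tuple[str, ...] = DEFAULT_FIXED_TERMS
    random_terms: tuple[str, ...] = DEFAULT_RANDOM_TERMS

    def __post_init__(self) -> None:
        if not (0.0 < self.tau < 1.0):
            raise ValueError(f"tau must lie in (0, 1); got {self.tau!r}")
        self.fixed_terms = tuple(self.fixed_terms)
        self.random_terms = tuple(self.random_terms)
        if not self.fixed_terms:
            raise ValueError("fixed_terms must be nonempty")

    def with_tau(self, tau: float) -> "ModelSpec":
        return ModelSpec(tau=tau, fixed_terms=self.fixed_terms, random_terms=self.random_terms)

    @property
    def p(self) -> int:
        return len(self.fixed_terms)

    @property
    def r(self) -> int:
        return len(self.random_terms)


@dataclass
class DesignBundle:
    """Per-subject fixed/random design matrices and responses."""

    subjects: list
    X: list  # n_i x p
    Z: list  # n_i x r
    y: list  # n_i
    fixed_terms: tuple[str, ...]
    random_terms: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def N(self) -> int:
        return sum(len(yi) for yi in self.y)

    @property
    def p(self) -> int:
        return len(self.fixed_terms)

    @property
    def r(self) -> int:
        return len(self.random_terms)

    def stacked(self) -> tuple[NDArray, NDArray]:
        return np.vstack(self.X), np.concatenate(self.y)


def load_long_csv(path, column_map: dict[str, str] | None = None) -> LongitudinalDataset:
    """Read a long-format CSV into a :class:`LongitudinalDataset`.

    ``column_map`` maps canonical names (``subject``, ``time``, ``response``,
    covariates) to the file's column headers; identity by default.
    """
    raw = pd.read_csv(path)
    if column_map:
        rename = {src: canonical for canonical, src in column_map.items()}
        missing = set(rename) - set(raw.columns)
        if missing:
            raise SchemaError(f"mapped columns absent from file: {sorted(missing)}")
        raw = raw.rename(columns=rename)
    for col in ("time", "response"):
        if col not in raw.columns:
            raise SchemaError(f"missing required column {col!r}")
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & ~raw[col].isna()
        if bad.any() or raw[col].isna().any():
            idx = int(np.flatnonzero(coerced.isna())[0])
            raise SchemaError(f"non-numeric or missing {col!r} at row {idx}")
        raw[col] = coerced
    return LongitudinalDataset(raw)


@dataclass
class ValidationReport:
    n_subjects: int
    n_obs: int
    obs_per_subject_min: int
    obs_per_subject_max: int
    obs_per_subject_median: float
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate(ds: LongitudinalDataset, strict: bool = False) -> ValidationReport:
    """Diagnostics on sample sizes and invariants.

    Checks: finite nonnegative times, finite responses, and monotone
    (0 -> 1, never back) therapy indicator within subject when an ``art``
    column is present.  ``strict=True`` raises on any violation.
    """
    f = ds.frame
    violations: list[str] = []
    if len(f) == 0:
        report = ValidationReport(0, 0, 0, 0, float("nan"), ["empty dataset (N=0)"])
        if strict:
            raise ValueError("; ".join(report.violations))
        return report
    if not np.isfinite(f["time"]).all() or (f["time"] < 0).any():
        violations.append("time must be finite and nonnegative")
    if not np.isfinite(f["response"]).all():
        violations.append("response must be finite")
    if "art" in f.columns:
        for sid, g in ds.groups():
            art = g["art"].to_numpy()
            if np.any(np.diff(art) < 0):
                violations.append(f"subject {sid!r}: therapy indicator decreases over time")
    counts = f.groupby("subject").size()
    report = ValidationReport(
        n_subjects=ds.n_subjects,
        n_obs=ds.n_obs,
        obs_per_subject_min=int(counts.min()),
        obs_per_subject_max=int(counts.max()),
        obs_per_subject_median=float(counts.median()),
        violations=violations,
    )
    if strict and violations:
        raise ValueError("; ".join(violations))
    return report


def _realize_terms(g: pd.DataFrame, terms: tuple[str, ...], columns) -> NDArray:
    n = len(g)
    cols = []
    for term in terms:
        if term == "intercept":
            cols.append(np.ones(n))
        elif term == "time":
            cols.append(g["time"].to_numpy(dtype=float))
        elif term == "sqrt_time":
            t = g["time"].to_numpy(dtype=float)
            if np.any(t < 0):
                raise ValueError("sqrt_time term requires nonnegative times")
            cols.append(np.sqrt(t))
        elif term in columns:
            cols.append(g[term].to_numpy(dtype=float))
        else:
            raise SchemaError(f"unknown model term {term!r}")
    return np.column_stack(cols) if cols else np.empty((n, 0))


def build_designs(ds: LongitudinalDataset, spec: ModelSpec) -> DesignBundle:
    """Realize per-subject X_i, Z_i, y_i in the spec's term order."""
    columns = set(ds.frame.columns)
    subjects, X, Z, y = [], [], [], []
    for sid, g in ds.groups():
        subjects.append(sid)
        X.append(_realize_terms(g, spec.fixed_terms, columns))
        Z.append(_realize_terms(g, spec.random_terms, columns))
        y.append(g["response"].to_numpy(dtype=float))
    return DesignBundle(
        subjects=subjects,
        X=X,
        Z=Z,
        y=y,
        fixed_terms=spec.fixed_terms,
        random_terms=spec.random_terms,
    )
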