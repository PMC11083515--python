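"""Allometric mass prediction by multiple linear regression.

Body mass M (g) is modelled as a linear function of a subset of the five
shell measurements (mm),

    M = b0 + sum_k b_k * x_k,        x_k in {LC, WC, LF, LP, WP},

fitted by ordinary least squares.  The canonical predictor subsets compared
for this species are {LC, WC}, {LP, WP} and {LP, WP, LF}.

Fit quality is reported with the standard regression metrics: coefficient
of determination R^2 = 1 - SS_res/SS_tot, mean absolute error, mean squared
error, root mean squared error, and the maximum per-sample absolute
relative error in percent (MaxRE), which bounds the worst-case grading
mistake a mass-based sorter would make.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import CollinearityError, InputError, MissingFieldError
from .morphometry import LENGTH_FIELDS, MorphometricRecord


@dataclass(frozen=True)
class MassModel:
    """Fitted linear mass model: ``mass = intercept + coefficients . x``."""

    predictors: tuple[str, ...]
    intercept: float
    coefficients: tuple[float, ...]

    def __post_init__(self):
        if not self.predictors:
            raise InputError("predictors must be non-empty")
        if len(set(self.predictors)) != len(self.predictors):
            raise InputError("duplicate predictors")
        unknown = set(self.predictors) - set(LENGTH_FIELDS)
        if unknown:
            raise InputError(f"unknown predictors: {sorted(unknown)}")
        if len(self.coefficients) != len(self.predictors):
            raise InputError("coefficient count must equal predictor count")

    def to_json(self) -> str:
        return json.dumps(
            {
                "predictors": list(self.predictors),
                "intercept": self.intercept,
                "coefficients": list(self.coefficients),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "MassModel":
        d = json.loads(s)
        return cls(
            predictors=tuple(d["predictors"]),
            intercept=float(d["intercept"]),
            coefficients=tuple(float(c) for c in d["coefficients"]),
        )


@dataclass(frozen=True)
class FitReport:
    """Regression quality metrics (mass units: grams)."""

    r2: float
    mae: float
    mse: float
    rmse: float
    max_re: float
    n: int


def _design(records: list[MorphometricRecord], predictors) -> tuple[np.ndarray, np.ndarray]:
    predictors = tuple(predictors)
    X = np.empty((len(records), len(predictors)), dtype=np.float64)
    y = np.empty(len(records), dtype=np.float64)
    for i, r in enumerate(records):
        missing = [p for p in predictors if getattr(r, p) is None]
        if missing:
            raise MissingFieldError(missing)
        if r.mass is None:
            raise MissingFieldError(["mass"])
        X[i] = [getattr(r, p) for p in predictors]
        y[i] = r.mass
    return X, y


def fit_mass_model(records: list[MorphometricRecord], predictors) -> MassModel:
    """Ordinary least squares fit of mass on the given predictor subset.

    Deterministic; raises :class:`CollinearityError` naming the dependent
    columns when the design matrix (with intercept) is rank deficient, and
    an error when there are too few records.
    """
    predictors = tuple(predictors)
    if len(set(predictors)) != len(predictors):
        dupes = sorted({p for p in predictors if predictors.count(p) > 1})
        raise CollinearityError(dupes)
    X, y = _design(records, predictors)
    n, k = X.shape
    if n < k + 2:
        raise InputError(f"need at least {k + 2} records to fit {k} predictors, got {n}")
    A = np.column_stack([np.ones(n), X])
    # QR rank check: a tiny diagonal of R pinpoints the dependent column
    _, R = np.linalg.qr(A)
    diag = np.abs(np.diag(R))
    tol = max(A.shape) * np.finfo(float).eps * diag.max()
    bad = np.nonzero(diag <= tol)[0]
    if bad.size:
        names = ["intercept"] + list(predictors)
        raise CollinearityError([names[j] for j in bad])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return MassModel(
        predictors=predictors,
        intercept=float(beta[0]),
        coefficients=tuple(float(b) for b in beta[1:]),
    )


def predict_mass(model: MassModel, record: MorphometricRecord) -> float:
    """Predicted mass in grams for one record."""
    missing = [p for p in model.predictors if getattr(record, p) is None]
    if missing:
        raise MissingFieldError(missing)
    return model.intercept + float(
        np.dot(model.coefficients, [getattr(record, p) for p in model.predictors])
    )


def evaluate_fit(model: MassModel, records: list[MorphometricRecord]) -> FitReport:
    """In-sample metric suite for a fitted model on measured records."""
    X, y = _design(records, model.predictors)
    if len(y) < 2:
        raise InputError("need at least 2 records to evaluate")
    yhat = model.intercept + X @ np.asarray(model.coefficients)
    resid = yhat - y
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if (y == 0).any():
        raise InputError("relative error undefined: a record has zero mass")
    mse = float((resid**2).mean())
    return FitReport(
        r2=1.0 - ss_res / ss_tot,
        mae=float(np.abs(resid).mean()),
        mse=mse,
        rmse=float(np.sqrt(mse)),
        max_re=float((np.abs(resid) / np.abs(y)).max() * 100.0),
        n=len(y),
    )
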