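"""Normative covariate modelling and w-score computation.

A per-feature ordinary-least-squares regression is fitted on normal-control
rows only; the w-score of a feature is its standardized residual,
``w = (observed - predicted) / sigma_resid`` with the residual scale using
an (n - p) denominator.  Also hosts the group-wise feature tests
(Welch t per feature with Benjamini-Hochberg FDR control).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from neurodiff.datamodel import Diagnosis, FeatureTable, SubjectRecord

logger = logging.getLogger(__name__)

#: default covariates, in design order
DEFAULT_COVARIATES = ("age", "sex", "field_strength", "icv", "site", "scanner")

_NUMERIC = {"age": lambda r: r.age, "icv": lambda r: r.icv}
_BINARY = {
    "sex": lambda r: 1.0 if r.sex.value == "F" else 0.0,
    "field_strength": lambda r: 1.0 if r.field_strength.value == "3T" else 0.0,
}
_CATEGORICAL = {"site": lambda r: r.site, "scanner": lambda r: r.scanner}


@dataclass(frozen=True)
class DesignSpec:
    """Fixed covariate ordering and categorical levels of a fitted design."""

    covariates: tuple
    levels: dict  # categorical covariate -> ordered levels (first = reference)
    column_names: tuple

    def build(self, records: Sequence[SubjectRecord]) -> np.ndarray:
        n = len(records)
        cols = [np.ones(n)]
        for cov in self.covariates:
            if cov in _NUMERIC:
                cols.append(np.array([_NUMERIC[cov](r) for r in records]))
            elif cov in _BINARY:
                cols.append(np.array([_BINARY[cov](r) for r in records]))
            elif cov in _CATEGORICAL:
                values = [_CATEGORICAL[cov](r) for r in records]
                known = self.levels[cov]
                unseen = sorted(set(values) - set(known))
                if unseen:
                    raise ValueError(
                        f"unseen level(s) {unseen} for covariate {cov!r}; "
                        f"known levels: {list(known)}"
                    )
                for level in known[1:]:  # first level is the reference
                    cols.append(np.array([1.0 if v == level else 0.0 for v in values]))
            else:
                raise ValueError(f"unknown covariate {cov!r}")
        return np.column_stack(cols)


def make_design_spec(
    records: Sequence[SubjectRecord], covariates: Sequence[str] = DEFAULT_COVARIATES
) -> DesignSpec:
    levels, names = {}, ["intercept"]
    for cov in covariates:
        if cov in _CATEGORICAL:
            lv = sorted({_CATEGORICAL[cov](r) for r in records})
            levels[cov] = tuple(lv)
            names.extend(f"{cov}[{v}]" for v in lv[1:])
        else:
            names.append(cov)
    return DesignSpec(tuple(covariates), levels, tuple(names))


@dataclass
class NormativeModel:
    """Per-feature OLS coefficients and residual scales over a fixed design."""

    beta: np.ndarray  # (p, F)
    sigma: np.ndarray  # (F,)
    design: DesignSpec
    feature_names: tuple

    def predict(self, records: Sequence[SubjectRecord]) -> np.ndarray:
        return self.design.build(records) @ self.beta

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fi, fname in enumerate(self.feature_names):
            for ci, cname in enumerate(self.design.column_names):
                rows.append(
                    {"feature": fname, "coefficient": cname, "value": self.beta[ci, fi]}
                )
            rows.append({"feature": fname, "coefficient": "sigma", "value": self.sigma[fi]})
        return pd.DataFrame(rows)


def _collinear_columns(x: np.ndarray, names) -> list[str]:
    """Names of design columns made redundant by earlier ones (QR pivoting)."""
    from scipy.linalg import qr

    _, r, piv = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    dependent = piv[np.sum(diag > tol):]
    return [names[i] for i in sorted(dependent)]


def fit_normative(
    nc_features: FeatureTable,
    nc_records: Sequence[SubjectRecord],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    sigma_floor_scale: float = 1e-8,
) -> NormativeModel:
    """OLS per feature on NC rows; sigma uses the (n - p) denominator.

    Raises on non-NC rows, a rank-deficient design (naming the collinear
    columns) or too few rows.
    """
    if nc_features.kind != "raw":
        raise ValueError("normative model must be fitted on raw features")
    if len(nc_records) != nc_features.n_rows:
        raise ValueError("records/table row counts differ")
    if any(r.diagnosis is not Diagnosis.NC for r in nc_records):
        raise ValueError("normative fit accepts NC rows only")
    spec = make_design_spec(nc_records, covariates)
    x = spec.build(nc_records)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more than {p} NC rows to fit {p} coefficients, got {n}")
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        cols = _collinear_columns(x, spec.column_names)
        raise ValueError(f"rank-deficient design; collinear columns: {cols}")
    y = nc_features.values
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    # one step of iterative refinement: large-scale covariates (ICV ~ 1e6)
    # leave the normal equations ill-conditioned enough that residual means
    # sit at ~1e-9 otherwise
    correction, _, _, _ = np.linalg.lstsq(x, resid, rcond=None)
    beta += correction
    resid = y - x @ beta
    sigma = np.sqrt((resid ** 2).sum(axis=0) / (n - p))
    floor = np.maximum(sigma_floor_scale * y.std(axis=0, ddof=1), 1e-12)
    sigma = np.maximum(sigma, floor)
    return NormativeModel(beta, sigma, spec, tuple(nc_features.columns))


def compute_wscore(
    model: NormativeModel,
    features: FeatureTable,
    records: Sequence[SubjectRecord],
) -> FeatureTable:
    """Standardized residuals wrt the fitted normative model."""
    if features.kind != "raw":
        raise ValueError("w-scores are computed from raw features")
    if tuple(features.columns) != model.feature_names:
        raise ValueError("feature columns differ from the fitted model")
    if len(records) != features.n_rows:
        raise ValueError("records/table row counts differ")
    predicted = model.predict(records)
    w = (features.values - predicted) / model.sigma
    return features.with_values(w, kind="wscore")


def groupwise_feature_tests(
    wtable: FeatureTable,
    records: Sequence[SubjectRecord],
    group_a: Diagnosis | str,
    group_b: Diagnosis | str,
    q: float = 0.05,
) -> pd.DataFrame:
    """Welch two-sample t per feature with Benjamini-Hochberg control.

    Returns a frame indexed by feature with columns t, p, reject.
    Zero-variance, zero-difference features get t = 0, p = 1.
    """
    group_a, group_b = Diagnosis(group_a), Diagnosis(group_b)
    labels = np.array([r.diagnosis.value for r in records])
    a = wtable.values[labels == group_a.value]
    b = wtable.values[labels == group_b.value]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 rows")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    degenerate = ~np.isfinite(t)
    same_mean = np.isclose(a.mean(axis=0), b.mean(axis=0))
    t = np.where(degenerate & same_mean, 0.0, t)
    p = np.where(degenerate & same_mean, 1.0, p)
    if np.any(degenerate & ~same_mean):
        # zero variance but different means: infinitely significant
        t = np.where(degenerate & ~same_mean, np.inf, t)
        p = np.where(degenerate & ~same_mean, 0.0, p)
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return pd.DataFrame(
        {"t": t, "p": p, "reject": reject}, index=pd.Index(wtable.columns, name="feature")
    )
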