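"""Ordinary least squares: the conventional-epidemiology arm.

Provides a scikit-learn-style OLS estimator that reports classical
(homoskedastic) inference for a designated term of interest, the thin
``ols_fit`` wrapper the pipeline uses, and the instrument-confounder
independence check (risk score regressed against each measured confounder,
crude and covariate-adjusted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin


class CollinearityError(ValueError):
    """Raised when the design matrix is rank-deficient; names the columns."""


@dataclass(frozen=True)
class RegressionResult:
    """Inference for one regression term.

    beta/se are in outcome units per unit of the term; ``stat`` is the t
    statistic and ``p`` its two-sided tail probability at ``n - k`` degrees
    of freedom; ``r2`` is the full-model coefficient of determination.
    """

    term: str
    beta: float
    se: float
    stat: float
    p: float
    n: int
    adjusted_for: tuple[str, ...] = ()
    r2: float = float("nan")


def _as_2d(arr) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a


def check_full_rank(design: np.ndarray, names: list[str]) -> None:
    """Raise :class:`CollinearityError` naming the dependent columns."""
    rank = np.linalg.matrix_rank(design)
    if rank == design.shape[1]:
        return
    # pivoted QR: columns beyond the numerical rank are the collinear ones
    _, r, piv = linalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    bad = sorted(names[j] for j in piv[np.sum(diag > tol):])
    raise CollinearityError(
        f"design matrix is rank deficient (rank {rank} < {design.shape[1]}); "
        f"collinear column(s): {bad}"
    )


class AdjustedOLS(RegressorMixin, BaseEstimator):
    """OLS with an always-included intercept and a designated term of interest.

    ``fit(X, y)`` treats the first column of ``X`` as the term of interest
    (the exposure) and remaining columns as adjustment covariates.
    Standard errors are classical homoskedastic ones, ``sqrt(sigma2 *
    [(X'X)^-1]_jj)`` with ``sigma2 = RSS / (n - k)``; an HC1 robust switch
    exists but is off by default.

    Attributes (post-fit): ``intercept_``, ``coef_``, ``se_``, ``tvalues_``,
    ``pvalues_`` (term order: intercept then columns of X), ``r2_``, ``n_``,
    ``result_`` (a :class:`RegressionResult` for the term of interest).
    """

    def __init__(self, robust: bool = False):
        self.robust = robust

    def fit(self, X, y, feature_names=None):
        X = _as_2d(X)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if len(y) != n:
            raise ValueError(f"X has {n} rows but y has {len(y)}")
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("missing values in design or outcome; filter first")
        names = list(feature_names) if feature_names is not None else [
            f"x{j}" for j in range(p)
        ]
        if len(names) != p:
            raise ValueError("feature_names length mismatch")
        k = p + 1
        if n <= k:
            raise ValueError(f"n = {n} too small for {k} model columns")
        design = np.column_stack([np.ones(n), X])
        check_full_rank(design, ["intercept"] + names)

        fit = sm.OLS(y, design).fit(
            cov_type="HC1" if self.robust else "nonrobust"
        )
        self.feature_names_in_ = names
        self.n_features_in_ = p
        self.intercept_ = float(fit.params[0])
        self.coef_ = np.asarray(fit.params[1:])
        self.se_ = np.asarray(fit.bse)
        self.tvalues_ = np.asarray(fit.tvalues)
        self.pvalues_ = np.asarray(fit.pvalues)
        self.df_resid_ = int(fit.df_resid)
        self.r2_ = float(fit.rsquared)
        self.n_ = n
        self.result_ = RegressionResult(
            term=names[0],
            beta=float(fit.params[1]),
            se=float(fit.bse[1]),
            stat=float(fit.tvalues[1]),
            p=float(fit.pvalues[1]),
            n=n,
            adjusted_for=tuple(names[1:]),
            r2=self.r2_,
        )
        return self

    def predict(self, X):
        X = _as_2d(X)
        return self.intercept_ + X @ self.coef_


def ols_fit(y, x, covariates=None, term: str = "exposure",
            covariate_names=None, robust: bool = False) -> RegressionResult:
    """OLS of ``y`` on ``x`` (term of interest) plus optional covariates."""
    x = np.asarray(x, dtype=float).ravel()
    if covariates is None or (hasattr(covariates, "size") and np.size(covariates) == 0):
        X = x[:, None]
        names = [term]
    else:
        C = _as_2d(covariates)
        X = np.column_stack([x, C])
        cov_names = (list(covariate_names) if covariate_names is not None
                     else [f"cov{j}" for j in range(C.shape[1])])
        names = [term] + cov_names
    return AdjustedOLS(robust=robust).fit(X, y, feature_names=names).result_


def confounder_check(grs, confounder, adjust=None, *, confounder_name: str = "confounder",
                     adjust_names=None) -> dict[str, RegressionResult]:
    """Instrument-validity check: regress a measured confounder on the risk score.

    Returns ``{"crude": ..., "adjusted": ...}`` (the adjusted entry present
    only when an adjustment matrix is supplied).  A risk score that is a
    valid instrument should show no association (p > 0.05) in either model.
    Binary confounders (e.g. sex) use the same linear-probability fit.
    """
    confounder = np.asarray(confounder, dtype=float).ravel()
    if np.ptp(confounder) == 0:
        raise CollinearityError(
            f"{confounder_name} is constant; association with the score is undefined"
        )
    out = {"crude": ols_fit(confounder, grs, term=f"grs->{confounder_name}")}
    if adjust is not None and np.size(adjust):
        out["adjusted"] = ols_fit(confounder, grs, covariates=adjust,
                                  term=f"grs->{confounder_name}",
                                  covariate_names=adjust_names)
    return out
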