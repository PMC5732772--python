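"""Two-stage least squares: the Mendelian-randomization estimator.

Stage 1 regresses the exposure (serum urate) on the instrument (genetic
risk score, or a single SNP dosage) plus covariates; stage 2 regresses the
outcome (total bilirubin) on the stage-1 fitted exposure plus the same
covariates.  The coefficient on the fitted exposure is the causal-effect
estimate.  Standard errors use the *structural* residuals — outcome minus
the stage-2 coefficients applied to the **actual** exposure — with the
stage-2 projection matrix; using second-stage fitted residuals instead is
the classic 2SLS mistake and understates the error variance.

Instrument-strength diagnostics follow the usual convention: the headline
F and R² come from the univariate exposure~instrument regression (they obey
``F = (R2/(1-R2)) * (n-2)`` exactly), a covariate-adjusted partial F is
computed alongside, and F < 10 flags a weak instrument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .regress import RegressionResult, _as_2d, check_full_rank

#: Conventional weak-instrument threshold for the first-stage F statistic.
WEAK_F_THRESHOLD = 10.0


class DegenerateInstrumentError(ValueError):
    """Instrument is constant, or identical to the exposure where forbidden."""


@dataclass(frozen=True)
class InstrumentStrength:
    """First-stage diagnostics for instrument -> exposure.

    ``f_stat``/``r2``/``p`` are from the univariate first stage;
    ``partial_f`` is the instrument's F given the adjustment covariates.
    """

    f_stat: float
    r2: float
    partial_f: float
    p: float
    n: int
    weak_instrument: bool


@dataclass(frozen=True)
class TslsResult:
    """2SLS causal-effect estimate with its first-stage diagnostics."""

    beta: float
    se: float
    stat: float
    p: float
    n: int
    first_stage: InstrumentStrength
    adjusted_for: tuple[str, ...] = ()


def first_stage(exposure, instrument, covariates=None, *,
                on_perfect: str = "raise") -> InstrumentStrength:
    """Instrument-strength diagnostics for the first-stage regression.

    Parameters
    ----------
    on_perfect : {"raise", "allow"}
        An instrument that explains (numerically) all exposure variance is
        degenerate for diagnostics and raises by default; the 2SLS fitter
        allows it, where it makes 2SLS collapse to OLS.
    """
    x = np.asarray(exposure, dtype=float).ravel()
    z = np.asarray(instrument, dtype=float).ravel()
    n = len(x)
    if len(z) != n:
        raise ValueError("exposure and instrument lengths differ")
    if n < 3:
        raise ValueError("need at least 3 observations for the first stage")
    if np.ptp(z) == 0:
        raise DegenerateInstrumentError("instrument is constant")
    zc = z - z.mean()
    xc = x - x.mean()
    denom = float(zc @ zc) * float(xc @ xc)
    r2 = float((zc @ xc) ** 2 / denom) if denom > 0 else 0.0
    if r2 >= 1.0 - 1e-12:
        if on_perfect == "raise":
            raise DegenerateInstrumentError(
                "instrument explains all exposure variance (R2 = 1); "
                "not a usable diagnostic"
            )
        r2 = min(r2, 1.0)
        f = np.inf
        p = 0.0
    else:
        f = (r2 / (1.0 - r2)) * (n - 2)
        p = float(stats.f.sf(f, 1, n - 2))

    if covariates is not None and np.size(covariates):
        partial_f = _partial_f(x, z, _as_2d(covariates))
    else:
        partial_f = f
    return InstrumentStrength(
        f_stat=float(f), r2=r2, partial_f=float(partial_f), p=p, n=n,
        weak_instrument=bool(f < WEAK_F_THRESHOLD),
    )


def _partial_f(x: np.ndarray, z: np.ndarray, C: np.ndarray) -> float:
    """F for the instrument in exposure ~ instrument + covariates (t²)."""
    n = len(x)
    design = np.column_stack([np.ones(n), z, C])
    k = design.shape[1]
    if n <= k:
        return float("nan")
    beta, _, rank, _ = np.linalg.lstsq(design, x, rcond=None)
    if rank < k:
        return float("nan")
    resid = x - design @ beta
    sigma2 = float(resid @ resid) / (n - k)
    if sigma2 == 0:
        return float("inf")
    cov = sigma2 * np.linalg.inv(design.T @ design)
    return float(beta[1] ** 2 / cov[1, 1])


class TwoStageLeastSquares(RegressorMixin, BaseEstimator):
    """scikit-learn-style 2SLS estimator for a single endogenous exposure.

    ``fit(X, y, instrument=z)`` treats the first column of ``X`` as the
    (endogenous) exposure and the remaining columns as exogenous adjustment
    covariates; ``z`` may be one instrument (1-d) or several (2-d), e.g.
    the composite risk score or individual SNP dosages.

    Parameters
    ----------
    df_mode : {"t", "asymptotic"}
        Small-sample t inference at ``n - k`` degrees of freedom of the
        stage-2 design (default), or normal-approximation inference.

    Attributes (post-fit): ``coef_`` / ``intercept_`` (structural
    coefficients: exposure first, then covariates), ``se_``, ``pvalues_``,
    ``first_stage_`` (:class:`InstrumentStrength` for the first listed
    instrument, univariate convention), ``result_`` (:class:`TslsResult`).
    """

    def __init__(self, df_mode: str = "t"):
        self.df_mode = df_mode

    def fit(self, X, y, *, instrument, feature_names=None):
        if self.df_mode not in ("t", "asymptotic"):
            raise ValueError(f"unknown df_mode {self.df_mode!r}")
        X = _as_2d(X)
        y = np.asarray(y, dtype=float).ravel()
        Z = _as_2d(instrument)
        n, p = X.shape
        if len(y) != n or Z.shape[0] != n:
            raise ValueError("X, y and instrument must share their subjects")
        if np.isnan(X).any() or np.isnan(y).any() or np.isnan(Z).any():
            raise ValueError("missing values in inputs; filter first")
        names = list(feature_names) if feature_names is not None else (
            ["exposure"] + [f"cov{j}" for j in range(p - 1)]
        )
        x = X[:, 0]
        C = X[:, 1:]

        self.first_stage_ = first_stage(
            x, Z[:, 0], C if C.size else None, on_perfect="allow"
        )

        # stage 1: project the exposure on instruments + exogenous columns
        stage1 = np.column_stack([np.ones(n), Z, C])
        check_full_rank(stage1, ["intercept"]
                        + [f"instrument{j}" for j in range(Z.shape[1])]
                        + names[1:])
        coef1, *_ = np.linalg.lstsq(stage1, x, rcond=None)
        x_hat = stage1 @ coef1
        if np.ptp(x_hat) < 1e-12 * max(1.0, np.ptp(x)):
            raise DegenerateInstrumentError(
                "fitted exposure is constant; instrument carries no signal"
            )

        # stage 2 on the fitted exposure
        W_hat = np.column_stack([np.ones(n), x_hat, C])
        k = W_hat.shape[1]
        if n <= k:
            raise ValueError(f"n = {n} too small for {k} model columns")
        check_full_rank(W_hat, ["intercept"] + names)
        WtW_inv = np.linalg.inv(W_hat.T @ W_hat)
        beta = WtW_inv @ (W_hat.T @ y)

        # structural residuals: actual exposure, not stage-2 fitted values
        W_actual = np.column_stack([np.ones(n), x, C])
        resid = y - W_actual @ beta
        sigma2 = float(resid @ resid) / (n - k)
        cov = sigma2 * WtW_inv
        se = np.sqrt(np.diag(cov))
        tvals = beta / se
        if self.df_mode == "t":
            pvals = 2.0 * stats.t.sf(np.abs(tvals), n - k)
        else:
            pvals = 2.0 * stats.norm.sf(np.abs(tvals))

        self.feature_names_in_ = names
        self.n_features_in_ = p
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.se_ = se
        self.tvalues_ = tvals
        self.pvalues_ = pvals
        self.df_resid_ = n - k
        self.n_ = n
        self.result_ = TslsResult(
            beta=float(beta[1]), se=float(se[1]), stat=float(tvals[1]),
            p=float(pvals[1]), n=n, first_stage=self.first_stage_,
            adjusted_for=tuple(names[1:]),
        )
        return self

    def predict(self, X):
        X = _as_2d(X)
        return self.intercept_ + X @ self.coef_


def tsls_fit(y, exposure, instrument, covariates=None, *,
             covariate_names=None, df_mode: str = "t") -> TslsResult:
    """2SLS fit of outcome ``y`` on ``exposure`` instrumented by ``instrument``."""
    exposure = np.asarray(exposure, dtype=float).ravel()
    if covariates is None or (hasattr(covariates, "size") and np.size(covariates) == 0):
        X = exposure[:, None]
        names = ["exposure"]
    else:
        C = _as_2d(covariates)
        X = np.column_stack([exposure, C])
        cov_names = (list(covariate_names) if covariate_names is not None
                     else [f"cov{j}" for j in range(C.shape[1])])
        names = ["exposure"] + cov_names
    est = TwoStageLeastSquares(df_mode=df_mode)
    est.fit(X, y, instrument=instrument, feature_names=names)
    return est.result_


def wald_ratio(y, exposure, instrument) -> float:
    """Single-instrument, no-covariate IV estimate, cov(z, y) / cov(z, x)."""
    z = np.asarray(instrument, dtype=float).ravel()
    zc = z - z.mean()
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(exposure, dtype=float).ravel()
    denom = float(zc @ (x - x.mean()))
    if denom == 0:
        raise DegenerateInstrumentError("instrument uncorrelated with exposure")
    return float(zc @ (y - y.mean())) / denom
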