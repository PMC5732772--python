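"""Durbin-(Wu-)Hausman test of exposure endogeneity.

Two classical equivalent forms for a single endogenous regressor:

* **contrast** — ``H = (b_2SLS - b_OLS)^2 / (se_2SLS^2 - se_OLS^2)``,
  referred to chi-square(1).  Under exogeneity OLS is efficient, so the
  variance difference should be positive; when it is not (a finite-sample
  artefact) the augmented form is used instead and the fallback recorded.
* **augmented** (control function) — regress the exposure on instrument +
  covariates, add its residual to the outcome regression, and test that
  residual's coefficient; the squared t referred to chi-square(1).

A significant test says OLS and 2SLS disagree beyond sampling error, i.e.
the exposure is endogenous and the 2SLS estimate is the one to trust.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .iv import DegenerateInstrumentError, TslsResult
from .regress import RegressionResult, _as_2d

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class DwhResult:
    """Endogeneity test outcome; ``decision`` applies the p < alpha rule."""

    statistic: float
    df: int
    p: float
    method: str           # "contrast" or "augmented"
    decision: str         # "use_tsls" or "either"
    fallback: bool = False


def _decide(p: float, alpha: float) -> str:
    return "use_tsls" if p < alpha else "either"


def dwh_contrast(ols: RegressionResult, tsls: TslsResult, *,
                 alpha: float = DEFAULT_ALPHA, fallback_data=None) -> DwhResult:
    """Hausman contrast of matched OLS and 2SLS fits.

    Both fits must be on the same subjects and adjustment set.  If the 2SLS
    variance does not exceed the OLS variance the contrast is undefined;
    with ``fallback_data = (y, exposure, instrument, covariates)`` the
    augmented form is computed instead, otherwise this raises.
    """
    if ols.n != tsls.n:
        raise ValueError(f"OLS fit has n = {ols.n} but 2SLS has n = {tsls.n}")
    var_diff = tsls.se ** 2 - ols.se ** 2
    if var_diff <= 0:
        if fallback_data is None:
            raise ValueError(
                "2SLS variance does not exceed OLS variance; contrast form "
                "undefined and no fallback data supplied"
            )
        aug = dwh_augmented(*fallback_data, alpha=alpha)
        return DwhResult(aug.statistic, aug.df, aug.p, "augmented",
                         aug.decision, fallback=True)
    stat = (tsls.beta - ols.beta) ** 2 / var_diff
    p = float(stats.chi2.sf(stat, 1))
    return DwhResult(float(stat), 1, p, "contrast", _decide(p, alpha))


def dwh_augmented(y, exposure, instrument, covariates=None, *,
                  alpha: float = DEFAULT_ALPHA) -> DwhResult:
    """Control-function (augmented regression) form of the test."""
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(exposure, dtype=float).ravel()
    Z = _as_2d(instrument)
    n = len(y)
    has_cov = covariates is not None and np.size(covariates)
    C = _as_2d(covariates) if has_cov else np.empty((n, 0))

    stage1 = np.column_stack([np.ones(n), Z, C])
    coef1, *_ = np.linalg.lstsq(stage1, x, rcond=None)
    v_hat = x - stage1 @ coef1
    if float(np.abs(v_hat).max()) <= 1e-10 * max(1.0, float(np.abs(x).max())):
        raise DegenerateInstrumentError(
            "first-stage residual is identically zero (instrument reproduces "
            "the exposure exactly); endogeneity test undefined"
        )
    aug_cov = np.column_stack([C, v_hat]) if C.size else v_hat[:, None]
    t_v = _coef_t(y, x, aug_cov)
    stat = float(t_v ** 2)
    p = float(stats.chi2.sf(stat, 1))
    return DwhResult(stat, 1, p, "augmented", _decide(p, alpha))


def _coef_t(y: np.ndarray, x: np.ndarray, covs: np.ndarray) -> float:
    """t statistic of the final covariate in y ~ 1 + x + covs."""
    n = len(y)
    design = np.column_stack([np.ones(n), x, covs])
    k = design.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < k:
        raise ValueError("augmented design is rank deficient")
    resid = y - design @ beta
    sigma2 = float(resid @ resid) / (n - k)
    cov = sigma2 * np.linalg.inv(design.T @ design)
    j = k - 1
    return float(beta[j] / np.sqrt(cov[j, j]))
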