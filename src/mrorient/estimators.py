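"""Summary-data MR estimators: IVW, MR-Egger, Radial-Egger.

All three are (weighted) least-squares fits of outcome associations on
exposure associations, treating the exposure associations as fixed
covariates:

* IVW: zero-intercept regression of beta_Y on beta_X with weights
  1/se_Y^2 — equivalently the inverse-variance-weighted average of the
  per-SNP Wald ratios. Invariant to SNP orientation.
* MR-Egger: the same regression with a free intercept, which absorbs the
  average directional pleiotropic effect. The slope equals
  cov_w(beta_Y, beta_X)/var_w(beta_X) and therefore depends on the
  orientation of individual SNPs (only a global flip leaves it unchanged).
* Radial-Egger: unweighted regression of sqrt(w_j)-scaled Wald ratios on
  sqrt(w_j) with first-order weights w_j = beta_Xj^2/se_Yj^2.

Standard errors use a multiplicative overdispersion scale estimated from
the weighted residual sum of squares over the residual degrees of freedom,
floored at 1 (no underdispersion); p-values are two-sided from the t
distribution with the residual df.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .exceptions import (
    CollinearityError,
    DegenerateInstrumentsError,
    RatioUndefinedError,
    ValidationError,
)
from .summary_data import EGGER, IVW_FE, IVW_RE, RADIAL_EGGER, MREstimate, SummaryDataset

__all__ = ["ivw", "egger", "radial_egger", "egger_plim"]


def _t_pvalue(estimate: float, se: float, df: int) -> float:
    if se == 0:
        return 0.0 if estimate != 0 else 1.0
    return float(2.0 * stats.t.sf(abs(estimate / se), df))


def ivw(data: SummaryDataset, variant: str = "RE") -> MREstimate:
    """Inverse-variance-weighted estimate of the causal effect.

    ``variant="FE"`` reports the fixed-effect standard error
    1/sqrt(sum w_j beta_Xj^2); ``variant="RE"`` scales it by the square
    root of the overdispersion sum w_j resid_j^2 / (m-1), floored at 1.
    The point estimate is identical for both variants.
    """
    if variant not in ("FE", "RE"):
        raise ValidationError(f"variant must be 'FE' or 'RE', got {variant!r}")
    bx, by = data.beta_exposure, data.beta_outcome
    if np.all(bx == 0):
        raise DegenerateInstrumentsError("all SNP-exposure associations are zero")
    w = 1.0 / data.se_outcome**2
    sxx = float(np.sum(w * bx * bx))
    slope = float(np.sum(w * bx * by)) / sxx
    m = data.m
    df = m - 1
    fe_var = 1.0 / sxx
    resid = by - slope * bx
    phi = float(np.sum(w * resid * resid)) / df
    overdispersion = max(phi, 1.0)
    var = fe_var if variant == "FE" else overdispersion * fe_var
    se = float(np.sqrt(var))
    return MREstimate(
        method=IVW_FE if variant == "FE" else IVW_RE,
        slope=slope,
        slope_se=se,
        slope_p=_t_pvalue(slope, se, df),
        intercept=0.0,
        overdispersion=1.0 if variant == "FE" else overdispersion,
        df=df,
        n_snps=m,
    )


def egger(data: SummaryDataset) -> MREstimate:
    """MR-Egger: weighted regression of beta_Y on beta_X with free intercept.

    Weights are 1/se_Y^2. The slope estimates the causal effect and the
    intercept the (weighted) average pleiotropic effect under the coding in
    use. Residual df is m - 2.
    """
    bx, by, w = data.beta_exposure, data.beta_outcome, 1.0 / data.se_outcome**2
    m = data.m
    sw = float(np.sum(w))
    xbar = float(np.sum(w * bx)) / sw
    ybar = float(np.sum(w * by)) / sw
    dx = bx - xbar
    sxx = float(np.sum(w * dx * dx))
    if sxx <= 0:
        raise CollinearityError("zero weighted variance of beta_exposure")
    slope = float(np.sum(w * dx * (by - ybar))) / sxx
    intercept = ybar - slope * xbar
    df = m - 2
    resid = by - intercept - slope * bx
    phi = float(np.sum(w * resid * resid)) / df
    overdispersion = max(phi, 1.0)
    slope_se = float(np.sqrt(overdispersion / sxx))
    intercept_se = float(np.sqrt(overdispersion * (1.0 / sw + xbar**2 / sxx)))
    return MREstimate(
        method=EGGER,
        slope=slope,
        slope_se=slope_se,
        slope_p=_t_pvalue(slope, slope_se, df),
        intercept=float(intercept),
        intercept_se=intercept_se,
        intercept_p=_t_pvalue(intercept, intercept_se, df),
        overdispersion=overdispersion,
        df=df,
        n_snps=m,
    )


def radial_egger(data: SummaryDataset) -> MREstimate:
    """Radial-Egger with first-order weights w_j = beta_Xj^2 / se_Yj^2.

    Fits the unweighted regression of theta_hat_j sqrt(w_j) on sqrt(w_j)
    with an intercept, where theta_hat_j = beta_Yj / beta_Xj is the Wald
    ratio. The sqrt(w) coefficient is the causal estimate; the intercept
    r' plays the role of the Egger intercept. Same overdispersion floor and
    t(m-2) conventions as :func:`egger`.
    """
    bx, by, sy = data.beta_exposure, data.beta_outcome, data.se_outcome
    zero = np.flatnonzero(bx == 0)
    if zero.size:
        raise RatioUndefinedError(
            f"Wald ratio undefined: beta_exposure is zero for SNP {data.snp_id[zero[0]]!r}"
        )
    m = data.m
    sqw = np.abs(bx) / sy
    resp = (by / bx) * sqw  # = beta_Y * sign(beta_X) / se_Y
    xbar = float(sqw.mean())
    ybar = float(resp.mean())
    dx = sqw - xbar
    sxx = float(np.sum(dx * dx))
    if sxx <= 0:
        raise CollinearityError("zero variance of sqrt(w): radial fit undefined")
    slope = float(np.sum(dx * (resp - ybar))) / sxx
    intercept = ybar - slope * xbar
    df = m - 2
    resid = resp - intercept - slope * sqw
    phi = float(np.sum(resid * resid)) / df
    overdispersion = max(phi, 1.0)
    slope_se = float(np.sqrt(overdispersion / sxx))
    intercept_se = float(np.sqrt(overdispersion * (1.0 / m + xbar**2 / sxx)))
    return MREstimate(
        method=RADIAL_EGGER,
        slope=slope,
        slope_se=slope_se,
        slope_p=_t_pvalue(slope, slope_se, df),
        intercept=float(intercept),
        intercept_se=intercept_se,
        intercept_p=_t_pvalue(intercept, intercept_se, df),
        overdispersion=overdispersion,
        df=df,
        n_snps=m,
    )


def egger_plim(theta: float, beta_x, alpha, weights=None) -> float:
    """Asymptotic MR-Egger slope for given true effects and weights.

    Returns theta + cov_w(alpha, beta_X) / var_w(beta_X): the probability
    limit of the Egger slope as the GWAS sample sizes grow, used as an
    analytic bias predictor. The covariance term vanishes exactly when the
    orientation in use satisfies the InSIDE condition.
    """
    beta_x = np.asarray(beta_x, dtype=np.float64)
    alpha = np.asarray(alpha, dtype=np.float64)
    if beta_x.shape != alpha.shape:
        raise ValidationError("beta_x and alpha must have equal length")
    w = np.ones_like(beta_x) if weights is None else np.asarray(weights, dtype=np.float64)
    sw = float(np.sum(w))
    xbar = float(np.sum(w * beta_x)) / sw
    abar = float(np.sum(w * alpha)) / sw
    var_x = float(np.sum(w * (beta_x - xbar) ** 2)) / sw
    if var_x <= 0:
        raise CollinearityError("zero weighted variance of beta_x")
    cov_ab = float(np.sum(w * (alpha - abar) * (beta_x - xbar))) / sw
    return float(theta + cov_ab / var_x)
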