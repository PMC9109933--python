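"""Diagnostics: InSIDE covariance, Q and I-squared, Egger intercept test.

* :func:`inside_covariance` — the weighted sample covariance between direct
  effects and SNP-exposure effects whose vanishing defines the InSIDE
  condition for the coding in use.
* :func:`nome_i_squared` — the heterogeneity statistic Q of the exposure
  estimates and I^2 = (Q - (m-1))/Q, which estimates the reliability ratio
  var(beta_X)/var(beta_X_hat); values near 1 mean the no-measurement-error
  assumption is benign, small values signal regression-dilution bias in the
  Egger slope. Re-orienting all SNPs to be exposure-increasing compresses
  the spread of beta_X_hat and therefore always lowers I^2.
* :func:`intercept_test` — two-sided test of a zero Egger (or radial)
  intercept, the conventional screen for directional pleiotropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .exceptions import DimensionError, MethodMismatchError, NomeExactError, ValidationError
from .summary_data import EGGER, RADIAL_EGGER, MREstimate, SummaryDataset

__all__ = [
    "inside_covariance",
    "nome_i_squared",
    "intercept_test",
    "NomeResult",
    "DiagnosticsResult",
    "diagnose",
]


class NomeResult(NamedTuple):
    q_stat: float
    i_squared: float  # NaN when Q == 0; may be negative (flagged by a warning)


def inside_covariance(alpha, beta_x, se_outcome=None) -> float:
    """Weighted sample covariance between alpha and beta_X.

    Weights are 1/se_outcome^2; omit ``se_outcome`` for the equal-weight
    (common-variance) form. The denominator is the sum of weights (the
    1/m-type convention), not m-1.
    """
    alpha = np.asarray(alpha, dtype=np.float64)
    beta_x = np.asarray(beta_x, dtype=np.float64)
    if alpha.shape != beta_x.shape or alpha.ndim != 1:
        raise DimensionError("alpha and beta_x must be 1-d of equal length")
    m = len(alpha)
    if m < 2:
        raise ValidationError("need at least 2 SNPs")
    if se_outcome is None:
        w = np.ones(m)
    else:
        w = 1.0 / np.asarray(se_outcome, dtype=np.float64) ** 2
        if w.shape != alpha.shape:
            raise DimensionError("se_outcome length must match alpha")
    sw = float(np.sum(w))
    abar = float(np.sum(w * alpha)) / sw
    xbar = float(np.sum(w * beta_x)) / sw
    return float(np.sum(w * (alpha - abar) * (beta_x - xbar)) / sw)


def nome_i_squared(beta_exposure, se_exposure) -> NomeResult:
    """Q and I^2 of the SNP-exposure estimates.

    Q = sum_j (b_j - bbar)^2 / se_j^2 with bbar the 1/se^2-weighted mean;
    I^2 = (Q - (m-1))/Q. I^2 is NaN when Q = 0 (no heterogeneity) and is
    reported as computed — with a warning — when negative (Q < m-1), rather
    than truncated at zero.
    """
    b = np.asarray(beta_exposure, dtype=np.float64)
    se = np.asarray(se_exposure, dtype=np.float64)
    if b.shape != se.shape or b.ndim != 1:
        raise DimensionError("beta_exposure and se_exposure must be 1-d of equal length")
    m = len(b)
    if m < 2:
        raise ValidationError("need at least 2 SNPs")
    if np.any(se <= 0):
        raise NomeExactError(
            "I^2 is undefined under exact NOME: all se_exposure must be > 0"
        )
    w = 1.0 / se**2
    bbar = float(np.sum(w * b)) / float(np.sum(w))
    q = float(np.sum(w * (b - bbar) ** 2))
    if q == 0.0:
        warnings.warn("Q = 0: I^2 undefined (no heterogeneity)", stacklevel=2)
        return NomeResult(q, float("nan"))
    i2 = (q - (m - 1)) / q
    if i2 < 0:
        warnings.warn(f"negative I^2 = {i2:.4g} (Q < m-1)", stacklevel=2)
    return NomeResult(q, float(i2))


def intercept_test(fit: MREstimate) -> float:
    """Two-sided p-value for H0: intercept = 0 in an Egger-type fit.

    Uses the t reference with the fit's residual df (m - 2), the same
    convention as the estimators' own p-values.
    """
    if fit.method not in (EGGER, RADIAL_EGGER):
        raise MethodMismatchError(
            f"intercept test requires an Egger-type fit, got {fit.method}"
        )
    if fit.intercept_se == 0:
        return 0.0 if fit.intercept != 0 else 1.0
    t = abs(fit.intercept / fit.intercept_se)
    return float(2.0 * stats.t.sf(t, fit.df))


@dataclass(frozen=True)
class DiagnosticsResult:
    """Bundle of the three diagnostics for one dataset/coding."""

    inside_cov: float
    q_stat: float
    i_squared: float
    intercept_p: float


def diagnose(
    data: SummaryDataset,
    egger_fit: MREstimate,
    true_alpha=None,
    true_beta_x=None,
) -> DiagnosticsResult:
    """Convenience wrapper computing all diagnostics at once.

    The InSIDE covariance needs the true effects (available in simulation;
    NaN otherwise). I^2 needs nonzero exposure SEs and is NaN when they are
    all zero.
    """
    if true_alpha is not None and true_beta_x is not None:
        cov = inside_covariance(true_alpha, true_beta_x, data.se_outcome)
    else:
        cov = float("nan")
    if np.all(data.se_exposure > 0):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q, i2 = nome_i_squared(data.beta_exposure, data.se_exposure)
    else:
        q, i2 = float("nan"), float("nan")
    return DiagnosticsResult(
        inside_cov=cov,
        q_stat=q,
        i_squared=i2,
        intercept_p=intercept_test(egger_fit),
    )
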