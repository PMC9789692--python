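"""Model selection and bias-assessment statistics.

Candidate response curves are compared by the determination coefficient
adjusted for the number of parameters and a Gaussian-likelihood Bayesian
information criterion. A fitted model is then screened for systematic bias
by regressing its residuals (observed − predicted) on the centred
predictions: the intercept ``b0`` measures an overall scale difference, the
slope ``b1`` a prediction bias, and ``precision`` (one minus the adjusted
R² of that residual regression) approaches 1 when residuals carry no
structure related to the predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import DesignError

__all__ = ["adjusted_r2", "bic", "residual_bias", "ResidualBias"]


@dataclass(frozen=True)
class ResidualBias:
    b0: float
    b1: float
    precision: float  # NaN when the residual regression is degenerate


def _as_arrays(observed, predicted):
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError("observed and predicted must have the same shape")
    return o, p


def adjusted_r2(observed, predicted, n_params: int) -> float:
    """R² adjusted for model size: 1 − (1 − R²)(n − 1)/(n − p − 1)."""
    o, p = _as_arrays(observed, predicted)
    n = o.size
    if n <= n_params + 1:
        raise DesignError("adjusted R2 needs n_obs > n_params + 1")
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0:
        warnings.warn("zero total variance: adjusted R2 undefined", stacklevel=2)
        return np.nan
    sse = float(np.sum((o - p) ** 2))
    r2 = 1.0 - sse / sst
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def bic(observed, predicted, n_params: int) -> float:
    """Gaussian BIC: n·ln(SSE/n) + (p + 1)·ln(n), the error variance
    counted as an extra parameter."""
    o, p = _as_arrays(observed, predicted)
    n = o.size
    if n == 0:
        raise DesignError("BIC needs at least one observation")
    sse = float(np.sum((o - p) ** 2))
    if sse == 0:
        warnings.warn("zero SSE: BIC is -inf", stacklevel=2)
        return -np.inf
    return n * np.log(sse / n) + (n_params + 1) * np.log(n)


def residual_bias(observed, predicted) -> ResidualBias:
    """Regress residuals on centred predictions to quantify prediction bias.

    Fits r_i = b0 + b1·(ŷ_i − mean(ŷ)) + e_i by ordinary least squares.
    An unbiased predictor gives b1 ≈ 0 and precision ≈ 1. Degenerate inputs
    (constant predictions, or identically zero residuals) are handled
    without error: the undefined quantity is returned as NaN (b0 = b1 = 0
    when all residuals vanish).
    """
    o, p = _as_arrays(observed, predicted)
    if o.size < 3:
        raise DesignError("residual regression needs at least 3 pairs")
    resid = o - p
    centred = p - p.mean()
    if np.allclose(resid, 0.0):
        return ResidualBias(b0=0.0, b1=0.0, precision=np.nan)
    if np.allclose(centred, 0.0):
        warnings.warn("constant predictions: bias slope undefined", stacklevel=2)
        return ResidualBias(b0=float(resid.mean()), b1=np.nan, precision=np.nan)
    ols = sm.OLS(resid, sm.add_constant(centred)).fit()
    precision = float(np.clip(1.0 - ols.rsquared_adj, 0.0, 1.0))
    return ResidualBias(b0=float(ols.params[0]), b1=float(ols.params[1]),
                        precision=precision)
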