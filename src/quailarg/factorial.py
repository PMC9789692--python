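"""Factorial intake model: maintenance plus egg-mass production.

The daily amino-acid intake required by a laying bird is modelled
additively as

    DAI (mg/bird·d) = m · BW^0.67 + q · min(EM, EM_plateau)

where ``m`` is the maintenance coefficient (mg per kg metabolic body
weight per day), ``q`` the egg-mass coefficient (mg per g of egg), BW the
body weight in kg and EM the daily egg-mass output in g. EM is capped at a
plateau to avoid extrapolating the linear production term beyond the
response range observed in the parameterizing trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["FactorialModel", "predict_intake", "validate", "arg_lys_ratio",
           "ARG_MODEL", "LYS_MODEL"]


@dataclass(frozen=True)
class FactorialModel:
    """Coefficients of the factorial intake model.

    Defaults are the arginine parameterization for laying Japanese quail:
    maintenance 90 mg/kg BW^0.67·d, egg-mass requirement 25 mg/g, expected
    prediction error band ±12 mg/bird·d, and an 11 g/d egg-mass plateau.
    """

    m: float = 90.0
    q: float = 25.0
    error_band: float = 12.0
    em_plateau: float = 11.0
    exponent: float = 0.67

    def __post_init__(self):
        if self.m <= 0 or self.q <= 0:
            raise DomainError("factorial coefficients must be positive")
        if self.error_band < 0:
            raise DomainError("error band must be nonnegative")


#: arginine model parameterized by this package's response analysis
ARG_MODEL = FactorialModel()
#: lysine factorial model from the laying-quail literature
#: (maintenance 136 mg/kg^0.67, 21 mg lysine per g egg, ±19 mg band)
LYS_MODEL = FactorialModel(m=136.0, q=21.0, error_band=19.0)


def predict_intake(model: FactorialModel, body_weight_kg, egg_mass):
    """Predicted daily intake, mg/bird·d (vectorized)."""
    bw = np.asarray(body_weight_kg, dtype=float)
    em = np.asarray(egg_mass, dtype=float)
    if np.any(bw <= 0) or np.any(em < 0):
        raise DomainError("body weight must be positive, egg mass nonnegative")
    return model.m * bw ** model.exponent + model.q * np.minimum(em, model.em_plateau)


def validate(model: FactorialModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Apply the model to literature observations and tabulate errors.

    ``rows`` needs columns ``source``, ``body_weight`` (kg), ``egg_mass``
    (g/d) and ``observed_intake`` (mg/bird·d). Adds ``predicted``,
    ``error`` (observed − predicted) and ``outside_band``.
    """
    out = rows.copy()
    out["predicted"] = predict_intake(model, out["body_weight"], out["egg_mass"])
    out["error"] = out["observed_intake"] - out["predicted"]
    out["outside_band"] = out["error"].abs() > model.error_band
    return out


def arg_lys_ratio(model: FactorialModel = ARG_MODEL,
                  lys_model: FactorialModel = LYS_MODEL,
                  body_weight_kg: float = 0.180,
                  egg_mass: float = 11.0) -> float:
    """Arginine-to-lysine ratio of predicted daily intakes at a reference
    body weight and egg-mass output."""
    arg = predict_intake(model, body_weight_kg, egg_mass)
    lys = predict_intake(lys_model, body_weight_kg, egg_mass)
    return float(arg / lys)
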