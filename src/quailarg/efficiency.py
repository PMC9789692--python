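"""Utilization efficiency and requirement extraction.

Efficiency of arginine utilization is the ratio of arginine deposited in
eggs to arginine supplied, read from a linear-plateau fit of deposition
against intake as plateau/breakpoint. Because part of the supply covers
maintenance, and birds in deficit mobilize body arginine to sustain egg
output, the intake axis can be corrected before fitting:

* ``total`` — dietary intake as is;
* ``minus_maintenance`` — intake less the maintenance requirement;
* ``minus_maintenance_plus_mobilization`` — additionally crediting
  mobilized body arginine (body loss only) as supply.

The per-treatment requirement statistic Req = (intake − maintenance)/egg
mass (mg arginine per g egg) and the egg-mass requirement coefficient — the
breakpoint of a linear-plateau fit of egg production on Req — are also
computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError
from .models import BrokenLineParams, FitResult, fit_broken_line
from .trial import metabolic_weight

__all__ = ["EfficiencyReport", "corrected_intake", "broken_line_efficiency",
           "efficiency_suite", "treatment_requirement", "requirement_table",
           "egg_mass_coefficient"]

MODES = ("total", "minus_maintenance", "minus_maintenance_plus_mobilization")


@dataclass(frozen=True)
class EfficiencyReport:
    k_total: float
    k_minus_maintenance: float
    k_minus_maintenance_plus_mobilization: float
    fits: dict


def corrected_intake(x, maintenance=0.0, mobilization=0.0, mode: str = "total"):
    """Correct standardized intake for maintenance and body mobilization.

    Mobilization follows the trial sign convention (negative = body loss);
    only body loss is credited as additional supply — body accretion is not
    subtracted from intake.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("intake must be nonnegative")
    if mode == "total":
        return x + 0.0
    if mode == "minus_maintenance":
        out = x - maintenance
    elif mode == "minus_maintenance_plus_mobilization":
        out = x - maintenance + np.maximum(0.0, -np.asarray(mobilization, dtype=float))
    else:
        raise ValueError(f"unknown correction mode {mode!r}")
    if np.any(out < 0):
        warnings.warn("negative corrected intake(s) passed through", stacklevel=2)
    return out


def broken_line_efficiency(params: BrokenLineParams) -> float:
    """Utilization efficiency implied by a linear-plateau fit:
    plateau / breakpoint."""
    return params.plateau / params.breakpoint


def efficiency_suite(x, y, maintenance: float, mobilization=None) -> EfficiencyReport:
    """Fit deposition against intake under each supply correction.

    Parameters
    ----------
    x, y
        Standardized intake and deposition per bird (mg/kg BW^0.67·d).
    maintenance
        Maintenance requirement, mg/kg BW^0.67·d.
    mobilization
        Standardized body-arginine flow per bird (negative = loss); zero
        when omitted.
    """
    mobilization = np.zeros_like(np.asarray(x, float)) if mobilization is None \
        else mobilization
    fits = {}
    ks = {}
    for mode in MODES:
        xc = corrected_intake(x, maintenance, mobilization, mode=mode)
        params, fit = fit_broken_line(xc, y)
        fits[mode] = (params, fit)
        ks[mode] = broken_line_efficiency(params)
    return EfficiencyReport(
        k_total=ks["total"],
        k_minus_maintenance=ks["minus_maintenance"],
        k_minus_maintenance_plus_mobilization=ks[
            "minus_maintenance_plus_mobilization"],
        fits=fits,
    )


def treatment_requirement(arg_intake_mg, body_weight_g, egg_mass_g,
                          m: float = 90.0, exponent: float = 0.67):
    """Requirement statistic Req = (intake − m·BW^0.67)/egg mass, mg/g.

    Undefined (NaN, with a warning) where egg mass is zero.
    """
    intake = np.asarray(arg_intake_mg, dtype=float)
    em = np.asarray(egg_mass_g, dtype=float)
    maint = m * metabolic_weight(body_weight_g, exponent)
    with np.errstate(divide="ignore", invalid="ignore"):
        req = np.where(em > 0, (intake - maint) / em, np.nan)
    if np.any(em <= 0):
        warnings.warn("zero egg mass: requirement undefined for some rows",
                      stacklevel=2)
    return req


def requirement_table(summary: pd.DataFrame, m: float = 90.0,
                      exponent: float = 0.67) -> pd.DataFrame:
    """Per-treatment Req from a treatment-mean table.

    ``summary`` needs columns ``treatment``, ``arg_intake``, ``body_weight``
    (g), ``egg_mass`` and ``egg_production`` (%). ``req_rounded`` is for
    display; downstream fits should use the raw ``req``.
    """
    req = treatment_requirement(summary["arg_intake"], summary["body_weight"],
                                summary["egg_mass"], m=m, exponent=exponent)
    out = summary[["treatment", "egg_production"]].copy()
    out["req"] = np.asarray(req)
    out["req_rounded"] = pd.array(
        [int(round(v)) if np.isfinite(v) else pd.NA for v in np.atleast_1d(req)],
        dtype="Int64")
    return out


def egg_mass_coefficient(req, egg_production_pct
                         ) -> tuple[float, BrokenLineParams, FitResult]:
    """Egg-mass requirement coefficient q from egg production vs Req.

    Fits the linear-plateau model EP(%) = plateau − slope·max(0, q − Req);
    the breakpoint q is the arginine requirement per g of egg mass (mg/g).
    Requires at least 4 treatments with a defined Req.
    """
    req = np.asarray(req, dtype=float)
    ep = np.asarray(egg_production_pct, dtype=float)
    ok = np.isfinite(req) & np.isfinite(ep)
    if ok.sum() < 4:
        raise DesignError("need at least 4 treatments with defined Req")
    params, fit = fit_broken_line(req[ok], ep[ok])
    return params.breakpoint, params, fit
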