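"""Published constants of the quail arginine dose-response trial.

The trial fed 49 laying Japanese quail (7 dietary arginine levels × 7
single-bird cages) for eight weeks, with responses collected over the last
four. This module packages the published treatment-mean response table, the
egg/body composition constants, the fitted response-curve parameters, the
linear-plateau efficiency fits, the factorial-model coefficients, and the
literature rows used for external validation, so every downstream statistic
can be recomputed without the per-bird data deposit.
"""

from __future__ import annotations

import pandas as pd

from .factorial import ARG_MODEL, LYS_MODEL
from .models import BrokenLineParams, MonomolecularParams, SaturationParams
from .trial import Composition

__all__ = [
    "ARG_LEVELS", "DEFAULT_COMPOSITION", "IMPLIED_EGG_ARG_COEFF",
    "MAINTENANCE_MG_PER_KG", "EGG_MASS_REQ_MG_PER_G",
    "PUBLISHED_MONOMOLECULAR", "PUBLISHED_SATURATION",
    "BROKEN_LINE_TOTAL", "BROKEN_LINE_MINUS_MAINTENANCE",
    "BROKEN_LINE_MINUS_MAINT_PLUS_MOB", "EP_REQ_BROKEN_LINE",
    "ARG_MODEL", "LYS_MODEL",
    "treatment_means", "validation_rows", "standardized_means",
]

#: dietary arginine levels of the seven treatments, g/kg (analyzed values)
ARG_LEVELS = (2.43, 3.64, 4.85, 6.07, 9.07, 12.13, 14.56)

#: egg/body protein and arginine composition used to derive arginine flows
DEFAULT_COMPOSITION = Composition()

#: egg arginine coefficient implied by the published deposition column
#: (deposition/egg-mass ≈ 7.0 mg/g, vs 6.68 mg/g from the composition table)
IMPLIED_EGG_ARG_COEFF = 7.0

#: maintenance requirement, mg arginine per kg BW^0.67 per day
MAINTENANCE_MG_PER_KG = 90.0

#: egg-mass production requirement, mg arginine per g egg
EGG_MASS_REQ_MG_PER_G = 25.0

#: fitted monomolecular curve (shifted four-parameter form)
PUBLISHED_MONOMOLECULAR = MonomolecularParams(rmax=249.0, rmin=11.0,
                                              k=0.003934, xm=90.0)

#: fitted saturation-kinetics curve
PUBLISHED_SATURATION = SaturationParams(rmax=232.0, rmin=21.0,
                                        km=291.0, n=3.413)

#: linear-plateau fits of deposition vs intake under each supply correction
BROKEN_LINE_TOTAL = BrokenLineParams(plateau=225.0, slope=0.53,
                                     breakpoint=484.0)
BROKEN_LINE_MINUS_MAINTENANCE = BrokenLineParams(plateau=225.0, slope=0.53,
                                                 breakpoint=394.0)
BROKEN_LINE_MINUS_MAINT_PLUS_MOB = BrokenLineParams(plateau=225.0, slope=0.49,
                                                    breakpoint=380.0)

#: linear-plateau model of egg production (%) against the per-treatment
#: requirement statistic; its breakpoint is the egg-mass coefficient
EP_REQ_BROKEN_LINE = BrokenLineParams(plateau=93.0, slope=3.1, breakpoint=25.0)

_TREATMENT_MEANS = [
    # treatment, arg_level, feed_intake, arg_intake, egg_production(%),
    # egg_weight, egg_mass, feed_efficiency, arg_deposition, body_weight,
    # bw_change, arg_mobilization
    ("D1", 2.43, 13.2, 32.0, 13.3, 5.4, 1.0, 0.08, 6.8, 147.2, -34.8, -11.9),
    ("D2", 3.64, 15.5, 56.3, 36.3, 8.8, 3.2, 0.21, 22.4, 149.4, -34.3, -11.7),
    ("D3", 4.85, 17.1, 82.9, 51.2, 8.9, 4.6, 0.27, 32.2, 151.3, -22.1, -7.5),
    ("D4", 6.07, 19.3, 116.9, 80.0, 9.5, 7.6, 0.39, 53.2, 167.1, -24.6, -7.8),
    ("D5", 9.07, 23.4, 212.6, 92.1, 10.8, 10.0, 0.43, 70.2, 174.2, -8.9, -3.0),
    ("D6", 12.13, 25.7, 311.3, 96.4, 10.9, 10.5, 0.41, 73.6, 179.7, -0.8, -0.3),
    ("D7", 14.56, 22.6, 328.7, 95.8, 10.2, 9.8, 0.43, 68.6, 173.3, 5.0, 1.7),
]

_VALIDATION_ROWS = [
    # source tag, body weight (kg), egg mass (g/d), observed intake (mg/bird·d)
    ("lima", 0.170, 10.72, 289.0),
    ("lima", 0.180, 10.72, 289.0),
    ("lima", 0.190, 10.72, 289.0),
    ("study2", 0.170, 11.13, 302.0),
    ("study2", 0.180, 11.13, 302.0),
    ("study2", 0.190, 11.13, 302.0),
    ("tavaniello", 0.181, 9.75, 259.0),
]


def treatment_means() -> pd.DataFrame:
    """Published per-treatment mean responses of the dose-response trial.

    Egg production is in %, intake/deposition/mobilization in mg/bird·d,
    body weight in g, body-weight change in g over the 28-d collection
    window. Note the published table's treatment means are rounded, so
    products of printed means (e.g. egg production × egg weight) can differ
    slightly from the printed derived columns, which were averaged per bird
    before rounding.
    """
    cols = ["treatment", "arg_level", "feed_intake", "arg_intake",
            "egg_production", "egg_weight", "egg_mass", "feed_efficiency",
            "arg_deposition", "body_weight", "bw_change", "arg_mobilization"]
    return pd.DataFrame(_TREATMENT_MEANS, columns=cols)


def validation_rows() -> pd.DataFrame:
    """Literature inputs used to validate the factorial model.

    Three published quail feeding studies; tags name the source article's
    first author where known. Two studies did not report body weight, so
    each is expanded over three plausible body weights (0.170-0.190 kg).
    """
    return pd.DataFrame(_VALIDATION_ROWS,
                        columns=["source", "body_weight", "egg_mass",
                                 "observed_intake"])


def standardized_means(exponent: float = 0.67) -> pd.DataFrame:
    """Treatment means with intake and deposition standardized to
    mg/kg BW^exponent·d (columns ``X`` and ``Y``)."""
    tm = treatment_means()
    mbw = (tm["body_weight"] / 1000.0) ** exponent
    tm = tm.copy()
    tm["X"] = tm["arg_intake"] / mbw
    tm["Y"] = tm["arg_deposition"] / mbw
    return tm
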