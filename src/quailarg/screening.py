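"""Pre-modelling screen: one-way ANOVA with orthogonal polynomial contrasts.

Before fitting nonlinear curves, each response variable is screened for a
dietary-level effect with a one-way analysis of variance and orthogonal
linear and quadratic contrasts built on the actual (unequally spaced)
arginine levels. Since each bird contributes a single period-mean
observation and birds are the experimental units, the one-way fixed-effects
decomposition is exact here. A simple k-standard-deviation rule provides an
outlier screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError

__all__ = ["ContrastResult", "polynomial_contrasts", "outlier_screen",
           "screen_table"]


@dataclass(frozen=True)
class ContrastResult:
    variable: str
    f_anova: float
    p_anova: float
    f_linear: float
    p_linear: float
    f_quadratic: float
    p_quadratic: float
    estimate_linear: float     # regression coefficient on the orthogonalized level
    estimate_quadratic: float  # coefficient on the orthogonalized squared level
    n_used: int


def _orthogonal_regressors(levels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gram-Schmidt orthogonalization of (level, level²) against the
    intercept at observation resolution, honouring unequal spacing and any
    imbalance in replication."""
    v1 = levels - levels.mean()
    x2 = levels ** 2
    v2 = x2 - x2.mean() - (x2 @ v1) / (v1 @ v1) * v1
    return v1, v2


def polynomial_contrasts(levels, values, variable: str = "response") -> ContrastResult:
    """Linear/quadratic orthogonal contrasts over unequally spaced levels.

    ``levels`` and ``values`` are per-observation vectors. Contrast sums of
    squares are tested against the within-level mean square from the
    one-way decomposition.
    """
    levels = np.asarray(levels, dtype=float)
    values = np.asarray(values, dtype=float)
    if levels.shape != values.shape:
        raise ValueError("levels and values must align")
    uniq = np.unique(levels)
    if uniq.size < 3:
        raise DesignError("polynomial contrasts need at least 3 distinct levels")
    counts = np.array([(levels == u).sum() for u in uniq])
    if np.any(counts < 2):
        raise DesignError("each level needs at least 2 observations")

    groups = [values[levels == u] for u in uniq]
    n = values.size
    df_err = n - uniq.size
    sse = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    mse = sse / df_err

    v1, v2 = _orthogonal_regressors(levels)
    out = {}
    for tag, v in (("linear", v1), ("quadratic", v2)):
        vv = float(v @ v)
        coef = float(v @ values) / vv if vv > 0 else 0.0
        ss = coef ** 2 * vv
        if mse > 0:
            f = ss / mse
            p = float(stats.f.sf(f, 1, df_err))
        else:  # zero within-group variance: saturated design
            f = np.inf if ss > 1e-300 else 0.0
            p = 0.0 if ss > 1e-300 else 1.0
        out[tag] = (coef, f, p)

    f_anova, p_anova = stats.f_oneway(*groups)
    return ContrastResult(
        variable=variable,
        f_anova=float(f_anova), p_anova=float(p_anova),
        f_linear=out["linear"][1], p_linear=out["linear"][2],
        f_quadratic=out["quadratic"][1], p_quadratic=out["quadratic"][2],
        estimate_linear=out["linear"][0],
        estimate_quadratic=out["quadratic"][0],
        n_used=int(n),
    )


def outlier_screen(values, treatments, k: float = 3.0) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag per-treatment outliers beyond ``k`` within-treatment SDs.

    Each observation is compared against the mean and SD of the *other*
    birds in its treatment (leave-one-out, Grubbs-style); including the
    candidate itself would bound the attainable deviation at (g-1)/sqrt(g)
    SDs in a group of g birds and make the screen vacuous at replication
    levels typical of cage trials. At most one observation per treatment
    (the largest deviation) is flagged per pass. Returns a boolean
    keep-mask aligned with ``values`` and a report of flagged observations.
    """
    if not k > 0:
        raise ValueError("k must be positive")
    values = np.asarray(values, dtype=float)
    treatments = np.asarray(treatments)
    keep = np.ones(values.size, dtype=bool)
    rows = []
    if not np.isfinite(k):
        return keep, pd.DataFrame(columns=["treatment", "index", "value", "z"])
    for t in pd.unique(treatments):
        idx = np.flatnonzero(treatments == t)
        g = values[idx]
        if g.size < 3:
            continue
        z = np.zeros(g.size)
        for j in range(g.size):
            rest = np.delete(g, j)
            sd = rest.std(ddof=1)
            if sd > 0:
                z[j] = abs(g[j] - rest.mean()) / sd
        worst = int(np.argmax(z))
        if z[worst] > k:
            keep[idx[worst]] = False
            rows.append({"treatment": t, "index": int(idx[worst]),
                         "value": float(g[worst]), "z": float(z[worst])})
    report = pd.DataFrame(rows, columns=["treatment", "index", "value", "z"])
    return keep, report


def screen_table(derived: pd.DataFrame, variables: list[str] | None = None,
                 k: float = 3.0) -> pd.DataFrame:
    """Run the outlier screen and polynomial contrasts for each response
    variable of a per-bird derived table; one row per variable."""
    variables = variables or ["feed_intake", "arg_intake", "egg_production",
                              "egg_weight", "egg_mass", "arg_deposition",
                              "body_weight", "bw_change", "arg_mobilization"]
    rows = []
    for var in variables:
        if var not in derived.columns:
            continue
        keep, _ = outlier_screen(derived[var].to_numpy(),
                                 derived["treatment"].to_numpy(), k=k)
        sub = derived.loc[keep]
        res = polynomial_contrasts(sub["arg_level"].to_numpy(),
                                   sub[var].to_numpy(), variable=var)
        rows.append(res.__dict__)
    return pd.DataFrame(rows)
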