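"""Nonlinear dose-response families for egg-arginine deposition.

Two four-parameter families describe daily arginine deposition in eggs (Y,
mg/kg BW^0.67·d) as a function of daily arginine intake (X, same units):

* a **monomolecular** (Mitscherlich) diminishing-returns exponential,
  anchored at a maintenance intake ``xm`` where the curve crosses its
  minimum response, and
* a **saturation-kinetics** (Hill-type) curve with half-response intake
  ``km`` and apparent kinetic order ``n``.

A **linear-plateau (broken-line)** model supports requirement and
efficiency estimation: the response rises linearly up to a breakpoint and
is constant above it, so the breakpoint is read as the requirement.

The module also provides closed-form efficiency curves (dY/dX), landmark
intakes of the saturation curve (inflection, maximum above-minimum average
efficiency), maintenance extraction, and nonlinear least-squares fitting
with multi-start initialization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from . import assessment
from .errors import DesignError, DomainError, FitError

__all__ = [
    "MonomolecularParams",
    "SaturationParams",
    "BrokenLineParams",
    "FitResult",
    "eval_monomolecular",
    "eval_saturation",
    "eval_broken_line",
    "efficiency_curve",
    "maintenance_intake",
    "intake_at_max_slope",
    "intake_at_max_efficiency",
    "fit_response",
    "fit_broken_line",
]


@dataclass(frozen=True)
class MonomolecularParams:
    """Four-parameter monomolecular response curve.

    ``form="shifted"`` (default) evaluates the increasing curve

        Y = rmax − (rmax + rmin) · exp(−k (X − xm)),

    which has asymptote ``rmax``, equals ``−rmin`` at the maintenance
    intake ``xm`` (so ``rmin`` is the magnitude of the minimum response),
    and reduces to the standard three-parameter monomolecular at
    ``rmin = 0``. ``form="printed"`` evaluates the non-increasing variant
    Y = rmax − rmin·(1 − exp(−k (X − xm))), retained for comparison only.
    """

    rmax: float
    rmin: float
    k: float
    xm: float
    form: str = "shifted"

    def __post_init__(self):
        if self.rmax <= 0 or self.k <= 0 or self.xm < 0 or self.rmin < 0:
            raise DomainError("monomolecular parameters out of range")
        if self.form not in ("shifted", "printed"):
            raise DomainError(f"unknown monomolecular form {self.form!r}")


@dataclass(frozen=True)
class SaturationParams:
    """Saturation-kinetics (Hill-type) response curve.

    Y = (rmin·km^n + rmax·X^n) / (km^n + X^n); ``km`` is the intake giving
    the midpoint (rmin + rmax)/2 and ``n`` the apparent kinetic order.
    """

    rmax: float
    rmin: float
    km: float
    n: float

    def __post_init__(self):
        if not (self.rmax > self.rmin >= 0) or self.km <= 0 or self.n <= 0:
            raise DomainError("saturation parameters out of range")


@dataclass(frozen=True)
class BrokenLineParams:
    """Linear-plateau model Y = plateau − slope · max(0, breakpoint − X)."""

    plateau: float
    slope: float
    breakpoint: float
    identified: bool = True

    def __post_init__(self):
        if self.breakpoint <= 0:
            raise DomainError("breakpoint must be positive")


@dataclass
class FitResult:
    """Outcome of a nonlinear least-squares fit."""

    params: object
    se: np.ndarray
    r2_adj: float
    bic: float
    n_obs: int
    sse: float
    param_names: tuple[str, ...] = field(default_factory=tuple)

    def summary(self) -> str:
        rows = [f"{nm} = {v:.6g} (se {s:.3g})"
                for nm, v, s in zip(self.param_names, self._values(), self.se)]
        rows.append(f"n = {self.n_obs}, R2adj = {self.r2_adj:.4f}, "
                    f"BIC = {self.bic:.2f}")
        return "\n".join(rows)

    def _values(self):
        return [getattr(self.params, nm) for nm in self.param_names]


# ---------------------------------------------------------------------------
# evaluation

def eval_monomolecular(p: MonomolecularParams, x):
    x = np.asarray(x, dtype=float)
    e = np.exp(-p.k * (x - p.xm))
    if p.form == "shifted":
        return p.rmax - (p.rmax + p.rmin) * e
    return p.rmax - p.rmin * (1.0 - e)


def eval_saturation(p: SaturationParams, x):
    x = np.asarray(x, dtype=float)
    t = (x / p.km) ** p.n
    return (p.rmin + p.rmax * t) / (1.0 + t)


def eval_broken_line(p: BrokenLineParams, x):
    x = np.asarray(x, dtype=float)
    return p.plateau - p.slope * np.maximum(0.0, p.breakpoint - x)


def efficiency_curve(params, x):
    """Marginal efficiency dY/dX of a fitted response curve (closed form)."""
    x = np.asarray(x, dtype=float)
    if isinstance(params, SaturationParams):
        rng_ = params.rmax - params.rmin
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (x / params.km) ** params.n
            d = params.n * rng_ * t / (x * (1.0 + t) ** 2)
        if params.n > 1:
            limit0 = 0.0
        elif params.n == 1:
            limit0 = rng_ / params.km
        else:
            limit0 = np.inf
        return np.where(x == 0, limit0, d)
    if isinstance(params, MonomolecularParams):
        e = np.exp(-params.k * (x - params.xm))
        if params.form == "shifted":
            return params.k * (params.rmax + params.rmin) * e
        return -params.rmin * params.k * e
    raise TypeError(f"unsupported parameter type {type(params).__name__}")


# ---------------------------------------------------------------------------
# landmarks

def maintenance_intake(params, body_weight_kg: float | None = None,
                       exponent: float = 0.67):
    """Intake at which net egg-arginine deposition is zero.

    Returns the maintenance intake per kg metabolic body weight
    (mg/kg^exponent·d); when ``body_weight_kg`` is given, also the per-bird
    value ``BW^exponent × maintenance`` (mg/bird·d) as a second element.

    For the monomolecular family this is the anchor parameter ``xm``;
    for saturation kinetics it is ``km · (rmin/rmax)^(1/n)``.
    """
    if isinstance(params, MonomolecularParams):
        per_kg = params.xm
    elif isinstance(params, SaturationParams):
        if params.rmin == 0:
            warnings.warn("rmin = 0: maintenance analogue is 0", stacklevel=2)
            per_kg = 0.0
        else:
            per_kg = params.km * (params.rmin / params.rmax) ** (1.0 / params.n)
    else:
        raise TypeError(f"unsupported parameter type {type(params).__name__}")
    if body_weight_kg is None:
        return per_kg
    if body_weight_kg <= 0:
        raise DomainError("body weight must be positive")
    return per_kg, body_weight_kg ** exponent * per_kg


def intake_at_max_slope(p: SaturationParams) -> float:
    """Inflection of the saturation curve: intake where dY/dX is largest.

    Closed form km·((n−1)/(n+1))^(1/n); only defined for kinetic order n > 1.
    """
    if p.n <= 1:
        raise DomainError("saturation curve has no inflection for n <= 1")
    return p.km * ((p.n - 1.0) / (p.n + 1.0)) ** (1.0 / p.n)


def intake_at_max_efficiency(p: SaturationParams) -> float:
    """Intake maximizing the above-minimum average efficiency (Y − rmin)/X.

    Closed form km·(n−1)^(1/n); only defined for n > 1.
    """
    if p.n <= 1:
        raise DomainError("no interior efficiency maximum for n <= 1")
    return p.km * (p.n - 1.0) ** (1.0 / p.n)


# ---------------------------------------------------------------------------
# fitting

_FAMILIES = {
    "monomolecular": (("rmax", "rmin", "k", "xm"), MonomolecularParams),
    "saturation": (("rmax", "rmin", "km", "n"), SaturationParams),
}


def _starts(family: str, x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    rng_x = float(np.ptp(x))
    if family == "monomolecular":
        base = np.array([max(y.max(), 1e-3), max(0.0, -y.min()) + 1.0,
                         1.0 / rng_x, max(x.min(), 1e-6)])
    else:
        base = np.array([max(y.max(), 1e-3), max(y.min(), 1e-3),
                         float(np.median(x)), 2.0])
    return [base, base * [1.2, 0.5, 0.6, 1.5], base * [0.9, 1.5, 1.6, 0.5]]


def _bounds(family: str, x: np.ndarray):
    if family == "monomolecular":
        lo = [1e-9, 0.0, 1e-12, 0.0]
        hi = [np.inf, np.inf, np.inf, float(x.max())]
    else:
        lo = [1e-9, 0.0, 1e-9, 1e-3]
        hi = [np.inf, np.inf, np.inf, 50.0]
    return np.array(lo), np.array(hi)


def _make_params(family: str, theta: np.ndarray):
    names, cls = _FAMILIES[family]
    kw = dict(zip(names, (float(v) for v in theta)))
    if family == "saturation" and kw["rmin"] >= kw["rmax"]:
        kw["rmin"] = kw["rmax"] * (1 - 1e-9)  # degenerate boundary guard
    return cls(**kw)


def _evaluate(family: str, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    if family == "monomolecular":
        rmax, rmin, k, xm = theta
        return rmax - (rmax + rmin) * np.exp(-k * (x - xm))
    rmax, rmin, km, n = theta
    t = (x / km) ** n
    return (rmin + rmax * t) / (1.0 + t)


def fit_response(x, y, family: str = "saturation", *,
                 bird_ids: Sequence | None = None,
                 random_max: bool = False) -> FitResult:
    """Fit a response family by multi-start nonlinear least squares.

    Parameters
    ----------
    x, y
        Standardized intake and deposition observations (mg/kg BW^0.67·d).
    family
        ``"saturation"`` or ``"monomolecular"`` (shifted form).
    bird_ids, random_max
        When ``random_max=True``, a two-stage random-maximum mode estimates
        per-bird offsets of the asymptote from the fixed fit residuals,
        shrinks them toward zero by the estimated variance ratio, and refits
        on the offset-corrected responses. With a single observation per
        bird the offset variance cannot be separated from residual noise, so
        shrinkage collapses to zero and the result equals the fixed fit.

    Raises
    ------
    FitError
        If no start converges; the error carries the best candidate found.
    """
    if family not in _FAMILIES:
        raise DomainError(f"unknown response family {family!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    names, _ = _FAMILIES[family]
    n_par = len(names)
    if x.size <= n_par:
        raise DesignError(f"need more than {n_par} observations")
    if np.ptp(x) <= 0:
        raise DesignError("no spread in intake values")

    def run(yy):
        lo, hi = _bounds(family, x)
        best = None
        for theta0 in _starts(family, x, yy):
            theta0 = np.clip(theta0, lo + 1e-12, np.where(np.isfinite(hi), hi, theta0))
            try:
                sol = optimize.least_squares(
                    lambda th: _evaluate(family, th, x) - yy, theta0,
                    bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12,
                    max_nfev=20000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        return best

    sol = run(y)
    if sol is None or not sol.success:
        raise FitError("nonlinear fit did not converge", best=sol,
                       diagnostics={"family": family})

    y_fit = y
    if random_max:
        if bird_ids is None:
            raise DesignError("random_max=True requires bird_ids")
        bird_ids = np.asarray(bird_ids)
        resid = y - _evaluate(family, sol.x, x)
        uniq, inv = np.unique(bird_ids, return_inverse=True)
        counts = np.bincount(inv)
        offsets = np.bincount(inv, weights=resid) / counts
        s2 = float(np.sum(resid ** 2)) / max(x.size - n_par, 1)
        var_off = float(np.var(offsets, ddof=1)) if uniq.size > 1 else 0.0
        sigma_b2 = max(var_off - s2 / counts.mean(), 0.0)
        shrink = sigma_b2 / (sigma_b2 + s2 / counts.mean()) if sigma_b2 > 0 else 0.0
        if shrink > 0:
            y_fit = y - shrink * offsets[inv]
            sol = run(y_fit)
            if sol is None or not sol.success:
                raise FitError("random-maximum refit did not converge", best=sol)

    theta = sol.x
    pred = _evaluate(family, theta, x)
    sse = float(np.sum((y_fit - pred) ** 2))
    dof = max(x.size - n_par, 1)
    # covariance from the Jacobian at the optimum
    try:
        cov = np.linalg.pinv(sol.jac.T @ sol.jac) * (sse / dof)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(n_par, np.nan)
    params = _make_params(family, theta)
    return FitResult(
        params=params, se=se,
        r2_adj=assessment.adjusted_r2(y_fit, pred, n_par),
        bic=assessment.bic(y_fit, pred, n_par),
        n_obs=int(x.size), sse=sse, param_names=names,
    )


def fit_broken_line(x, y, n_grid: int = 50) -> tuple[BrokenLineParams, FitResult]:
    """Fit the linear-plateau model by breakpoint profiling.

    The breakpoint is profiled on a grid of ``n_grid`` candidates between
    the 5th and 95th percentiles of ``x`` (ordinary least squares for the
    plateau and slope conditional on each candidate), then polished by
    bounded scalar minimization around the best grid cell. Ties break toward
    the smaller breakpoint. If the optimum sits at the lower grid edge or no
    observation lies below it, the breakpoint is flagged unidentified.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise DesignError("broken-line fit needs at least 4 observations")
    if np.ptp(x) <= 0:
        raise DesignError("no spread in x: breakpoint is undefined")
    lo, hi = np.percentile(x, [5, 95])
    if lo == hi:
        raise DesignError("degenerate design: all x at a single candidate")
    grid = np.linspace(max(lo, 1e-9), hi, n_grid)

    def profile(bp):
        z = np.maximum(0.0, bp - x)
        design = np.column_stack([np.ones_like(x), z])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        sse = float(np.sum((y - design @ beta) ** 2))
        return sse, beta

    sses = np.empty(n_grid)
    for i, bp in enumerate(grid):
        sses[i], _ = profile(bp)
    i_best = int(np.argmin(sses))  # argmin takes the first (smallest bp) on ties
    flat_profile = np.ptp(sses) <= 1e-10 * max(1.0, float(np.mean(sses)))
    if flat_profile:
        # breakpoint carries no information (e.g. pure plateau data):
        # report the lower grid bound and flag it
        bp = float(grid[0])
    else:
        bracket_lo = grid[max(i_best - 1, 0)]
        bracket_hi = grid[min(i_best + 1, n_grid - 1)]
        res = optimize.minimize_scalar(lambda b: profile(b)[0],
                                       bounds=(bracket_lo, bracket_hi),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        bp = float(res.x) if res.fun <= sses[i_best] else float(grid[i_best])
    sse, beta = profile(bp)
    plateau, slope = float(beta[0]), float(-beta[1])

    identified = not (flat_profile or np.isclose(bp, grid[0])
                      or np.all(x >= bp))
    params = BrokenLineParams(plateau=plateau, slope=slope, breakpoint=bp,
                              identified=identified)
    pred = eval_broken_line(params, x)

    # standard errors from the full three-parameter nonlinear Jacobian
    def resid3(theta):
        p, s, b = theta
        return p - s * np.maximum(0.0, b - x) - y
    try:
        sol = optimize.least_squares(resid3, [plateau, slope, bp],
                                     xtol=1e-12, ftol=1e-12)
        dof = max(x.size - 3, 1)
        cov = np.linalg.pinv(sol.jac.T @ sol.jac) * (sse / dof)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except Exception:
        se = np.full(3, np.nan)

    fit = FitResult(params=params, se=se,
                    r2_adj=assessment.adjusted_r2(y, pred, 3),
                    bic=assessment.bic(y, pred, 3),
                    n_obs=int(x.size), sse=sse,
                    param_names=("plateau", "slope", "breakpoint"))
    return params, fit
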