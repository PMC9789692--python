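# Methods

## The problem

Laying Japanese quail (*Coturnix japonica*) require dietary arginine:
birds lack the enterocyte pyrroline-5-carboxylate pathway, so arginine
cannot be synthesized and egg output responds directly to intake. The
package models a completely randomized dose–response trial — seven dietary
arginine levels (2.43–14.56 g/kg) × seven single-bird cages, eight weeks
with responses collected over the last four — and extracts from it the two
quantities a feed formulator needs: the maintenance requirement
(mg arginine per kg metabolic body weight per day) and the egg-mass
production requirement (mg arginine per g of egg).

## Derived variables

From each bird's raw record (feed intake FI g/d, egg production EP as a
fraction of days, egg weight EW g, initial/final body weight g) and a
composition table:

* arginine intake = FI × dietary level (g/d × g/kg = mg/d);
* egg mass EM = EP × EW (g/d);
* egg arginine deposition = EM × c, where the coefficient c defaults to
  egg protein (129.9 g CP/kg egg) × egg arginine (5.14 g/100 g CP) =
  6.68 mg/g. The deposition column of the source trial's published
  treatment means implies c ≈ 7.0 mg/g, so the coefficient is
  configurable (`Composition(egg_arg_coeff=...)`) and the golden tests
  pin the implied value;
* arginine mobilization = ΔBW × 9.40 mg/g ÷ 28 d (negative = body loss);
* metabolic standardization divides per-bird flows by (BW/1000)^0.67,
  with BW the per-bird mean of initial and final weight (the single
  body-weight column of the published treatment table sits between the
  initial and final values, which is consistent with this convention).
  The exponent is configurable; 0.67 is the conventional laying-bird
  scaling.

## Response families

With X = standardized intake and Y = standardized deposition
(mg/kg BW^0.67·d):

* **Monomolecular (Mitscherlich), four parameters** — evaluated as the
  shifted form Y = Rmax − (Rmax + Rmin)·e^(−k(X − Xm)), an increasing
  curve with asymptote Rmax that passes through −Rmin at the maintenance
  anchor Xm and reduces to the standard three-parameter monomolecular at
  Rmin = 0. (A non-increasing variant of the formula circulates in the
  applied literature; it cannot produce a rising dose–response and is kept
  only behind `form="printed"`.) Note this family is structurally
  over-parameterized: Y = Rmax − A·e^(−kX) with A = (Rmax+Rmin)e^(k·Xm),
  so on nonnegative data only Rmax, k and A are identifiable and the
  (Rmin, Xm) pair trades off along a ridge. Fitted curves, maintenance
  via a supplied Rmin, and all predictions are unaffected; individual
  (Rmin, Xm) estimates should not be over-interpreted.
* **Saturation kinetics (Hill-type)** —
  Y = (Rmin·km^n + Rmax·X^n)/(km^n + X^n), with km the intake at the
  midpoint (Rmin+Rmax)/2 and n the apparent kinetic order. All four
  parameters are identifiable.
* **Linear-plateau (broken line)** —
  Y = plateau − slope·max(0, breakpoint − X); the breakpoint is read as
  the requirement and plateau/breakpoint as the utilization efficiency.

Landmarks of the saturation curve (closed forms, each verified against
numeric optimization in the tests):

* maintenance analogue X|Y=0 → km·(Rmin/Rmax)^(1/n);
* inflection (maximum marginal efficiency dY/dX) →
  km·((n−1)/(n+1))^(1/n), defined for n > 1;
* maximum above-minimum average efficiency, argmax of (Y−Rmin)/X →
  km·(n−1)^(1/n), defined for n > 1. The "above-minimum" form is used
  because the average of total Y has no interior maximum when Rmin > 0.
  Note the ordering inflection < km < max-efficiency intake holds only
  for n > 2; for 1 < n < 2 the efficiency landmark falls below km.

## Fitting

Nonlinear least squares via `scipy.optimize.least_squares` with bounds
(all parameters nonnegative, n ≤ 50), a data-driven start
(max(Y), max(0, −min(Y)), 1/range(X), min(X)) plus two deterministic
perturbed restarts, and tolerances 1e−12; the lowest-SSE converged
solution wins. Standard errors come from the Jacobian at the optimum
(σ² · (JᵀJ)⁻¹ with σ² = SSE/dof). Non-convergence raises a `FitError`
carrying the best candidate.

A two-stage random-maximum mode approximates the mixed-model treatment of
bird-level maxima: per-bird residual means are shrunk by the estimated
variance ratio and the curve refit on offset-corrected responses. With one
observation per bird (this trial's design) the offset variance is not
separable from residual noise, shrinkage collapses to zero and the mode
equals the fixed fit — which is therefore the default and what all
reference results use.

The broken-line breakpoint is profiled on a 50-point grid between the 5th
and 95th percentiles of X (OLS for plateau/slope conditional on each
candidate), tie-breaking toward the smaller breakpoint, then polished by
bounded scalar minimization; a flat SSE profile (e.g. pure-plateau data)
reports the lower grid bound flagged `identified=False`.

## Screening

One-way fixed-effects ANOVA with linear and quadratic orthogonal
contrasts built by Gram–Schmidt on the actual unequal level spacing at
observation resolution; contrast F-tests use the within-level mean
square. Because each bird contributes one period-mean observation and
birds are the experimental units, the fixed-effects decomposition is
exact — no mixed model is needed at this stage. The outlier screen is
leave-one-out: each bird is compared with the mean ± k·SD (default k=3)
of the *other* birds in its treatment; including the candidate would
bound the attainable deviation at (g−1)/√g ≈ 2.27 SD in a 7-bird group
and make the screen vacuous. At most one bird per treatment is removed
per pass.

## Efficiency, requirement and the factorial model

Utilization efficiency is plateau/breakpoint of the broken-line fit of
deposition against intake, optionally after correcting the intake axis:
subtracting maintenance, and crediting mobilized body arginine (body loss
only) as additional supply — body-weight gain is not subtracted from
intake. Under this supply-credit convention the body-loss correction
*increases* corrected intake and lowers apparent efficiency; the
correction modes therefore coincide when no net loss occurs.

The per-treatment requirement statistic is
Req = (arginine intake − m·BW^0.67)/EM (mg/g), with m = 90 the
monomolecular maintenance estimate; rounding to integers is for display
only. The egg-mass coefficient q is the breakpoint of a linear-plateau
fit of egg production (%) against Req. On this package's least-squares
refit of the seven published treatment means that breakpoint is ≈16 mg/g,
not the published 25 mg/g — the published EP-vs-Req model is not the
least-squares optimum of the treatment means (it was presumably fitted to
per-bird values, which are not deposited) — so the reference coefficient
25 is shipped as a constant rather than claimed as a refit result.

The factorial model DAI = m·BW^0.67 + q·min(EM, 11) predicts daily
arginine intake (mg/bird·d) with an expected error band of ±12 mg; the
11 g/d egg-mass plateau prevents extrapolating the linear production term
beyond the observed response range. The packaged literature validation
table applies the model to three published quail studies; the published
version of that comparison did not apply the plateau (two rows have
EM = 11.13 g/d), so `validate` reproduces it with `em_plateau=inf`.
The arginine:lysine ratio uses the literature lysine factorial
(136 mg/kg^0.67 maintenance, 21 mg/g egg, ±19 mg).

## Model assessment

Adjusted R² = 1 − (1−R²)(n−1)/(n−p−1); BIC in the Gaussian form
n·ln(SSE/n) + (p+1)·ln(n) (error variance counted as a parameter — only
BIC *differences* on identical data are meaningful, and absolute values
from other software are not comparable). Bias assessment regresses
residuals on centred predictions: intercept b0 = overall scale
difference, slope b1 = prediction bias, precision = 1 − adjusted R² of
that residual regression (clipped to [0,1]); an unbiased predictor gives
b1 ≈ 0, precision ≈ 1. Degenerate cases (zero residuals, constant
predictions) return NaN for the undefined quantity instead of failing.

## Synthetic trials

`generate_trial` emulates the study conditions: the seven dietary levels,
seven birds per level, and a 28-d collection window. Feed intake follows
a monomolecular rule in the level (34.25·(1 − 0.778·e^(−0.0955·level)),
fitted once to the published D1–D6 intake means, spanning ≈13–26 g/d)
plus Gaussian noise (SD 1 g/d). Mean body weight is N(171, 8²) g. The
bird's standardized deposition is the true curve (default: the published
saturation parameters) evaluated at its realized standardized intake,
with a bird-level Gaussian shift of Rmax (SD 12, the order of the
published Rmax standard error) and residual noise (SD 15); negative draws
are clipped at zero with a warning. Egg weight interpolates the observed
level–egg-weight profile, egg production is back-solved from the target
egg mass (capped at one egg/day, with the excess carried into egg weight
so derived deposition still equals the target), and body-weight change is
back-solved from a deficit-driven balance — body arginine (9.40 mg/g) is
mobilized only when intake falls short of maintenance plus
deposition/0.59 — applied symmetrically around the mean body weight so
the derivation recovers it exactly.

What the generator does **not** emulate: week-level autocorrelation,
mortality, the intake depression at excess arginine (the published D7),
heteroscedastic or non-Gaussian residuals, and any real covariance
between body weight and intake. Passing parameter-recovery tests
therefore show the estimators are correct under the stated noise model,
not that the model is correct for real birds.

## Problem sizes and numerical choices

Simulation studies in the test suite use 200 seeded replicates of the
49-bird design (saturation km mean bias ≈ 0.04%, broken-line breakpoint
mean bias ≈ 0.05% under the default noise); these sizes keep the whole
suite under ten seconds while estimating mean bias to well under the
tested thresholds. Percentages in input tables are auto-normalized to
fractions with a warning; zero egg mass makes Req undefined (NaN) rather
than infinite; ties in breakpoint profiling resolve to the smaller
breakpoint; all arginine flows are mg/d, body weight in g (converted to
kg only inside the metabolic power).

## Known limitations

* The (Rmin, Xm) ridge of the shifted monomolecular family (above).
* Efficiency corrections assume a single maintenance value for all birds.
* The EP-vs-Req coefficient cannot be reproduced from treatment means
  (above); per-bird data would be needed.
* The random-maximum mode is a two-stage approximation, not a full
  mixed-model likelihood, and is inert for one-observation-per-bird
  designs.
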