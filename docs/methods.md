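# Methods

## Model

`h2mix` fits a nonlinear mixed-effects model to long-format panels of
age-adjusted mortality rates, one observation per (state, race, year). The
mean of series *i* (a state-by-race series) at model time t = year − 1974
is the hyperbolastic type II (H2) curve

    m(t; θ_i) = (θ_i1 + θ_i5) / (1 + θ_i2 · arcsinh(exp(−(θ_i3 + θ_i6) · t^θ_i4)))

— a sigmoidal family whose arcsinh-of-exponential composition gives more
shape flexibility than logistic or Gompertz curves. For a declining
trajectory θ_i2 < 0: the curve starts above its asymptote θ_i1 + θ_i5 and
relaxes onto it as the arcsinh term vanishes. Per-series parameters are
linear in the fixed and random effects, θ_i = A_i α + B_i b_i, with

* α = (level, level_race, shape, rate, rate_race, power): the Black-arm
  level and decay rate, their shifts for the White arm (Race = 1 codes
  White women, 0 Black women), and the shared shape coefficient and time
  exponent;
* b_i = (b1, b2) ~ N₂(0, V): series-level deviations of the level
  (per-100,000 units) and the decay rate (1/years), the two θ slots that
  are exactly zero in the fixed-effects reduction;
* y_ij = m(t_j; θ_i) + ε_ij, ε_ij ~ N(0, σ²_ε), homoscedastic across
  arms and series (a heteroscedastic per-arm hook exists in the simulator;
  whether real rate panels are homoscedastic across races is not knowable
  from published summaries).

Assumptions: rates are consumed as given (age-adjustment happens upstream);
series are independent given the fixed effects; a single binary covariate;
exactly two random effects. DF for t-intervals defaults to
(number of series) − 2 = 24 for the 26-series design, matching the output
convention of the reference analysis; it is configurable.

## Marginal likelihood and fitting

The random effects are integrated out by **adaptive Gauss–Hermite
quadrature**: for each series the integrand's conditional mode is located
by a damped Newton search using the exact 2×2 Hessian of the joint
log-density (Gauss–Newton fallback if the exact matrix loses positive
definiteness), and the tensor Hermite rule is recentred at the mode and
rescaled by the Cholesky factor of that Hessian. One node per axis gives
the Laplace approximation. The default is 9 nodes/axis: on full-length
(36-observation) series the 9 → 15 refinement moves the panel
log-likelihood by under 1e-4, while 7 nodes leaves ~1.5e-4. Short series
(a few observations) have markedly non-Gaussian integrands and need more
nodes; the oracle tests use 15.

Maximisation is quasi-Newton (L-BFGS-B) on transformed parameters — log
variances, atanh of the random-effect correlation, log σ²_ε — standardised
by fixed characteristic scales so that step conditioning does not suffer
from the orders-of-magnitude spread between, e.g., the level (~2.5) and the
decay rate (~0.005). Two-stage initialisation: a fixed-effects-only fit
positions α and σ²_ε before the marginal optimisation. The
fixed-effects-only model itself is fitted as plain nonlinear least squares
(trust-region reflective) with σ²_ε profiled out in closed form (RSS/n);
this keeps the zero-noise limit exactly solvable — a noise-free panel is
recovered to machine precision. Failed optimisations restart from seeded
jittered starts (3 by default); an unconverged fit is always flagged, never
silently returned.

Standard errors come from a central-difference observed-information matrix
on the transformed scale (steps proportional to the same characteristic
scales, which keeps them above evaluation noise for parameters sitting near
zero), inverted and mapped to the original scale by the analytic Jacobian
of the transform (delta method). If the information matrix is not positive
definite the SEs are reported as undefined with a diagnostic, not guessed.
Empirical-Bayes series curves (`predict_subject`) plug in the mode of
b_i | data at the fitted parameters.

Admissibility: parameters must keep the curve denominator ≥ 1e-8 and the
level positive over the declared time interval (default t ∈ [1, 36]);
violations raise a domain error rather than propagating NaN. Inside the
quadrature, excursions of b beyond the admissible region are handled by
flooring the denominator, which leaves the integrand finite and
negligible-weight there.

## Pace analytics

The pace of decline is the exact analytic derivative −dm/dt (positive
while the rate falls). `max_pace` combines a 64-point grid with bounded
scalar refinement and endpoint checks; a flat curve is reported as
degenerate at the left endpoint. `equal_pace_time` pre-scans the pace
difference at 512 points and polishes each sign change by Brent bracketing
(|Δt| well below 1e-6); identical parameter vectors are rejected as a
distinct condition (the difference is identically zero, not an isolated
crossing).

## Synthetic-data scenario

No per-state-per-year rate matrix is published, so the generator emulates
the study design: 13 states × 2 races × 1975–2010 (936 rows), each series
drawing its own b_i, plus truncated-at-zero Gaussian noise. The reference
calibration was fixed once, before any testing, by requiring that the two
population curves pass through the *combined* printed endpoint rates
(Black 13.95 → 4.20, White 4.88 → 2.24 per 100,000), that the Black:White
ratio narrows monotonically (2.86 → 1.88), that both arms have an interior
pace maximum a few years into the panel (as the fitted state curves do),
and that the Black pace dominates the White pace throughout:

* α = (2.5, −1.6352, −0.9353, 0.00534, −0.00302, 1.4)
* σ²_ε = 1.0442 — the residual-variance scale of the reference analysis
* V: v11 = 0.0225 (level SD 0.15, ≈0.85 per 100,000 of 1975-level spread
  between states), v22 = 6.4e-7 (rate SD 8e-4, ~15% of the Black decay
  rate), v12 = −2.4e-5 (correlation −0.2, mildly coupling high levels to
  faster decay). Random-effect draws are clipped at 4 SD per axis so no
  state can leave the admissible region; at these scales the clip is
  essentially never active.

What the generator does **not** emulate: age structure and death counts
(rates are drawn directly), spatial correlation between neighbouring
states, heteroscedasticity of observed rates (real sparse-population rates
are noisier), and secular changes in rate variance. Passing tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to their violation in real SEER
panels.

## Simulation-study results and a known bias

The recovery study (200 seeded panels at the reference calibration, each
refitted with 3 quadrature nodes — study-level conclusions are insensitive
to the node count) shows 95% Wald coverage between 0.89 and 0.96 for every
fixed effect, and mean estimates within ~2 Monte-Carlo SEs of truth for
level, level_race, shape and power. The two decay-rate effects carry a
small negative relative bias (~8% of the rate, ~3–4 Monte-Carlo SEs at 200
replicates, i.e. ~0.4 per-panel SEs). Probes show it is intrinsic
maximum-likelihood skew of this curve family at the calibrated noise scale,
not an implementation artifact: it is unchanged by quadrature refinement
(3 vs 9 nodes), by tighter optimizer tolerances (1e-9 vs 1e-11), and by
disabling the zero-truncation of simulated rates, and pure fixed-effects
nonlinear least squares at the same conditions shows the same bias even
more sharply. The asymptote of a still-declining 36-year series is an
extrapolated quantity; its skewed likelihood couples into the decay rate.

## Printed-value fixtures

The package ships transcriptions of the reference summary tables (per-state
and per-year mean/SD/CV/quartiles), the reference parameter table, and the
state endpoint rates quoted in the source's state narratives, each row
carrying a citation string. Known print inconsistencies are shipped as
printed and annotated in a `flag` column rather than corrected (e.g. an NC
CV of 0.89 inconsistent with its own mean and SD; a "5%" White decline
inconsistent with the quoted 5.1 → 2.5 endpoints). The parameter table's
row labels are unreadable in the source, so the package names its own
parameters and claims no row-by-row correspondence; Wald-interval
reconstruction from a printed row's estimate/SE agrees with the printed
interval only to ~2e-4 because the original engine rounded after, not
before, computing the interval.

Summary tables use type-7 (linear-interpolation) quartiles; the printed
quartiles are not asserted as exact targets because the underlying series
are unpublished and the original convention is unstated. Reporting
precision follows the printed convention: ratios to 2 decimals, percent
declines to the nearest integer, CV to 2 decimals.

## Problem sizes

Unit fixtures use 1–3 series with 3–10 time points; oracle integrations use
a 400² trapezoid grid over ±6 prior SDs; the recovery study uses the full
936-row design × 200 replicates; derivative consistency is checked at
2,000 random admissible points. These sizes make the whole suite run in a
few minutes on one core while keeping every check at the study's native
panel dimensions.
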