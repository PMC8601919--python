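# Methods

## Scope and model

`avitherm` analyzes steady-state thermoregulatory physiology of a small
passerine measured by open flow-through respirometry over a stepped
ambient-temperature (Ta) protocol.  The resting metabolic curve is
modeled as continuous piecewise-linear in Ta with two breakpoints — the
lower (Tlc) and upper (Tuc) critical temperatures delimiting the
thermoneutral zone (TNZ) — and evaporative water loss (EWL) as
flat-then-rising with a single inflection.  Basal metabolic rate (BMR)
is defined operationally as the mean *observed* VO2 at test temperatures
inside the fitted TNZ, not the fitted plateau value, and TNZ breadth is
Tuc − Tlc by construction.  Population values are per-individual
estimates aggregated to mean ± SE over converged fits; no simultaneous
population-level (GEE-style) fit is attempted.

## Respirometry reduction

Gas-exchange rates come from the dry-air, CO2-unscrubbed flow-through
equations with a fixed respiratory quotient of 0.70 (postabsorptive,
lipid-catabolizing birds):

    VO2 [ml O2 min^-1] = FR (FiO2 - FeO2) / (1 - FiO2 (1 - RQ))
    EWL [mg h^-1]      = FR (FeH2O - FiH2O) / (1 - FeH2O) * 0.803 * 60

with FR the mass-flow rate in ml min⁻¹ STP, water-vapor fractions
wvp/BP, and 0.803 mg ml⁻¹ the STP density of water vapor.  The
denominator choice (FiO2 rather than FeO2) matters by <0.1% at the
depletions involved; it is a documented constant of the implementation.

Analyzer drift is removed per analyte by a Catmull-Rom spline through
baseline anchor points (segment-midpoint time, trimmed mean of the
central 80% of the segment — the edges carry multiplexer switching
artifacts), with one-sided end tangents and linear extrapolation beyond
the anchors; the nominal incurrent value is added back.  A single
baseline segment degrades to a constant offset correction, logged.

Steady states use the "lowest stable 2-min" rule: among all contiguous
120-s windows of the instantaneous VO2 series whose internal SD is at
most 5% of the window mean (the stability threshold is a free,
configurable definition — "stable" has no standard operationalization),
the window with the lowest mean is selected, ties to the earliest; EWL
is averaged over the same window.  Animal samples earlier than 5 chamber
time constants (tau = volume/flow; 3.9 L gives 234 s at 1000 ml min⁻¹
and 78 s at 3000 ml min⁻¹) after the start of exposure are discarded.
The washout clock runs from exposure start rather than per analyzed
segment because the chamber is flushed continuously regardless of which
channel the multiplexer is reading; with the 360-s channel dwell a
per-segment discard would leave no usable data at the low flow rate.
The residual washout deficit at the first eligible window biases
recovered rates low by 0.3–0.5%, well inside the 1% round-trip
tolerance asserted in the tests.

## Breakpoint estimation

The broken-line model y = b0 + b1 x + sum_j d_j (x - psi_j)+ is fitted
by profiling: for fixed breakpoints the model is linear, so RSS(psi) is
evaluated exhaustively on a 0.05 °C grid inside breakpoint bounds
([12, 28] and [28, 38] °C for the VO2 fit, [20, 38] °C for EWL,
reflecting the protocol's coverage), then polished by bounded
golden-section search per coordinate.  With only 8 points per
individual a global grid search is far more reliable than iterative
linearization; the latter (gap-covariate updates,
psi <- psi + gamma/delta, tolerance 1e-4 °C, 50 iterations) is provided
for long series and agrees with the grid to <0.1 °C on well-conditioned
instances.  Grid ties break toward the midpoint of the bounds.  The
plateau slope is freely estimated, not constrained to zero.

Breakpoint SEs use the delta method on the gap reparameterization
(SE(psi) = SE(gamma)/|delta|).  A fit is flagged non-converged when the
RSS profile carries no breakpoint signal (constant response or
psi-indifferent RSS), when the design is rank-deficient, or when a
segment is left without any data point.  An outer segment holding a
single point is deliberately *not* flagged: continuity makes it
identifiable, and discarding such fits would bias the population mean
of the upper breakpoint downward.  Per-segment point counts are
recorded on the fit for callers preferring a stricter rule.

Small-sample behavior: under 5% multiplicative noise the per-individual
Tlc estimate is biased high by ~0.4 °C (the bias falls to ~0.06 °C at
2% noise and ~0.02 °C noise-free — the estimator is consistent); Tuc
and the EWL inflection are essentially unbiased.  The recovery
experiment (20 replicate 24-bird populations) reproduces the generating
truths within the tolerances the tests assert (1 °C for breakpoints,
0.05 ml O2 min⁻¹ for BMR).

## Morphometrics

Bill area treats the bill as an elliptical cone: pi * BL * (BW + BD)/4
(exact pi·r·L in the circular limit).  Tarsi area treats each tarsus as
an elliptical cylinder with semi-axes TW/2, TD/2 and the
root-mean-square perimeter approximation
P = pi * sqrt(2(a² + b²) − (a − b)²/2), doubled for two legs; the
semi-axis form of the correction term is used throughout (the
alternative full-width form changes areas by <2% at tit-like
dimensions).  Whole-body surface area uses a Meeh allometry
A = k·Mb^0.667 cm² with k = 10 by default (k is an argument; classic
passerine fits use k ≈ 8.1) — it serves only the order-of-magnitude
check that bill and tarsi are ~1% and ~3% of the integument.

Relative-size indices are residuals of log area on log wing length
(natural logs), fitted separately per sex because males are larger;
mass-independent physiological rates are residuals of log rate on log
body mass with the sexes pooled (the allometric mass correction is
shared; only the morphometric indices are sex-stratified).  Both
choices are configurable at the call site.

## Energetics

MHP = VO2 · 20 J ml⁻¹ / 60 (W); EHL = EWL · λ(Ta) with the linear
latent-heat approximation λ(T) = 2501 − 2.361·T J g⁻¹ (within 0.2% of
tabulated values over 0–50 °C, evaluated at chamber Ta); cooling
efficiency is the ratio EHL/MHP, meaningful at the three test
temperatures above Tuc (35, 37, 40 °C).

## Inference

Candidate models are every marginality-respecting subset of {sex, bill
index, tarsi index, bill×sex, tarsi×sex} (13 models; cooling-efficiency
responses add body mass, 26 models), fitted as Gaussian linear models
with sex coded 0/1, female reference.  Ranking uses
AICc = −2 logLik + 2k + 2k(k+1)/(n−k−1) with k counting coefficients
plus the residual variance and n taken from the rows actually fitted.
Akaike weights are computed over the full candidate set; the ΔAICc < 2
cut applies only to reporting and to the averaging set.  Averaging is
natural (conditional): each coefficient is averaged over the top-set
models containing it with renormalized weights, an unconditional SE
sqrt(sum w (SE² + (b − b̄)²)), and a 95% CI of ±1.96 SE; a top model
with weight ≥0.9 is returned unaveraged.  Full-model (zero-substitution)
averaging was deliberately not used: reported coefficient tables in
this literature carry single estimates per predictor with no zero rows.
Relative importance weights sum the full-set Akaike weights of models
containing a term.  VIF is computed on the main-effects design only
(interactions inflate it trivially).

## Synthetic data generator

The generator defines the study conditions: 24 individuals, balanced
sexes (deterministically interleaved so each individual's sex and
random substream are independent of population size), measured at the
8 protocol temperatures.  Latent truths per individual are normal draws
around Tlc 17.7 ± 1.6 °C, Tuc 34.5 ± 0.7 °C, EWL inflection
31.85 ± 0.27 °C, BMR 0.96 ± 0.12 ml O2 min⁻¹, truncated to keep
Tlc < Tuc − 5 °C.  The printed population dispersions are used directly
as between-individual SDs; within-individual measurement noise is
multiplicative lognormal with CV 0.05 on both VO2 and EWL (rates are
positive and right-skewed; the within-individual CV is a free parameter
of the generator, chosen once).

Slopes and EWL levels are not reported quantities; they were set a
priori to physiologically reasonable values: cold slope −0.05 and hot
slope +0.05 ml O2 min⁻¹ °C⁻¹ (a bird at 10 °C runs ~1.4× BMR and at
40 °C ~1.3× BMR), EWL baseline 120 ± 10 mg h⁻¹ and hot slope
48 mg h⁻¹ °C⁻¹ — the latter pair calibrated so the population mean
cooling efficiency at 40 °C is 0.83, the study-scale value.  Males'
EWL at 40 °C is additionally scaled by exp(effect · tarsi index); the
effect is on the log scale because the cooling-efficiency analysis is
log-transformed, and its default (4.2) is sized so the
tarsi-by-sex interaction model attains R² ≈ 0.5 at n = 24 — the
effect-size scale at which detection behavior is evaluated.
Morphometric means/SDs are literature-plausible Great tit values
(males larger in wing, mass, bill; tarsi identical); downstream tests
depend only on this relative structure, never on the absolute values.

Raw traces are forward-modeled by inverting the reduction module's gas
equations for the steady excurrent composition, relaxing toward it with
the single-compartment washout time constant (the only washout model
the chamber geometry supports), on the multiplexer schedule (300-s
baseline at the start, after every 2 animal segments, and at the end,
so drift anchors bracket all animal data), with optional linear
analyzer drift and additive Gaussian analyzer noise.  Seed handling is
one master seed with fixed per-individual spawn keys.

What the generator does **not** emulate: behavioral artifacts (activity
bursts, panting, wing drooping), body-temperature dynamics, circadian
drift in BMR, correlated morphometric dimensions, exposure-order
effects, or analyzer nonlinearity.  Passing recovery tests therefore
demonstrates correctness of the estimators under the stated statistical
structure, not robustness to every field contingency.

## Numerical choices and degenerate inputs

Grid RSS uses batched normal equations with a 1e-12 ridge (candidates
whose hinge falls outside the data remain solvable; the perturbation is
far below all tolerances); the final fit and the brute-force test
oracles use plain least squares.  Perfect linear fits (RSS ≈ 0) have
unbounded Gaussian likelihood and are flagged degenerate rather than
ranked.  Zero-variance t-tests return t = 0, p = 1 on equal means and
±inf, p = 0 otherwise.  Windows with no SD-qualifying candidate return
the minimal-SD window flagged unstable.  Traces whose post-washout
animal samples cannot fill a 2-min window are flagged at generation.

## Problem sizes

The recovery experiment uses 20 replicate populations of 24 birds (the
study's design) and the detection experiment 50 replicates; the
brute-force optimality check verifies 50 random instances against a
0.01 °C scan.  These sizes give stable Monte-Carlo summaries (seed-bank
SE well under the asserted tolerances) while keeping a full test run in
the low minutes on one CPU.

## Known limitations

* Individual-level fits at n = 8 points have wide breakpoint sampling
  error (SD ~2 °C for Tlc at 5% noise); conclusions should rest on the
  population aggregate, as the tests do.
* The EWL inflection and Tuc are near one another; at noise well above
  the default CV the one-breakpoint EWL fit can collapse toward the
  bounds.
* Model averaging reports conditional estimates; predictors appearing
  only in low-weight models carry optimistically small unconditional
  SEs, as is inherent to the method.
* The GEE-style simultaneous population fit used in parts of the
  originating literature is out of scope by design.
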