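# Methods and design notes

## Observation model

The observation unit is one behavioural record.  Record types constrain the
state space: haulout and surface records are pinned to their respective
known states, and dive records may occupy any dive state but never a
non-diving one.  This is semi-supervision in both directions; it reflects
that the tag itself, not the model, distinguishes diving from non-diving
behaviour.

Conditional on the state, the five streams are independent.  Families and
parameterisations:

- **Gamma** streams (duration, hunting depth) are parameterised by
  (mean, sd) and converted internally to shape/rate
  (k = m²/s², r = m/s²).  Mean/sd is what telemetry summaries report,
  and it keeps the working scale well conditioned.
- **Beta** (hunting proportion) uses (mean μ, precision φ) with
  a = μφ, b = (1−μ)φ.
- **Bernoulli** (bathymetry contact) is a single probability per dive
  state.  The model stream is the thresholded indicator; the continuous
  depth/bathymetry ratio is retained in the records table for reporting
  only.
- **Normal** (salinity).  Salinity is far from zero so the mean needs no
  bound.

Missing salinity or bathymetry-contact values simply drop that stream's
term from the record's emission density (and yield missing
pseudo-residuals); the record is never discarded.

## Transition model and covariates

Off-diagonal logits are linear in
(1, cos 2πh/24, sin 2πh/24, w̃, w̃·cos, w̃·sin), with the diagonal as the
multinomial-logit reference.  The interaction enters as the product of the
scaled week with both circular terms; this is the natural "hour × week"
interaction for a circular-by-linear design, and `covariate_design`
("full" / "no_interaction" / "intercept") exposes the choice.  The week
covariate is centred and scaled as w̃ = (w − 15)/10 inside the design row
for optimiser conditioning; coefficients are reported on this scale.

The transition matrix into record t is evaluated at record t's covariates
(its start time is the moment the transition completes).

The initial distribution per individual defaults to the stationary
distribution of the transition matrix at the first record's covariates
(`initial: stationary`); `uniform` and `estimated` (N−1 free logits) are
available.  Stationarity is the parsimonious choice for sequences that
start mid-deployment rather than at a behavioural boundary.

## Likelihood, gradient and optimisation

The forward recursion runs in scaled (linear) space with per-step
max-shifted emission weights, compiled with numba.  Because pinned records
admit exactly one state, the gamma duration terms of the two non-diving
states factor out of the path sum exactly; they are maximised in closed
form (Newton iteration on the gamma shape) and the numerical search covers
the remaining parameters.  The joint maximum is exact, not approximate.

Optimisation is L-BFGS-B on the unconstrained working scale (log for
positive parameters, logit for probabilities, raw for normal means and
transition coefficients) with an analytic gradient assembled from the
forward–backward identities: the emission gradient reduces to
posterior-weighted sufficient statistics per dive state; the transition
gradient to pair-posterior sums pushed through the softmax; the
stationary-initial term chains the smoothed first-record probabilities
through a central finite difference of the (small) logits→stationary map.
The gradient is verified against finite differences in the test suite.
Convergence tolerance is 1e-8 on the relative objective, with at most
2,000 iterations.

Multi-start: start 0 bins dive records into depth quantiles (one bin per
dive state) and seeds each state with its bin's sample moments; further
starts jitter that construction on the working scale (sd 0.35), keeping
depth means sorted.  Transition intercepts start near self-transition 0.9
with zero slopes.  Twenty starts is the default; each is deterministic
given (seed, start_id).  After fitting, dive states are relabelled in
increasing mean hunting depth, which resolves label switching and makes
fits comparable across starts and seeds.

Uncertainty: the covariance of the working parameters is the inverse of a
central-finite-difference Hessian (step 1e-4·max(1, |θ|)), computed lazily
on first access and block-diagonal between the profiled pinned-state gamma
blocks and the jointly-estimated block (exact, by the factorisation above).
A singular Hessian flags the covariance missing without failing the fit.

## Dive processing

- Hunting intervals are profile intervals with |Δdepth/Δt| **strictly**
  below 0.5 m s⁻¹; an interval at exactly the threshold counts as transit
  (conservative hunting classification).
- A dive with no sub-threshold interval still needs a depth for the model
  stream: it takes the mean depth of its slowest interval.
- Hunting depth is the duration-weighted mean depth of the longest hunting
  segment (weighting by interval duration over trapezoid midpoints).
- The hunting proportion is squeezed off the boundary with
  (p(n−1) + 0.5)/n, n the number of dives in the dataset, because the beta
  density is undefined at 0 and 1.
- Bathymetry contact: indicator of hunting depth ≥ 0.97 × bathymetry, with
  the ratio clamped to [0, 1] first because bathymetry grids err near steep
  topography.  The 0.97 fraction is a configuration default chosen so that
  dives hunting within a few per cent of the seabed count as bottom
  contact; it is exposed as `benthic_fraction`.
- CTD matching is two-stage linear interpolation — in depth within each
  bracketing cast, then in time between casts, queried at the dive's
  midpoint.  Beyond the deepest cast level the nearest level is used with a
  logged warning; with only one cast inside the 24 h window that cast's
  value is used; with none the value is missing.
- Local solar hour is UTC + lon/15 wrapped to [0, 24); week of year is the
  ISO week.  Both are evaluated at the record's start time.
- Record assembly keeps the earlier of two overlapping records (with a 1 s
  tolerance for tag-clock jitter) and drops records after a configurable
  cutoff date (default 2011-06-19, where transmission throughput collapses
  in the reference deployment).

## Synthetic data

The generator emulates the statistical structure the analysis assumes: a
Markov chain over behavioural states (homogeneous, or covariate-driven
through the same design as the model), per-state stream draws from the
emission families, timestamps advancing by each record's duration, and —
for the dataset writer — broken-stick profiles, CTD casts and bathymetry
constructed to be consistent with the drawn streams so the prepare stage
round-trips.

Reference scenarios carry per-state mean values representative of adult
Weddell seals in the southern Weddell Sea (six states for females including
a pelagic dive type; five for males).  Published summaries report means and
confidence intervals but not spread parameters, so the generating sds and
precisions are fixed, field-realistic choices: duration CVs of ~0.3–0.5
(dive durations are right-skewed), depth sds growing from 3 m (shallow) to
50 m (benthic), beta precision 30 (sd ≈ 0.09 at μ ≈ 0.5), and salinity sd
0.04 psu (within-water-mass variability is small compared with the
0.1–0.17 psu separation between state means).  Bathymetry-contact
probabilities printed as 0.00 are generated as 0.005, since an exact zero
sits on the boundary of the logit working scale.  Transition matrices for
these scenarios use self-transition 0.8 with off-diagonal mass proportional
to the long-run state occupancy, which yields realistic persistence and a
stationary distribution within ~0.01 of the target occupancy.

What the generator does **not** emulate: Argos location error, transmission
gaps and duty cycling, spatial autocorrelation of bathymetry along real
tracks, within-dive depth wiggles finer than the broken-stick points, and
water-mass structure beyond a linear-in-depth salinity proxy.  Passing
tests therefore demonstrate the correctness and calibration of the
machinery under the model's own assumptions, not robustness to the
messiness of field data.

## Diagnostics and derived quantities

- **Pseudo-residuals** are one-step-ahead conditional CDF values,
  conditioning the forecast state weights on the record's type (so non-dive
  records use only their duration, through their pinned state).  Continuous
  streams are Uniform(0,1) under the true model; the discrete contact
  stream uses a seeded randomised PIT.
- **Posterior predictive checks** simulate replicate datasets of the
  observed length from the fitted parameters and compare stream summaries
  (means, sds, quantiles, contact rate) with central 95% envelopes.
- **Equilibrium curves** solve δΓ(z) = δ on an (hour × week) grid
  (default hours 0–23.75 by 0.25; weeks 7, 15, 24 — late summer, autumn,
  midwinter).  Delta-method 95% bands propagate the transition-coefficient
  covariance through a central finite difference of δ with respect to the
  coefficients, on the probability scale, and are clipped to [0, 1];
  clipping after the delta method keeps the bands honest near the simplex
  boundary.  A parametric-bootstrap comparison in the test suite checks the
  endpoints agree to within 0.05.
- **Occupancy intervals** bootstrap over individuals (the natural exchange-
  able unit); a single individual falls back to a flagged within-individual
  block bootstrap.
- **Viterbi ties** break toward the lower state index so decoded output is
  deterministic.

## Model selection

`select_n_dive_states` fits each candidate dive-state count and ranks by
BIC (default; AIC reported alongside).  BIC is the conservative default for
picking the number of states in HMMs, where AIC tends to overfit
state-splitting of heavy-tailed streams.

## Problem sizes used in the checks

The packaged simulation studies use 20,000 records for parameter-recovery
checks (recovery errors there are a few per mille to ~1%), 5,000 for
residual calibration, 1,200 × 10 seeds for state-count selection, and 500
records × 500 replicates for the bootstrap comparison of equilibrium
intervals.  These sizes were chosen so each check's Monte-Carlo error is
small against its tolerance while the whole suite stays quick to run.

## Known limitations

- No random effects across individuals: parameters are shared within sex,
  as in the motivating analysis.
- Dwell times are geometric (ordinary HMM, not semi-Markov).
- Temperature is carried through processing for TS plots but is not a model
  stream.
- The equilibrium distribution is an instantaneous summary of Γ(z); it
  ignores that covariates drift during a visit to z.
- The exact on-tag broken-stick compression and CTD calibration are
  upstream of this package and are consumed as given.
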