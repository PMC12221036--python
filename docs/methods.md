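# Methods

This note records the modelling and numerical choices behind `kayakpace`,
their defaults, and what the synthetic validation does and does not show.

## Velocity normalisation

Split times arrive as per-50 m durations Δt_i (10 for 500 m, 20 for
1000 m). Segment velocity is v_i = 50/Δt_i. The race-average velocity is
defined as **total distance / total time**, not the unweighted mean of
segment velocities; the two differ by ~0.1% on realistic profiles. The
chosen definition is the physically standard one and makes the
normalisation contract exact: with u_i = v_i/v̄, the time-weighted mean
Σ Δt_i u_i / Σ Δt_i equals 1 identically (equivalently, the harmonic mean
of the u_i is 1). Durations are recoverable as Δt_i = 50/(u_i v̄) to
rounding error.

Profiles are indexed by segment midpoints (25, 75, …, p−25) m: a segment-
average velocity is best attributed to the segment's centre, and the
midpoint grid places the observed peak of the mean 500 m profile at the
second point (75 m), consistent with peak speeds early in the first 100 m.

Filtering removes every (Domestic, heat) record — domestic heats often lack
competitive depth — and nothing else automatically. Expert outlier removal
is represented only by an explicit caller-supplied exclusion list; no
automatic rule stands in for judgement. Records with missing or
non-positive splits are rejected, not imputed.

## Functional PCA

Curves live in a clamped cubic B-spline space (order 4) with equally
spaced interior knots: 8 basis functions for 500 m (10 observations per
race), 12 for 1000 m (20 observations). These counts keep the per-race
least-squares smoothing full-rank while denoising; both are configurable.
No roughness penalty is applied — at 10–20 points per curve the basis
dimension itself is the smoother, and a penalty would add a tuning
parameter the data cannot pin down.

All inner products use the exact B-spline Gram matrix, assembled by
per-knot-span Gauss–Legendre quadrature (exact for the polynomial
products), never grid quadrature. The covariance eigenproblem is solved in
coefficient space through the Cholesky factor of the Gram matrix, so
eigenfunctions satisfy ∫Φ_jΦ_k = δ_jk to machine precision and scores are
exact integrals. Scores are computed against mean-centred curves.
Variance explained is λ_k over the sum of the full eigenvalue spectrum.

Sign convention: each eigenfunction is oriented so that its value at the
location of its largest magnitude is positive. This is deterministic and
tends to orient the first component so that a positive score means a
front-loaded (dropoff) profile.

## Hidden Markov model

One chain per athlete; the initial distribution π and transition matrix A
are shared across athletes and estimated freely (π is not tied to the
stationary distribution). Emissions are Gaussian with **diagonal**
state-specific covariance — one variance per state per PC — and a mean
linear in the covariate indicators. Covariate coding drops the baselines
(Open age group, Domestic event), giving 4 indicators for the women's
model and 5 for the men's (adds U18).

EM details:

- E-step: scaled forward–backward, vectorised across sequences of equal
  length; per-step renormalisation makes underflow impossible for finite
  log-densities. Log-likelihoods are exact (sum of log scale factors).
- M-step: π from averaged first-step posteriors; A from Σξ/Σγ with rows
  renormalised onto the simplex; emission coefficients by per-state
  weighted least squares with posterior weights (one solve per state,
  shared design across the four PC dimensions); variances as weighted
  residual second moments, floored at 1e−8.
- Convergence: relative log-likelihood change < 1e−8 or 500 iterations.
  Per-iteration log-likelihood is non-decreasing (monotonicity is asserted
  in the test suite).
- Restarts: each restart initialises A at 0.85 on the diagonal with random
  off-diagonal mass, π uniform, state intercepts at random per-dimension
  data quantiles, covariate effects at zero, and variances at the pooled
  per-dimension variance. Restart seeds are spawned deterministically from
  the caller's seed. The restart with the highest final log-likelihood is
  kept. The default of 200 restarts matches the study protocol;
  tests and the state-count scan use 10–20, which already reach the same
  optimum on the synthetic cohorts.
- Degeneracy guard: a restart in which any state's total posterior mass
  falls below 1% of all observations (floored at the number of emission
  regressors + 1) is discarded as degenerate. Without this guard a
  near-empty state can collapse its variances onto a handful of points and
  inflate the likelihood without describing any real cluster — which
  biases AIC towards too many states. The guard is the model-level
  analogue of checking fitted models for collapsed states.

AIC is −2·loglik + 2k with k = (n−1) + n(n−1) + n·d·(c+1) + n·d for n
states, d = 4 score dimensions and c covariate indicators. The state-count
scan fits every candidate and returns the AIC minimiser; a candidate whose
restarts all degenerate is reported as +inf, never silently skipped.

A caveat from our simulations: when two states are separated by only
~1.5 pooled SDs (as states 1 and 4 of the published women's model are at
emission SD 0.2), the best (n+1)-state fit's log-likelihood gain hovers at
the AIC penalty itself, so the scan's 4-vs-5 decision carries real Monte
Carlo noise across simulated cohorts. The acceptance script therefore
repeats the scan on replicate cohorts and reports the modal selection.
Decoding is global (Viterbi) with ties broken to the lowest state index.
Recovery tests align state labels by Hungarian assignment on emission
intercepts before comparing parameters.

## Published-parameter tables

`kayakpace.tables` carries the reported four-state estimates for both
events (baseline intercepts, event-tier and age-group effects, transition
matrices) as the default simulation truth and for worked-example
evaluation of the emission equation. Two transcription notes: one men's
event-effect cell is printed with a malformed decimal ("−0.0.96") and is
read as −0.096, and transition rows that sum to 0.999–1.001 at printed
precision are renormalised on load. Per-state emission SDs are not printed
in the main text; the generator default is SD 0.2 on every state and
dimension, exposed in `SyntheticConfig.sigma`.

## Synthetic data generator

The generator emulates the cohort the analysis expects:

- **Careers**: 70 athletes by default, 10–40 races each; age groups
  progress monotonically (U18 →) U21 → U23 → Open with athlete-specific
  random change points; event tiers drawn i.i.d. per race at 0.60 / 0.25 /
  0.15 (Domestic / World Cup–Juniors / Champs–Olympics); phases include
  domestic heats (30% heat probability) so the filter is exercised.
- **States and scores**: latent paths from the published transition
  matrices (initial state from the stationary distribution); scores from
  the covariate-dependent state Gaussians.
- **Curves**: a shape library per event built inside the same B-spline
  space the fPCA stage uses — a mean curve rising to its peak at the
  second/third segment then declining (with a small late kick in the
  1000 m shape, the "seahorse" profile) whose midpoint values have
  harmonic mean exactly 1, plus four perturbation shapes (projected
  low-order cosine/sine contrasts) orthonormalised under the exact Gram
  matrix. A race's normalised curve is mean + Σ β_k·shape_k plus optional
  i.i.d. grid noise (default SD 0.01, a ~1% measurement/process
  perturbation); multiplying by a race-average velocity drawn at
  4.29 ± 0.23 m/s (women) or 4.80 ± 0.24 m/s (men) and inverting gives the
  split times.

Because the planted shapes span the analysis basis, the noise-free
pipeline round trip recovers planted scores almost exactly (the only slack
is the harmonic-mean renormalisation, second-order in the scores — bounded
by 0.02 in the tests). What the generator does **not** emulate: within-race
environmental drift, athlete-specific shape idiosyncrasies, non-Gaussian
score tails, and any dependence between consecutive races beyond the
Markov state. Passing recovery tests therefore demonstrate correctness of
the estimation machinery under the model's own assumptions, not robustness
to real-data violations of them.

One consequence of simulating from state means that are not axis-aligned:
the fPCA stage recovers the planted *subspace* but its eigenfunctions are
a rotation of the planted shapes (eigenvectors of the score covariance).
End-to-end recovery tests therefore compare fitted HMM intercepts against
the truth *expressed in the fitted score coordinates* (true state-mean
curves projected onto the fitted eigenfunctions); transition matrices and
decoded states are basis-free and compared directly.

## Problem sizes

Validation runs use cohorts of 100 athletes × 30 races (3 000
observations) for parameter recovery and state-count selection, 200–400
curves for fPCA recovery, 200 replicates of n = 1 000 run lengths for
goodness-of-fit calibration, and 10–20 EM restarts — sizes at which the
quantities under test are statistically resolvable while the full suite
runs in about a minute of CPU.

## Known limitations

- Full (non-diagonal) emission covariance, hidden semi-Markov dynamics,
  covariate-dependent transitions and joint fPCA–HMM estimation are out of
  scope.
- AIC order selection near state-overlap is noisy (see above); BIC would
  be more conservative but is not the protocol modelled here.
- The B-spline basis sizes assume complete races at 50 m resolution;
  sparse or irregular sampling is not supported.
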