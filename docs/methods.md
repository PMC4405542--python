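# Methods

## Models

A discretized trajectory is a sequence of planar positions; each step
has a bearing `y_t` in `[-pi, pi)` (radians, measured from east —
only angle differences ever enter a likelihood, so the reference
direction is immaterial and all estimates are invariant to a common
rotation of every angle) and a length `d_t`. A biased correlated random
walk (BCRW) makes the expected bearing a compromise between the
previous bearing and the bearing(s) `psi_kt` toward one or more
targets, through the compromise vector

    v_t = (cos y_{t-1}, sin y_{t-1}) + sum_k beta_k (cos psi_kt, sin psi_kt).

Its direction `mu_t` (two-argument arctangent) is the expected heading;
its length `l_t` measures the agreement between persistence and taxis
(`|1 - beta| <= l_t <= 1 + beta` for a single bias). The two-argument
arctangent makes `mu_t` invariant to adding full turns to any input
angle, which a convex combination of angles is not.

Three estimators of the bias strength are implemented.

**Angular model.** `y_t ~ vM(mu_t, kappa)` with constant concentration.
Parameters `(beta_1[, beta_2], kappa)` are estimated by maximum
likelihood.

**Consensus model.** `y_t ~ vM(mu_t, kappa * l_t)`: agreement between
goals sharpens the step. Writing `kappa_1 = kappa`, `kappa_{k+1} =
kappa beta_k`, the density is exponential-family,

    f(y_t) = exp{ sum_k kappa_k cos(y_t - a_kt) } / (2 pi I0(r_t)),

where `a_t = (y_{t-1}, psi_1t, ...)` and `r_t = kappa_1 l_t` is the
norm of the kappa-weighted resultant. The likelihood is well defined
for *any* real concentrations — a negative `kappa_k` is a repulsive
bias — so the optimization is unconstrained and negative estimates are
reported, not clipped.

**Step selection function (SSF).** Each observed step is paired with J
control angles sharing its anchors; a conditional-logistic likelihood
with covariates `cos(angle - y_{t-1})`, `cos(angle - psi_kt)` estimates
the same `kappa`'s. The link to the consensus model is the identity

    (1/2pi) ∫ exp{kappa_1 cos(t - a) + kappa_2 cos(t - b)} dt
        = I0(kappa_1 l),   l = agreement length of (a, b, kappa_2/kappa_1),

so with many uniform controls the per-stratum log-denominator converges
to `log I0(kappa_1 l_t)` and the SSF likelihood converges to the
consensus likelihood. Both the identity and the convergence rate are
exercised directly in the test suite.

## Estimation details

* Optimizers are quasi-Newton (L-BFGS-B) with analytic gradients;
  convergence at gradient norm 1e-8; concentrations are box-bounded at
  |kappa| <= 500 and estimates pinned there are flagged `at_bound`
  (noise-free data legitimately diverge to the bound). Consensus and
  SSF start at `kappa = 1` / `kappa = 0`; the angular fit optimizes
  `log kappa` and a softplus-transformed bias weight (`beta >= 0`),
  starting at `kappa = 1` and `beta = 0.1` — softplus cannot represent
  a start of exactly zero and its gradient vanishes far below it.
* Degenerate compromise vectors (`l_t < 1e-12`, e.g. exactly opposing
  unit goals at beta = 1) report direction 0 with a flag; the consensus
  density remains well defined there since `kappa l_t -> 0` is the
  uniform circle, so likelihood code never fails.
* Model-based covariance is the inverse observed information (numeric
  differentiation of the analytic gradient for the circular models; the
  exact analytic information for the conditional logit). Robust
  covariance is the sandwich `H^{-1} (sum g g') H^{-1}`. Scores are
  summed per animal before the outer product *when at least three
  animals are present*: with k clusters the cluster score sums add to
  zero at the optimum, so the meat matrix has rank at most k - 1 and a
  two-animal clustered sandwich is degenerate (rank 1); below three
  animals per-record scores are used instead. `sandwich_vcov` accepts
  arbitrary cluster labels for other designs (e.g. trails).
* Bias strengths `beta_k = kappa_{k+1}/kappa_1` carry delta-method
  standard errors (gradient `(-kappa_{k+1}/kappa_1^2, ..., 1/kappa_1)`)
  from the robust covariance; `kappa_1` within 1e-10 of zero makes the
  ratio undefined and is reported as NaN, never silently patched.
* The first record of each animal has no previous bearing and is
  dropped from every likelihood: two animals observed for 61 steps
  yield 120 usable records.

## Simulators

The Monte Carlo design simulates two independent animals on a
1024 x 1024 map, starting at uniform random pixels of the northwest and
southeast quarter-quadrants, biased toward the center pixel, 61 steps
each (120 usable records), step length 60 units for the continuous
models. Condition pairs `(kappa_1, kappa_2)` are (2, 2), (2, 0.5) and
(0.5, 0.5); the angular simulation uses error concentrations 3, 2 and
0.75 respectively. The initial bearing is uniform; it only seeds the
chain since the first step is excluded from likelihoods. Von Mises
sampling is Best–Fisher rejection (numpy's implementation), with
`kappa = 0` short-circuited to uniform draws.

**Landscape.** A stationary Gaussian random field with torus-wrapped
exponential correlation (range 20 pixels by default) is synthesized
spectrally and cut at its empirical quantiles so habitat codes 1/2/3
occupy fractions 0.8/0.1/0.1 exactly up to integer pixel counts. The
exponential kernel is rough: at 1024^2 the middle decile (habitat 2)
fragments into thousands of small patches rather than a few large ones.
`corr_range = 0` gives white noise.

**Discrete choice.** At each step the candidate set is the nearest
pixel of every 8-connected habitat-2 and habitat-3 patch lying more
than 60 units away (distance ties break to the lowest row-major index),
one of which is selected with probability proportional to
`exp{kappa_1 cos(y_j - y_{t-1}) + kappa_2 cos(y_j - psi_t)}`. Step
lengths therefore vary. A known property of this design: because every
patch of the map contributes a candidate, availability itself points
toward the map interior — which is also where the target lies — so the
apparent bias strength recovered by all three estimators exceeds
`kappa_2/kappa_1` (all three agree closely with *each other*; the
misspecification is shared). The tests therefore assert estimator
agreement, sign and variance ordering for this model, not centering.
Restricting candidates to the nearest pixel of each habitat type was
evaluated and rejected: it induces artificial anti-persistence and
destroys the bias signal.

**Consensus / angular walks.** Continuous-plane, unbounded, fixed step
length; target bearing recomputed from each step's origin.

**Pixel trails.** Raster walks choosing among the 7 neighbors of the
current pixel other than the one just vacated, with two taxes (target
bearing and nearest-gap bearing); `trail_ssf_design` rebuilds exactly
that choice set (1 case + 6 exhaustive controls, pixel-center to
pixel-center bearings, row 0 at the north edge), so the SSF refit is a
correctly specified conditional logit and recovers the generating
concentrations.

Master seeds spawn per-scenario and per-replicate `SeedSequence`
substreams, so any Monte Carlo cell reruns bit-identically in
isolation. Landscapes are regenerated each replicate by default
(`share_landscape` fixes one per scenario).

## What the synthetic data do and do not show

The generators emulate the study conditions: short pooled series, two
animals, a fixed known target, von Mises (or discrete-choice) steps.
They do not emulate GPS measurement error, irregular sampling,
behavioral state switching, step-length/turn correlation, or unknown or
moving targets — passing tests show correct inference *under the
stated models*, not robustness to those features of field data. The
discrete-choice scenarios probe one specific misspecification
(choice-set availability) only.

## Problem sizes

Recovery experiments run at 200 replicates per condition (the
full-scale study used 500); the reduced count keeps the Monte Carlo
error of cell means near 0.6% of the mean while the suite stays quick.
The SSF-vs-consensus agreement check uses one 500-step series with
J = 2000 uniform controls; the trail pipeline uses 100 replicates of
200 trails x 28 steps. All sizes are set in the tests and
`scripts/acceptance.py`, not hidden in the library.

## Known limitations

* The discrete-choice availability artifact above: recovered bias
  strength under that simulator is a property of the candidate-set
  geometry, not of the estimators.
* Clustered sandwich variances need enough clusters; with two animals
  the package deliberately falls back to per-record robust scores.
* Kuiper p-values use the asymptotic series with Stephens'
  finite-sample correction; they are accurate for n >= 8 but p-values
  extremely close to 1 are reported as exactly 1.
* No support for step-length covariates, land-cover selection terms,
  multi-state switching or home-range advection-diffusion models.
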