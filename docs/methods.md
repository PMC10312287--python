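# Methods

## The decomposition

The package treats a task-induced FC change on an edge as the sum of a part
predictable from network-input fluctuation and a residual, the
communication change.  The input proxies are graph-local: shared input is
proxied by the total variance (covariance-matrix trace) of the signals of
neighbors adjacent to both endpoints, and each unshared input by the
residual total variance of the exclusive neighbors of one endpoint after
regressing out all shared-neighbor signals (least squares, with
intercept).  Variances use the unbiased T−1 denominator throughout,
matching the internal standardization of the Pearson FC.

The baseline model `FC ~ shared + unshared₁ + unshared₂ + const` is fitted
per edge across baseline sessions by OLS.  The delta prediction has no
intercept: differencing removes the constant.  The identity
`ΔComm = ΔFC − predicted ΔFC` holds exactly by construction and is asserted
as such.  Edges whose baseline design is degenerate (a regressor constant
across sessions — e.g. an empty neighbor set, whose variance term is
defined as 0 — or collinear regressors) carry an undefined model; the
pipeline skips them and reports the count.  No Fisher z-transform is
applied to FC before the regression (an option exposes it).

Graphs come from thresholding the average baseline FC matrix at a sparsity
fraction (default 5%): exactly ⌊sparsity·P(P−1)/2⌋ strongest edges by
signed value (absolute-value ranking is an option), ties broken
lexicographically.  One graph serves all conditions.  The FC change of a
session is taken against the mean over rest sessions.

## Two-node validation model

Neural dynamics are a stochastic two-node Wilson–Cowan system with sigmoid
gain k = 0.5, recurrent self-coupling 2, and baseline inter-node coupling
1.  The shared input s(t) and idiosyncratic inputs I₁(t), I₂(t) are
zero-mean Gaussian *signals* with variances V_sh = 0.25 and V_un = 0.35 at
baseline: one independent draw per integration step enters the drift
directly, so the realized signal variance equals the configured variance
regardless of the step size (they are not scaled white-noise increments —
the variances are swept as signal variances).

Time constants and discretization are package choices: τ = 1 model time
unit, one unit = 1 s, Euler step dt = 0.05τ, one neural step per emitted
BOLD sample, 2000 emitted samples per run after a 200-step burn-in,
initial state at the zero-input fixed point (0.5, 0.5).  With these
choices the baseline mean FC lands near 0.5, inside the realistic
resting-state band (0.1–0.6) that the calibration test asserts.  All
randomness flows from a single scenario seed; run r of a batch depends
only on (seed, r), so any run is reproducible in isolation.

## Hemodynamics

The Balloon–Windkessel model maps each neural series (nodes and input
signals alike — the input-variance proxies are computed on BOLD-transformed
inputs) to BOLD, with the standard parameter set κ = 0.65 s⁻¹,
γ = 0.41 s⁻¹, τ_h = 0.98 s, α = 0.32, ρ = 0.34, V₀ = 0.02, k₁ = 7ρ,
k₂ = 2, k₃ = 2ρ − 0.2.  Inputs are mean-centered before integration so
baseline activity maps to the resting state (the sigmoid's fixed point
would otherwise saturate flow); centering is a flag.  Integration sub-steps
so the effective step is ≤ 0.01·τ_h.  The positive states f, v, q are
integrated in log space, which makes positivity structural; additionally
the inflow is floored at 1% of resting flow inside the derivative
evaluation, because the 1/f terms are stiff as f → 0 and physiological
inflow never vanishes.  The floor is inactive except during extreme
negative noise excursions.  Zero input yields an identically zero BOLD
output (asserted to 1e−9), the impulse response shows the canonical
peak–undershoot–return shape, and small-signal responses scale linearly
within 10%.

## Simulation protocol

The baseline scenario is run 500 times; the Eq.-style baseline regression
is fitted across runs, identified by run-to-run stochastic variation in the
realized input variances (the simulation analog of session-to-session
variation).  Sweeps cover V_sh ∈ [0.15, 0.35], V_un ∈ [0.25, 0.45] and
w₁₂ = w₂₁ ∈ [0.4, 1.6] on 5 evenly spaced points, 500 runs per point
(100 for the coupling sweep in the test suite), each grid point seeded
independently.  Communication change per run compares that run's FC and
variances to the baseline means using the baseline coefficients; slopes are
OLS of per-grid-value means on the grid; the sensitivity ratios are
|slope(FC)|/|slope(ΔComm)| per variance sweep, with 95% bootstrap CIs over
runs.

The ratio statistic deserves a caveat: the communication slope is designed
to be near zero, so the ratio's denominator is ill-conditioned and its
sampling distribution is heavy-tailed — the bootstrap CI should always be
read alongside the point estimate.  A common-random-numbers sweep option
(same per-run draws at every grid value) is provided for low-variance
*slope-direction* experiments, but is deliberately not the default for
ratios: with run noise removed, the communication slope collapses to the
baseline-regression estimation error and the ratio becomes less stable,
not more.  The qualitative pattern — FC slope positive for shared and
coupling sweeps, negative for unshared; communication dampened against
both variance sweeps but tracking coupling with nearly the same slope as
FC; partial correlation mirroring FC — is robust across seeds.  The
partial correlation residualizes both node BOLD series on the three input
BOLD series before correlating.

## Synthetic cohort generator

The parcellated pipeline is validated on a linear latent-factor generator,
not on chained neural-mass nodes: per session,
`y = (I − C)⁻¹(L·driver + noise)` followed by first-order autoregressive
smoothing (φ = 0.3).  Parcels partition into communities (default 50
parcels, 4 communities, 800 time points, 10 sessions per condition);
each parcel loads on its community's unit-variance driver with a loading
drawn once from U(0.5, 1.5) — heterogeneous loadings make within-community
FC graded, so thresholded graphs have ragged, realistic neighborhoods
rather than cliques.  Baseline coupling is a feed-forward set of
source → receiver pairs (25 pairs, weight 0.7, `C[receiver, source]` only):
the nilpotent structure keeps the mixing stable at any weight, gives each
receiver an idiosyncratic neighbor (its source survives the 5% threshold
at weight 0.7), and guarantees that perturbing the mutual coupling of two
non-source parcels changes exactly those two series and no other — which is
what makes coupling-recovery scoring exact.  Session-to-session variability
enters as amplitude jitter (default 20%) on driver and noise standard
deviations; this is the variation that identifies the baseline regression.
Condition perturbations change one mechanism at a time: an additive
symmetric coupling offset on listed edges, a multiplicative driver-amplitude
scale on listed communities, or a noise-amplitude scale on listed parcels;
every perturbation is recorded in a ground-truth ledger.

The model-implied correlation matrix is available in closed form (the AR
filter applies the same impulse response to every parcel and leaves
zero-lag correlations untouched; amplitude jitter averages out), which
provides the oracle for generator tests — e.g. two unit-loading parcels
sharing a driver of variance v over unit noise correlate at v/(v+1) — and
drives the principled selection of perturbation targets: the strongest
within-community edges of the expected thresholded graph whose three
neighbor sets are all nonempty, at most one per community, endpoints not
sources.

What the generator does not emulate: hemodynamic convolution at cohort
scale, evoked task responses (task sessions are "background-connectivity
like" by construction), motion or physiological artifacts, spatial
structure, and heavy-tailed noise.  Passing recovery tests therefore shows
the estimator chain is correct under its own assumptions, not that those
assumptions hold in scanner data.

Two null-model facts surfaced by testing are worth recording.  First, with
no condition differences the per-edge correlation between actual and
predicted ΔFC does *not* vanish: realized input variance covaries with
realized FC within any finite session by sampling alone, and the baseline
model legitimately tracks that; the correct null statement is the absence
of task-type information (ICC near its small-sample bias).  Second, the raw
ICC(1,k) of i.i.d. data is not centered at zero — 1 − MSW/MSB is
heavy-tailed below zero — so null behavior is asserted on the median and on
the floored estimate.

## Statistics

ICC(1,k) is computed from one-way ANOVA mean squares,
`(MS_between − MS_within)/MS_between`, with F = MS_between/MS_within on
(n_groups − 1, n_groups·(k − 1)) degrees of freedom; groups are task types
(rest included), raters are session indices, and the design must be
balanced.  Negative estimates are floored at 0 by default with the raw
value retained.  A paired Wilcoxon z-comparison of two per-edge ICC
distributions is provided as a descriptive utility.  Partial correlation is
the Pearson correlation of intercept-included least-squares residuals and
matches the precision-matrix form −Ω₁₂/√(Ω₁₁Ω₂₂) to 1e−10 on random
instances; rank-deficient covariates raise unless a minimum-norm flag is
set, and a residual that is numerically zero (a covariate explaining a
series exactly) is an error rather than a spurious correlation.

## Problem sizes

Defaults are desk-scale by design: the full three-sweep protocol at 100
runs per grid point takes tens of seconds on one CPU, the 500-run protocol
under a minute, and cohort pipelines a few seconds.  Criterion-style
validation cohorts use 20 rest sessions and 30% jitter where a
well-identified baseline regression is the point (shared-amplification
dampening; coupling-sign recovery at 72 parcels / 6 communities), and
graded coupling across three task conditions for the task-discrimination
contrast.  Everything scales up by configuration (up to 333 parcels) at
proportional cost.

## Known limitations

- The sensitivity ratios are convention-dependent (τ, dt, noise
  discretization, hemodynamic detail) and heavy-tailed; only their
  qualitative structure (both > 1, coupling slopes nearly equal) is a
  stable claim.
- The empirical-data preprocessing stack (motion handling, nuisance
  regression, evoked-response removal, surface mapping) is entirely out of
  scope; the pipeline consumes clean parcellated matrices.
- The baseline regression assumes a locally linear FC–variance
  relationship; large input excursions leave a nonlinearity residual inside
  ΔComm.
- Directionality of coupling is not addressed; the coupling perturbation
  and its recovery are symmetric.
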