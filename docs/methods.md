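# Methods

## Problem setting

A perennial crop in continuous production yields in repeated flushes: each
~50–60-day cycle traces one sigmoid in cumulative harvest, and cycles
follow each other for the life of the crop. Treatment questions ("does
compost raise the yield ceiling? does it speed up growth?") are therefore
per-flush questions, and the analysis splits the record into flushes
before fitting an interpretable growth curve to each.

## Flush segmentation

The pooled cumulative series (summed over all beds, one value per day from
the first harvest day onward) is smoothed, differenced daily, and passed
through a centered 7-day rolling mean; flush boundaries are local minima
of this harvest-rate series.

Smoothers. Either a penalized B-spline GAM (basis dimension `gam_basis_dim`,
default 18; penalty weight chosen by generalized cross-validation over a
log-spaced grid, second-derivative penalty so linear trends are
reproduced exactly) or a LOESS fit (`loess_span`, default 0.1).

Minima handling. Candidate minima are interior local minima of the rate
series (plateau ties resolve to the first day). Candidates closer than
twice `candidate_window_halfwidth` merge, keeping the deeper one; each
survivor is refined to the argmin within ± half-width, ties again toward
the earlier day. The half-width must be below half the expected flush
spacing, otherwise genuine neighbouring boundaries merge — with 40–60-day
flushes a half-width of 15 days is appropriate, and the 30-day default
mirrors the 60-day visual range practitioners use on mature, well-
separated flushes.

Smoother flexibility matters more than its family: the inter-flush valley
in the pooled rate is only ~10 days wide, so the smooth must resolve
features on that scale (LOESS span ≈ 0.06 on an 18-month record, or a GAM
basis of ~40). An oversmoothed fit displaces every detected minimum into
the valley's centre of mass.

Edge policy. The rolling mean uses shrinking centered windows at the
series edges rather than padding; boundaries never sit at the edges in
practice. Day coordinates are integers with day 0 = planting; flush *k*
covers [t_k, t_{k+1}) half-open, and flush 1 starts at the first harvest
day rather than at a detected minimum.

Offsets. The per-bed offset y_k is the bed's cumulative total at t_k (for
flush 1: just before the first harvest), so y' starts at zero and adding
y_k back reconstructs the original series exactly — the partition is
lossless by construction.

Sensitivity analysis. Each smoothing setting on a grid is re-run; settings
that change the number of boundaries are flagged non-comparable, the rest
score the RMSE of their boundary-day shifts against the reference setting,
and the recommended setting minimizes the mean RMSE over its grid
neighbourhood.

## Gompertz nonlinear mixed model

Per flush, cumulative yield of bed *i* follows
y' = A_i exp(−exp(B_i − C t')) + ε with A_i and B_i decomposed into
treatment fixed effects plus additive normal block and bed random effects
on the natural scale; C is shared by all beds (block effects on B can be
disabled with `block_on_b=False`). Residuals are iid normal; observation
weights multiply the per-observation log-likelihood contributions
(equivalently inflate residual variance by 1/w), which implements the 0.01
down-weighting of harvest-pause windows. The random-effect covariance is
diagonal (independent A and B effects).

### SAEM estimator

Each iteration runs `n_kernel` (default 2) Metropolis-within-Gibbs sweeps
over bed effects (accepted independently per bed) and block effects
(accepted per block), with proposal scales adapted toward ~35% acceptance
during burn-in only, so the averaging phase is a fixed kernel. After
sampling, the within-treatment means of the bed effects and the grand
means of the block effects are absorbed into the fixed effects
(recentring); this is a reparametrization of the same model that decouples
the slow fixed-effect/random-mean direction of the chain and is what makes
the estimator collapse cleanly onto nonlinear least squares when the true
random-effect variances are zero.

Sufficient statistics (per-bed offset means, second moments of the
effects, weighted residual sum of squares) are smoothed with step size 1
for `n_burnin` iterations (default 300) and 1/m for `n_smooth` more
(default 100). The M-step updates σ² and the variance components in
closed form and advances the fixed effects (a, b, C) by up to three damped
Gauss-Newton steps with an analytic Jacobian, warm-started from the
previous iterate; C is constrained positive.

Variance components receive a restricted-likelihood-style
degrees-of-freedom correction before reporting — bed: n_beds/(n_beds −
n_treatments), block: G/(G − 1) — because the recentring removes exactly
those fixed-effect means from the sampled effects, so raw second moments
underestimate the variances the way ML does. Without the correction, Wald
intervals for treatment contrasts undercover noticeably in designs with
only three beds per treatment.

Start values default to (A, B, C) = (1000, 2, 0.1), which suit bed-scale
stem counts; `data_driven_start=True` instead uses A₀ = 1.05·max y' and
(B₀, C₀) from regressing −log(−log(y'/A₀)) on t', exact on clean Gompertz
data and useful when the yield scale differs by orders of magnitude.

Convergence is declared when the per-iteration relative slope (linear fit
over the final 50 iterations of each fixed-effect trace, normalized by the
estimate) stays below `convergence_rtol` (default 1e-4); otherwise the fit
raises a diagnostic error carrying the full trace. With a fixed
`NlmeSpec.seed` the whole run is bit-reproducible.

Standard errors and contrasts. The fixed-effect covariance is the inverse
Fisher information of the marginal model linearized at the estimated
random-effect means: V = σ²W⁻¹ + Z_bed Ω_bed Z_bedᵀ + Z_blk Ω_blk Z_blkᵀ
and Cov(θ) = (Xᵀ V⁻¹ X)⁻¹. Treatment-vs-control differences in A and B use
this joint covariance for their Wald intervals; when only marginal SEs
exist (two-stage estimator) the covariance term is set to zero and the row
is flagged, which is conservative for positively correlated estimates.

Two-stage fallback. For degenerate or very small data a deterministic
alternative fits each bed by nonlinear least squares, averages C, refits
(A_i, B_i) with C fixed, and takes treatment means with moment-based
variance components; results always name the estimator used.

Reported fit quality is Efron's R² of the conditional (bed-level) fit.

## Additive mixed benchmark

The flexible reference model is cumulative yield ~ smooth(t') + treatment
+ (1|bed) + (1|block) with normal residuals. The penalized spline (B-spline
basis of dimension k, default 5, second-difference penalty) is cast in
mixed-model form: the penalty null space (constant and linear trend)
enters as fixed effects and the scaled penalized directions as one
variance component, so smoothing amount, random-intercept variances and
σ² are estimated jointly by (RE)ML. The variance-component likelihood is
multimodal in degenerate cases, so the fit keeps the better of two
optimizers (Powell handles boundary solutions). Conditional fitted values
use explicit BLUPs u_c = λ_c Z_cᵀ V⁻¹ (y − Xβ).

Basis dimension is selected by refitting over a grid with maximum
likelihood (models differing in effective fixed structure should not be
compared by REML) and taking the smallest k whose AIC is within 2 units of
the grid minimum. Residual-normality diagnostics (D'Agostino-Pearson) are
exposed because the normal response is an approximation over integer
counts.

Because the model has a single shared smooth plus treatment intercepts,
it fits parallel curves: it saturates (R² ≥ 0.999) on homogeneous data but
cannot track treatment-specific curve shapes, which is precisely the
interpretability/flexibility trade-off the parametric comparison is meant
to expose. Comparison tables report per-observation prediction
differences, the R² gap, and where the largest disagreement occurs
(typically the beginning and end of a flush).

## Synthetic-data generator

The generator emulates the motivating trial: 5 treatments × 3 blocks = 15
beds, daily integer counts over a 560-day horizon, ~8 flushes. Per flush
it draws a block effect on A (SD 50 stems), bed effects on A and B (SD 80
stems and 0.1), evaluates the Gompertz curve per bed, perturbs the
cumulative trajectory with iid normal noise (SD 5 stems — differenced onto
the daily increments with carry-forward, so a noisy day is compensated
later, the perturbation never integrates, and the flush total stays
anchored to the realized asymptote), enforces monotonicity, and emits
integer counts by carry-forward rounding (cumulative error ≤ half a stem).
A bed whose realized asymptote would be non-positive is redrawn with a
warning. One seed governs the experiment; per-bed substreams are spawned
deterministically so any bed re-simulates identically in isolation.

Two parameter presets exist:

- `default_flush_truths` — the realistic trajectory: irregular flush
  windows (starts 91, 129, 186, …, 490), asymptotes rising ~1000 → ~3300
  stems with a final-flush dip, B low in the short first flush then
  declining, C = 0.1 throughout; compost treatments gain ~300 stems early
  with the advantage fading at maturity, and the half-fertigation
  treatment keeps pace through flush 4 before falling back to control.
  These windows truncate each curve at ~93–97% of its asymptote, as real
  flushes blur into each other.
- `evenly_spaced_flush_truths` — the identifiable design for boundary-
  recovery studies: equal gaps, B = 2.5 and C = (B+4)/gap so each curve is
  ~98% complete at the next start. Closed-form analysis of the pooled
  expected rate shows the inter-flush minimum then falls on the generative
  start day itself; with the truncated realistic preset the minimum is
  displaced several days into the valley, so "the true boundary" is only
  sharply defined for this preset.

An optional harvest-pause artifact zeroes a day window and redistributes
the withheld stems uniformly over the catch-up window (remainders to the
earliest days), conserving totals exactly.

What the generator does not emulate: plant-level processes (shoot counts,
pruning), weather and disease shocks beyond what per-flush parameter
changes encode, carry-over between flushes, and any observation-noise
structure beyond the bounded iid perturbation — real harvest-count errors
may be burstier. Passing recovery tests therefore demonstrate estimator
correctness under the stated model, not robustness to every field
pathology.

## Numerical choices and degenerate inputs

- Variance components are floored at negligible positive values so the
  MCMC kernel stays proper; the floor is far below any scientifically
  meaningful variance.
- Gauss-Newton uses Marquardt damping scaled by the diagonal of JᵀWJ, so
  the very different parameter scales (A ~ thousands, C ~ 0.1) need no
  manual normalization.
- Flushes with all-zero y', beds with fewer than 5 observations, and
  missing treatments are rejected with explicit errors; a treatment
  represented by a single bed fits but warns that random effects are
  weakly identified.
- In the CSV reader, negative or non-integer counts, duplicate (bed, day)
  rows and day gaps are rejected with the offending row or gap named.
- Pipeline runs isolate failures per flush: a flush whose fit fails is
  logged and skipped, and the report accounts for every detected flush as
  either a fit or a logged failure.

## Problem sizes

Simulation studies in the test suite and the acceptance script use the
trial-scale design throughout (15 beds; single flushes of ~60 days for
estimator studies, full 8-flush horizons for segmentation and pipeline
checks), with 10–20 replicate seeds for recovery and coverage summaries —
enough replication for stable medians while keeping a full run in the
tens of seconds.

## Known limitations

- Confidence intervals are Wald-type with z quantiles; with 3 blocks and
  15 beds they are mildly optimistic even after the df correction
  (observed contrast coverage ≈ 92% at nominal 95% in the recovery study).
- No uncertainty propagation across flushes: cumulative multi-flush
  predictions would need the cross-flush covariance of parameter
  estimates, which consecutive-flush correlation makes non-trivial; this
  is deliberately out of scope.
- The boundary day of a truncated flush sequence is a soft quantity; on
  the realistic preset detected boundaries sit a few days after the
  generative window starts, and estimates of B inherit that origin shift
  (a boundary displaced by d days shifts B by about C·d).
- Only the Gompertz law is implemented; the model surface (parameters,
  gradient, start values) would admit other monophasic sigmoids, but none
  are provided.
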