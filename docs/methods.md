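# Methods

## The model

`tfcdiff` models the time evolution of a scalar clinical parameter —
thoracic fluid content (TFC, the inverse of chest impedance, 1/Ohm) as
registered in heart-failure monitoring — as an anomalous-diffusion
process.  The probability density P(x, t) obeys a fractional
Fokker–Planck equation (FFPE)

    ∂P/∂t = D_t^{1−α} K_α ∂²P/∂x² ,       0 < α < 2,

where D_t^{1−α} is the Riemann–Liouville fractional derivative and K_α a
generalized diffusion coefficient.  The package does not discretize this
operator; it evaluates the equation's closed-form free-space Green's
function

    P(x, t | x₀) = f_{β,γ}(t, g) / (2√K_α),
    f_{β,γ}(t, g) = t^{−(1+β)} Σ_{k≥0} (−g t^{−γ})^k / (k! Γ(−kγ − β)),
    β = α/2 − 1,  γ = α/2,  g = |x − x₀| / √K_α .

At α = 1 this is the Gaussian heat kernel; for α < 1 the density has a
cusp at the origin and heavier-than-Gaussian tails, so large sudden
excursions of the monitored parameter ("grey swans" in the risk
vocabulary) are ordinary events rather than anomalies.  The second
moment grows as

    ⟨(x − x₀)²⟩ = 2 K_α t^α / Γ(1 + α) ,

i.e. Hurst exponent H = α/2; H = 1/2 is ordinary diffusion.

Normalization convention.  Some presentations scale the similarity
variable by √(Γ(α+1)K_α) instead of √K_α.  The two conventions differ
only by the reparametrization K_α ↔ Γ(α+1)K_α, leaving α, H and all fit
qualities unchanged; this package uses the g = |x−x₀|/√K_α convention
throughout because it is the one under which the Laplace-domain
representation P̃(x, s) = s^{α/2−1}/(2√K_α) · exp(−|x−x₀| s^{α/2}/√K_α)
and the moment law above hold simultaneously, and both are verified
numerically at build and test time.

The MSD is implemented with a positive time exponent (variance grows
with time).  Renderings of the scaling law as t^{−α} (equivalently
t^{−2H}) appear in parts of the source literature; with a negative
exponent the variance would decay, contradicting the accompanying text,
so it is treated as typographical.

## Units

One time unit is one 31-day registration period (the protocol's
accumulation window), so K_α carries (1/Ohm)² · period^{−α}.  The
synthetic cohort simulator works internally in days and converts at
binning time.  The source material does not state time units for K_α;
the period convention is this package's choice.

## Numerical evaluation of the propagator

The series is alternating, with reciprocal-Gamma coefficients (entire,
so Gamma poles contribute exact zeros — at α = 1 every odd term).  Terms
are computed in log space and summed with compensated (Kahan) summation;
truncation at `term_tol = 1e−14` or `k_max = 250` terms, whichever
first, requiring two consecutive sub-tolerance terms so pole zeros never
fake convergence.

Three practical failure modes are handled explicitly:

1. **Cancellation** (large z = g/t^γ at α near 2): the double-precision
   sum loses digits faster than tolerance.  A guard estimates the
   rounding amplification (largest term × machine epsilon against the
   sum); failing points are resummed with the same series in
   arbitrary-precision arithmetic (mpmath), with coefficients cached per
   exponent pair.
2. **Term-count explosion**: the series' turnover index grows as
   (zγ^γ)^{1/(1−γ)} and explodes as α → 2.  Points whose turnover lies
   beyond the truncation budget are routed directly to the
   Laplace-inversion evaluator.
3. **Far tail** (z > `regime_threshold` = 5): evaluation switches to the
   exact Laplace-domain representation inverted on a fixed-Talbot
   contour — double precision (64 nodes, ~1e−9 relative) in the
   moderate band, escalating to arbitrary precision with doubled degree
   and digits until two consecutive evaluations agree.  Deeply
   suppressed values (saddle suppression > 25 nats below the peak scale,
   i.e. below ~1e−11 of it) use the one-term steepest-descent
   (stretched-exponential) asymptote, whose few-percent relative error
   is far below every downstream absolute tolerance; it is exact at
   α = 1.

`laplace_oracle` exposes the arbitrary-precision Talbot inversion as an
independent cross-check of the series; the two routes agree to better
than 1e−6 relative on the tested grid (α ∈ {0.47, 0.8, 1.2, 1.5},
z ≤ 3), and a contour that fails to stabilize raises instead of
returning a number.

Normalization and moment quadratures integrate the series over the
central region and add closed Laplace-domain tail terms (tail mass
= L^{−1}[s^{−1}e^{−g₀s^γ}], a Mittag-Leffler-type survival function;
the tail second moment analogously), one inversion each.  The heavy
tails matter: at α = 0.47 roughly 10% of the variance lies beyond
z = 5.

## Evolution of binned distributions

Observed data are hit counts in 15 contiguous half-open value slots
(a value on an interior edge belongs to the upper slot; the top edge is
closed).  `evolve_distribution` convolves the slot masses with the
propagator using the midpoint rule at slot centers; a dense mode
(`refinement` cells per slot, re-binned by summation) converges to the
exact piecewise-constant convolution and serves as the internal oracle.
Midpoint accuracy requires the kernel to be resolved by the slots
(spread ≳ 2–3 slot widths); in the near-delta limit the renormalization
step restores the identity map exactly, so both extremes are safe and
the intermediate regime is where the dense mode is worth its cost.

The observable range is physiologically bounded while the free-space
propagator is not; mass leaking past the outer edges is truncated and
the distribution renormalized.  Reflecting or absorbing boundaries would
require a different Green's function; truncation-plus-renormalization is
a modelling choice, documented rather than inferred.

## Fitting (α, K_α)

`fit_params` scores candidate parameter pairs by the root-mean-square
error between evolved model slot masses and observed per-period slot
frequencies — the same criterion the clinical analysis uses — over a
coarse grid (α from 0.05 to 1.95 in steps of 0.05; K log-spaced 1e−2 to
1e2, 41 points) followed by Nelder–Mead polish in (α, log₁₀K).  The
polish is clamped to the grid hull: as α → 2 the propagator degenerates
toward ballistic peaks and no evaluator is reliable there.  Ties break
toward smaller α, then smaller K.  Out-of-range pairs are rejected at
construction; the winning pair's full admissibility report (nonnegative
density, unit mass, slot masses ≤ 1) is attached to the result.  The
Hurst exponent is reported as H = α/2 exactly.

Two pairings of initial and target distribution are supported, because
the registration protocol admits both readings:

* `initial="stationary"`, `target="final_period"` (default): evolve the
  pooled distribution over the whole window and compare with the final
  period.  This mirrors the protocol's "stationary distribution, closed
  over five months" description.
* `initial="first_period"`, `target="all_periods"`: evolve the first
  period's own frequencies forward and score every later period at its
  elapsed time.

For **parameter recovery** only the second pairing is identifiable.  The
pooled distribution is a time-average and therefore wider than every
early period; evolving it forward can only widen it further, so the
optimum collapses to K → 0 ("don't move"), leaving α unconstrained.
Recovery experiments in the test suite and the acceptance script use
first-period/all-periods with the full 12-month follow-up binned into
12 periods (which also uses ~94% of the simulated measurements instead
of the 40% that fall in a 5-period window).

Identifiability is intrinsically weak at clinical sample sizes: the RMSE
objective has a pronounced α ↔ log K ridge (the data pin the mid-window
spread well, the curvature of spread-versus-time — which separates α
from K — poorly).  The estimator is unbiased in the large-sample limit
(fitted α 0.80–0.82 at 50k observations for a true 0.8), but at ~5000
observations the replicate scatter is σ(α̂) ≈ 0.13–0.15, so individual
cohort fits carry substantial uncertainty; see "What passing tests show"
below.

## Synthetic cohorts

The generator emulates the registration protocol that produced the
(undeposited) clinical data: 605 patients by default, followed up to 372
days, Poisson visit counts (floored at one visit) at a mean of 2860/605
≈ 4.73 visits per patient so the expected cohort-wide measurement count
matches the study's 2860, visit times uniform over follow-up, values
binned into 15 equal slots spanning 20–80 value units per 31-day period
over a 5-period window.  Slot edges, the value range, and the visit-time
law are configuration, not claims about the original cohort, which never
published them.

The latent dynamics are an uncoupled CTRW — Pareto waiting times
(survival (w/τ)^{−α} for w ≥ τ) alternating with Gaussian jumps — the
microscopic process whose hydrodynamic limit is the FFPE.  Defaults:
jump scale 3 value units (slot crossings common within one period),
waiting scale τ = 2 days, latent exponent 0.47 (the value the model
estimates from the clinical data).  Patient initial values draw from a
discretized normal (mean 40, sd 8) baseline.  Reproducibility: each
patient's stream derives from (root seed, patient id), so growing the
cohort never reshuffles existing patients.

CTRW scaling experiments use a smaller waiting scale (0.02 days) and a
late window (100–372 days): Pareto renewal theory has a transient of
relative size (τ/t)^{1−α} which, at α = 0.8, biases the measured log-log
slope by about −0.05 for any window reachable with τ ≳ 0.5 d.  The
chosen regime measures slopes of 0.50 and 0.77 for configured exponents
0.5 and 0.8.

### What the generator does and does not emulate

It reproduces the registration structure (irregular correlated visits,
binning, approximate stationarity of the pooled distribution) and the
subdiffusive latent scaling.  It does not model therapy feedback,
measurement error, patient dropout, inter-patient parameter
heterogeneity, or any physiological TFC dynamics.  Passing tests
therefore demonstrate that the pipeline recovers its own model's
parameters from data with the assumed structure — not that clinical TFC
series are subdiffusive, and not that the fitted clinical exponent is
correct.  CTRW aging (the ensemble is non-stationary for α < 1, while
the fitted propagator is age-zero) is one deliberate mismatch between
generator and fitted model that keeps the recovery experiment from
being a pure inverse crime.

## Known limitations

* No uncertainty quantification on (α, K_α); point estimates only.
  The recovery experiments quantify the sampling scatter empirically
  (σ(α̂) ≈ 0.14 at 5000 observations) and should be read as the error
  bar to attach to any single-cohort fit.
* No drift term (therapy modelled as drift is a different model) and no
  bounded-domain Green's functions.
* The evolution step treats each registration period as a single time
  point at its offset; within-period visit-time mixing is ignored on
  both the model and data side symmetrically.
* Fits with α near the upper grid edge (≥ 1.9) rely on the saddle/Talbot
  evaluators in part of their (z, t) range; accuracy there is bounded by
  the contour-agreement check rather than the series tolerance.

## Problem sizes used in tests and the acceptance script

Propagator checks run on grids of ~100 points per (α, t); the CTRW
scaling check uses 1e5 walkers per exponent; recovery uses 20 cohorts of
~5000 observations (1058 patients); the study-scale illustration fits a
single 605-patient, ~2860-measurement cohort at latent exponent 0.47.
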