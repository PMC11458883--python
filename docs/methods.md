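# Methods

## Model structure

`myelosim` is a deterministic state-transition cohort model of sequential
treatment in transplant-ineligible multiple myeloma.  The health states
are: progression-free on line 1…K (K ≤ 4), post-progression after the
final line (partitioned mode only), and dead (absorbing).  A cohort of
mass 1 starts progression-free in line 1.

Time advances in cycles of Δ = 14/365.25 years (2 weeks) over 1044 cycles
(40 years).  Within line *k*, the progression-free fraction follows a
survival curve S<sub>k</sub> in *time-in-line*: the conditional event
probability for a sub-cohort that has spent *u* cycles in the line is
q<sub>k</sub>(u) = 1 − S<sub>k</sub>((u+1)Δ)/S<sub>k</sub>(uΔ).  Because
q depends on u, the model is semi-Markov and the cohort is tracked over
(line, time-in-line) tunnel states.  The implementation is an exact
convolution: occupancy of line k at cycle t with time-in-line u equals
entrants<sub>k</sub>(t−u)·S<sub>k</sub>(uΔ), so each line's
progression-free series and event series are single `numpy` convolutions
of the entrant stream with the survival grid and its decrements.  This is
O(n²) per line (~10⁶ multiply-adds at 1044 cycles), exact to machine
precision, and avoids the bias of collapsing the curve to a homogeneous
rate.

Timing convention: events resolve at cycle end; the attrition fraction
a<sub>k</sub> of event mass enters line k+1 at the start of the following
cycle with u = 0; the complement moves to dead.  No half-cycle correction
is applied, and outcomes are not discounted.  State occupancy is counted
at cycle starts and multiplied by Δ, i.e. a left-endpoint rule; its bias
is ≈ Δ/2 per unit of line-entry mass (verified against the exponential
closed form under Δ → Δ/2 → Δ/4 refinement in the test suite).

After progression on the final line the default is **terminal death**:
all final-line event mass moves directly to dead.  A
**partitioned-survival** mode is available for the final line, where each
entrant sub-cohort's alive fraction follows an OS curve and
post-progression occupancy is S<sub>OS</sub> − S<sub>PFS</sub>.
Independently fitted curves can cross in extrapolation; the model clamps
post-progression at 0 by treating max(S<sub>OS</sub>, S<sub>PFS</sub>) as
the alive curve (mass balance is preserved exactly) and logs a warning,
or raises under `strict_partition`.  Terminal death is the default
because it makes overall survival exactly additive over per-line
progression-free times, which is the decomposition the shipped reference
targets obey.

Mass conservation (occupancy + post-progression + dead = 1) is asserted
every cycle at 1e−9 inside the engine itself.

## Survival curves

Five families, parameterized as: exponential (rate λ), Weibull (shape,
scale), log-normal (meanlog, sdlog), log-logistic (shape, scale),
Gompertz (shape > 0, rate).  This is the standard extrapolation set for
health-technology assessment.  Two deliberate exclusions: the generalized
gamma (three parameters are too weakly identified on summary points) and
spline/cure models.  The Gompertz negative-shape variant (which plateaus
at a cure fraction) is rejected at construction; within this model's
lifetime horizon a plateauing PFS curve is not clinically plausible for
relapsed myeloma.

Hazard ratios are applied under proportional hazards:
S<sub>target</sub>(t) = S<sub>ref</sub>(t)<sup>HR</sup>.  Exponential,
Weibull and Gompertz are closed under this operation and return exact
family members; log-normal and log-logistic return a power-wrapper
survival function.  Time-varying HRs are out of scope.

**Fitting** to Kaplan–Meier summary points minimizes weighted least
squares on the complementary log-log scale, log(−log S), with weights =
numbers at risk when provided (else 1).  The cloglog scale linearizes the
exponential and Weibull families (their minimizers are closed-form, used
as starting values), stabilizes the tails, and works on published summary
points without reconstructing pseudo individual-patient data.  Points
with S = 1 or S at the numerical floor carry no cloglog information and
are dropped; a fit needs at least (number of parameters + 1) usable
points.  Non-linear families are refined with Levenberg–Marquardt from
transform-scale regressions, positive parameters optimized in log-space.
Families are ranked by n·log(RSS/n) + 2k (an AIC-like penalized score);
ties break by the fixed order exponential → Weibull → log-normal →
log-logistic → Gompertz, and callers may override the winner on clinical
plausibility grounds.

Numerical guards: survival is clipped to [0, 1]; probabilities below the
floor 1e−12 are treated as 0 in ratios (a sub-cohort whose curve has
underflowed experiences the event with probability 1); restricted means
use the composite trapezoid rule.

## Calibration (synthetic curve libraries)

The trial-derived curves behind the published sequencing exercise are not
public; only the per-line expected progression-free times per sequence
are.  The fixtures module therefore calibrates one exponential curve per
line so the engine reproduces those times exactly.  Exponential is the
right family here: the targets constrain exactly one moment per line, so
one parameter per line makes the fixed point well-posed.  The entry
probability into line k is e<sub>k</sub> = Π<sub>j&lt;k</sub>
a<sub>j</sub>, giving conditional mean c<sub>k</sub> =
target<sub>k</sub>/e<sub>k</sub> and starting rate 1/c<sub>k</sub>; a
multiplicative fixed-point update (rate ← rate·achieved/target, at most
20 iterations, tolerance 1e−3 years) absorbs the discrete-cycle and
horizon-truncation bias.  It converges in 3–4 iterations for all shipped
rows.

The attrition fraction between lines defaults to 0.7, in the range of
published real-world drop-out (≈ 19–28% per line is *lost*, i.e. dies
without further treatment, at the first and third transitions).  The
actual per-line values behind the reference exercise are unpublished, so
the default is a single representative value — and in terminal-death mode
the reproduced OS is provably insensitive to it, because the targets are
unconditional and OS is their sum for any feasible attrition (asserted at
0.5/0.7/0.9 in the tests).

What the synthetic generator does *not* emulate: real line-specific curve
shapes (anything calibrated here is exponential, hence memoryless within
a line), correlation between a patient's successive line durations,
time-varying or sequence-dependent attrition, and post-progression
survival after the fourth line.  Passing reproduction tests therefore
shows the engine arithmetic and calibration are correct, not that the
underlying clinical inputs are.

The pseudo-KM generator samples event times by inverse transform, censors
each subject independently with the requested probability at a uniform
time before its event, and computes the product-limit estimate
(`lifelines`).  All stochastic fixtures take explicit integer seeds
(default 20221101).

## Outcomes, rounding, projection

Per-line expected progression-free years are unconditional sums of
occupancy × Δ; per-entrant (conditional) times and entry fractions are
exposed separately.  Table cells round half-up to 2 decimals, aggregates
to 1 decimal, matching the precision of the published tables.  The
non-weighted mean OS is taken over the non-optimal sequences only.

The population projection is stepwise with half-up integer rounding at
each named stage — cases → TIE patients → fourth-line patients →
life-years — reproducing how such national projections are printed; the
single-step unrounded product is also reported.  The fourth-line share
default is 0.175.  Note one internal inconsistency of the published
projection that users should be aware of: the comparator life-years
figure there (570 = 93 × 6.13) corresponds to the *worst* common
sequence's OS, not to the stated non-weighted mean OS of 6.925 (which
gives 644); the package computes both scenarios and takes no side.

## Known limitations

- Cohort expectations only: no patient-level heterogeneity, subgroups, or
  probabilistic sensitivity analysis.
- PFS proxies time-to-next-treatment; treatment-duration caps, adverse
  events and discontinuation are not modelled.
- Attrition is constant within a line and independent of the upstream
  sequence.
- OS is truncated after fourth-line progression in terminal-death mode
  (a small underestimate; survival after a fourth-line relapse without
  further treatment is typically short).
- Proportional hazards is assumed exact when transporting reference
  curves to other regimens.
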