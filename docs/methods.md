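# Methods

This note documents the models implemented in `sitefidelity`, the
assumptions behind them, the synthetic study system used to exercise
them, and the numerical choices made where the original field workflow
delegated details to software defaults.

## Telemetry screening and analysis units

Fixes are kept inside half-open seasonal windows `[start 00:00,
end 00:00)` per calendar year (UTC throughout), which removes
double-counting at boundaries. The step filter computes Euclidean step
lengths per animal-season, takes the linear-interpolation percentile
(default 95) as a threshold, and removes in a single pass every fix
that *terminates* a step strictly longer than the threshold; the first
fix is never removed and steps are not recomputed after removals, so
the operation is order-independent of later binning. The percentile is
per animal-season rather than global so that one animal's movement
cannot set another's screening threshold. Duplicate timestamps keep
the first record with a warning.

Monthly (30-day) and biweekly (14-day) windows are anchored at the
season start (not the calendar month); a trailing partial window is
kept only when it spans at least half the nominal length, mirroring
the monitoring-inclusion rule. An animal-interval enters the analysis
when at least 50% of the interval's days contain a fix — a joint proxy
for survival and collar function.

## Dynamic Brownian bridge home ranges

The Brownian bridge between consecutive fixes conditions the animal's
position on both endpoints: at fractional time α the position is
Gaussian on the chord with variance
`T·α(1−α)·σ²ₘ + (1−α)²δₐ² + α²δᵦ²`, where σ²ₘ (m²/s) is the Brownian
motion variance and δ (m) the telemetry error sd (default 20 m). The
*dynamic* extension re-estimates σ²ₘ along the track: a window of 7
fixes slides one fix at a time; within each window a single-σ²ₘ model
competes by BIC against breakpoint models whose pieces each retain at
least the margin (3 fixes); σ²ₘ in each piece maximizes the
leave-one-out likelihood in which each interior odd-indexed fix is
scored under the bridge implied by its neighbours (the left-out fix's
own δ² adds to the bridge variance). A segment's final σ²ₘ is the mean
over all windows covering it. With window 7 and margin 3 at most one
breakpoint fits in a window, so only single-break models are
enumerated. σ²ₘ is optimized on a log scale by bounded scalar search
in [10⁻⁶, 10⁴] m²/s with tolerance 1e−8; tracks shorter than one
window fall back to a single global σ²ₘ with a warning.

The utilization distribution is the time-weighted average of bridge
densities, evaluated by midpoint quadrature at 10 interior times per
segment (each point weighted by segment duration / 10) on a 50-m grid
whose extent pads the fix bounding box by three maximal bridge
standard deviations. Gaussians are truncated at 5σ for speed; a grid
that fails to cover the 3σ envelope is auto-expanded with a warning.
Segments spanning more than 6× the nominal (median) fix interval
contribute density only at their endpoint fixes, so telemetry outages
do not fabricate corridors. The home range is the smallest set of
cells, by descending density, whose cumulative mass reaches the
isopleth level (default 0.99); at level 1.0 all nonzero cells are
kept. Area is cell count × cell area. A two-fix UD agrees with a
dense-time-quadrature bridge integral to <1% total variation (at 30
integration points), and halving the cell size changes the 99%
isopleth area by <5% on test tracks, which is the accuracy relevant
here given that downstream constancy is computed on the coarser 250-m
foodscape grid.

## Colwell constancy and home-range quality

Suitable-biomass rasters are min–max scaled to [0, 1] using the global
minimum and maximum across all layers, dates and sites in a run, so
quality and predictability are comparable across study areas; the
scaling constants are recorded and invertible. Constancy of a value
set is `C = 1 − H/ln(n)` with `H = −Σ Pᵢ ln Pᵢ` over n = 100 evenly
spaced bins spanning [0, 1] exactly (half-open bins, last closed at
1.0, so every value maps to exactly one bin). The sign convention
follows the standard entropy definition so that C ∈ [0, 1] with C = 1
for a perfectly constant series; the result is invariant to the
logarithm base. Temporal constancy is computed per pixel over the
interval's days and averaged across home-range pixels; spatial
constancy per day over home-range pixels and averaged across days;
mean scaled biomass over pixels × days is the quality metric.
Home-range membership of a foodscape pixel is decided by cell-center
containment in the isopleth mask (nearest-neighbour resampling from
the finer UD grid). Degenerate cases — single-day intervals,
single-pixel ranges, a globally constant foodscape — return C = 1 (or
scaled value 1.0) with warnings rather than errors.

## Distance-based site fidelity

Fidelity is measured inversely as the mean minimum Euclidean distance
from each focal-interval fix to the previous interval's fixes. At the
annual scale the comparison set is restricted to prior-year fixes
within a symmetric ±W day-of-year window (sidedness is a design
choice; Feb-29 off-by-one is tolerated for summer-only data). Focal
fixes with an empty comparison set are skipped, and the matched
fraction is reported so poorly covered records can be filtered. At
monthly and biweekly scales consecutive intervals are compared without
a day window. The window-size sensitivity analysis evaluates W = 5…100
days in steps of 5 and reports the mean and between-individual CV of
inter-annual distance per W; the selected W is the smallest whose next
two grid steps change both mean and CV by less than 2% relative — an
explicit, reproducible stand-in for visual asymptote identification
(plots are still emitted for human override, and W is always
configurable). The model response is ln(distance in meters); when
exact zero distances occur (possible on identical synthetic tracks)
ln(distance + 1 m) is used and flagged.

## Recruitment labels

Annual success means a neonate born in year t−1 survived to 120 days;
at-heel status means the neonate was alive ≥15 of the previous 30-day
window or ≥7 of the previous 14-day window. Alive-days are calendar
days where `[birth, end)` overlaps the window. Censoring that leaves a
rule undecidable (e.g., collar failure at day 80 for the 120-day rule,
or mid-window censoring when the remaining days could still have
reached the threshold) yields status *unknown*, and the female-interval
is excluded from models with a logged reason.

## Inference

Fidelity models are Gaussian linear mixed models of ln(distance) with
a single random intercept — animal at the annual scale, animal-year
(one concatenated grouping factor, not nested components) at finer
scales — fitted by maximum likelihood, not REML, because REML
likelihoods are not comparable across fixed-effect structures in AICc.
Continuous covariates are standardized within scale × site and the
statistics stored for back-transformation; home-range size (km²)
enters every model. Candidate sets follow the three hypotheses:
resource heterogeneity (predictability; quality; predictability +
quality; predictability × quality), previous success (recruit only),
and their combination (six sub-models). Sub-models containing a
covariate pair with |r| > 0.6 are split into variants each holding one
member of the pair; constant covariates are removed. AICc is
`−2ℓ + 2k + 2k(k+1)/(n−k−1)` with n the number of rows (a documented
choice; group count is a defensible alternative) and k the fixed
effects plus two variance parameters. The 95% confidence set is the
smallest top-weight set with cumulative Akaike weight ≥ 0.95.
Coefficients are averaged *naturally* — over confidence-set models
containing the term with renormalized weights — with the unconditional
SE `√Σwⱼ(sⱼ² + (βⱼ − β̄)²)`; zero-substitution (shrinkage) averaging
is deliberately not the default. A term is significant when the
averaged 95% CI excludes zero. Interaction sub-models are generated
but excluded from the averaging set by default, so inference rests on
the additive set.

Condition models regress autumn IFBFat (and spring→autumn fat accrual,
with spring fat as the state variable) on standardized log fidelity
distance and recruitment, with a random intercept for animal; the
fidelity × recruit interaction is dropped when fewer than three
females recruited. Neonate survival over [0, 120] days from birth uses
the Andersen–Gill Cox form `h(xᵢ) = h₀(t)·exp(xᵢβ)` on maternal
fidelity with a mother-level cluster-robust sandwich variance and
Breslow tie handling (heavy ties are unlikely with continuous summer
mortality times); fewer than five mortalities raises an error that
points to the two-sided Mann–Whitney comparison instead. The
Mann–Whitney path reports U and p (U is nonnegative by definition).

## The synthetic study system

The generators emulate the *structure* of the field data, with every
parameter a dial whose truth is recorded:

- **Movement**: an Ornstein–Uhlenbeck walk attracted to a yearly
  activity center (exact discretization, stationary start), attraction
  0.1 h⁻¹ and diffusion 5×10⁴ m²/h by default (stationary sd 500 m, a
  few-km² summer range), hourly fixes over Jun 1–Sep 1, i.i.d.
  Gaussian location error (sd 20 m, matching the dBBMM δ).
  Consecutive-year centers displace by `ou_center_shift_m` (default
  300 m, the scale of observed mean inter-annual distances
  0.29–0.94 km) in a uniformly random direction — the ground-truth
  fidelity dial. An optional thinning fraction emulates failed fixes.
- **Foodscape**: daily rasters on a 250-m grid; spatial structure from
  a stationary Gaussian random field with exponential covariance
  (range 1 km) generated by Cholesky factorization (seed-stable);
  per-pixel AR(1) persistence (0.9) with innovation sd 0.1 sharing the
  spatial field; a half-sine seasonal mean (amplitude 0.3 over base
  1.0); values floored at 0. Raw biomass stays on an arbitrary
  positive scale — the pipeline's global 0–1 scaling is part of the
  analysis, not the generator.
- **Reproduction**: at most one neonate per mother-year, birth uniform
  in May 15–Jun 15 (configurable), exponential mortality hazard
  `0.005/day × exp(β_fid · z)` (≈55% survival to 120 days, within the
  observed 11–78% range) where z is the mother's standardized log
  inter-annual centroid displacement; survivors past 120 days are
  censored there.
- **Condition**: spring IFBFat ~ N(8, 2)%; autumn = 13% − 3 ×
  recruited + β_fid·z + 0.3 × spring + N(0, 1.5) — recruit cost of the
  order reported for lactating ewes.

What the generator does **not** emulate: real foodscapes' estimation
error and remote-sensing structure, terrain- or migration-driven
movement, predation and disease processes, fix-success gaps beyond
random thinning, and multi-site contrast (a single site is generated
per run). Passing tests therefore demonstrate the correctness and
calibration of the *pipeline* under known structure, not ecological
conclusions about real populations.

## Problem sizes and determinism

All randomness flows from a single seed through independent named
substreams, so a fixed configuration reproduces every output byte for
byte; the test suite checks this end to end on a reduced configuration
(two animals over two 45-day seasons, annual + monthly scales) chosen
so the whole chain runs in minutes on one CPU.
Parameter-recovery checks use 300-row analysis tables (20 replicates),
150-neonate survival sets (20 replicates), 500-fix Brownian tracks (5
replicates), and 10-replicate monotonicity sweeps of the foodscape
dials — sizes at which the relevant estimators are well inside their
asymptotic regimes while keeping the suite fast.

## Known limitations

- The dBBMM enumerates at most one breakpoint per window; with larger
  windows and small margins the original construction allows more.
- The UD grid resolution and contour algorithm of the original
  software are unknown; agreement is established against closed-form
  bridges and refinement studies rather than bit-level comparison.
- Calendar day-of-year matching ignores leap-year offsets (irrelevant
  for summer seasons).
- AICc uses row count for n; with strong within-animal correlation an
  effective sample size would be smaller.
- The asymptote rule for W is a heuristic; it reproduces the intent of
  visual selection, not any particular analyst's choice.
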