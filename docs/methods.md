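# Methods

## The problem

During labor, repeated compressions of the umbilical cord cause fetal
heart-rate (FHR) decelerations and, if sustained, progressive metabolic
acidemia. A fetus compensates for a while — mounting hypertensive arterial
blood-pressure (ABP) responses to each occlusion — until cardiovascular
decompensation (CVD): the conversion to hypotensive responses that heralds
inadequate cerebral perfusion. Clinically available FHR is a 4 Hz series;
blood chemistry (pH, lactate, base excess) is only available intermittently
and, in human labor, essentially only after delivery. The package
implements an FHR-only monitoring pipeline: four scale-dependent
variability features computed in sliding windows, their aggregation into a
self-referenced "distance to the healthy state", and a sentinel rule on
that distance that flags incipient decompensation; plus a synthetic
umbilical-cord-occlusion (UCO) cohort generator so the entire chain is
testable without animal data.

## Sliding-window features

Windows have length `T = 20 min` (4,800 samples at 4 Hz) and shift
`dT = 5 min` (75% overlap); window `k` spans `[k*dT, k*dT + T)` (half-open;
sample `n` sits at `start_time + n/fs`) and its value is stamped at the
center `t_k = k*dT + T/2`. Within a window, each integer sample lag `tau`
(default grid 2–128 samples, i.e. 0.5–32 s) defines `floor(N_w/tau)`
non-overlapping intervals anchored at the window start; per interval
`(t - tau, t]`:

* increment mean `m_t(tau) = (1/c) * sum_i (x_i - x_{t-tau})` — the local
  trend over the lag, in bpm; requires a valid anchor and at least
  `max(2, ceil(f_min * tau))` valid samples (`f_min = 0.5`);
* standard deviation `sigma_t(tau)` — population (divisor `n`) standard
  deviation of the interval samples, in bpm; at least 2 valid samples;
* Student ratio `R_t(tau) = m_t/sigma_t` — the trend in local-noise units;
  intervals with `sigma_t = 0` are excluded, not zeroed, to avoid biasing
  the window average toward 0.

The window value of each is the mean over valid intervals, invalid when
fewer than `max(1, floor(f_min * floor(N_w/tau)))` remain. Missing samples
only ever reduce the counts that enter these averages; no value is ever
interpolated into a gap. When `tau` divides `N_w` the last interval's
final evaluation point coincides with the (excluded) window end; that
single sample is treated as absent, which the missing-data semantics
handle uniformly.

### Entropy rate

The fourth feature is the order-1 entropy rate
`h_k(tau) = H(x_t, x_{t-tau}) - H(x_t)` in nats: the extra information in a
sample given one lagged sample; it falls as the signal becomes more
predictable at that lag. The window is first normalized to zero mean and
unit variance over its valid samples (making `h` amplitude-free), then both
Shannon entropies are estimated on all valid pairs with the
Kozachenko–Leonenko nearest-neighbor estimator: `k = 5` neighbors,
maximum norm, natural logarithm. Temporally adjacent points are excluded
as neighbor candidates (Theiler prescription) within `±tau` samples, and
the estimator uses per-point candidate counts `psi(M_i + 1)` so the
exclusion does not bias the normalization. Implementation detail: the
k-d-tree query asks for `k + 8` neighbors and re-queries the rare points
whose admissible count falls short (worst case `k + 2*theiler + 2`); this
is exact, not approximate. Duplicate points would give zero neighbor
distances; the estimate is flagged invalid if that floor fires for more
than 1% of points. Windows need `min_entropy_pairs = 500` valid pairs and
nonzero variance.

Measured accuracy (the test suite recomputes these): on i.i.d. Gaussian
input of 2,400 samples the mean bias over 20 replicates is below 1% of the
closed form `0.5*ln(2*pi*e)`; on lag-correlated Gaussian input
(`rho = 0, 0.5, 0.9`, N = 4,800) the closed form
`0.5*ln(2*pi*e*(1-rho^2))` is recovered within 2%. Because the realized
lag correlation of a finite strongly-correlated sample varies
substantially between realizations, the `rho = 0.9` check averages 100
seeded replicates so that the test's own sampling error (~1%) does not
dominate the comparison.

## Distance to the healthy state and the sentinel

Per window, each feature is summed over the long-term (LT) scale band
2.5–8 s inclusive — lags 10–32 samples at 4 Hz, 23 lags — as a plain
discrete sum (no trapezoid weighting). Shorter scales carry little
metabolite-related information at 4 Hz and scales above 8 s lose
statistical power as `floor(T/tau)` shrinks. The LT vector is valid only
if every contributing lag is valid for every feature.

The four LT sums are normalized by per-component standard deviations
computed over all animals and windows of a cohort (population divisor), or
by supplied constants; the published cohort constants
`(0.0155, 0.0282, 0.1630, 0.4127)` are available as
`NormalizationConstants.table_defaults()` for use with comparable data.
The state vector `u_k` is referenced to the subject's own first *valid*
window (`u_0`), and `D_k = ||u_k - u_0||_2`. Using the first valid rather
than literally the first window tolerates missing data at recording start;
the monitoring assumption remains that recording starts while the fetus is
healthy. The sentinel fires at the first run of 3 consecutive valid
windows with `D > 2.5`; its time `t_D` is the center of the run's first
window, consistent with the window timestamp convention (the source data
do not pin which point of the run defines the alert). A window with
invalid `D` breaks a run — conservative alerting. `D = 2` serves as a
softer alert level: baseline `D` fluctuates with a standard deviation
near 1 by construction of the normalization.

## Metabolites

Blood-sample analytes are interpolated piecewise-linearly between draws,
never extrapolated beyond the sampled span; `t_pH` is the earliest time
the interpolant reaches pH 7.00 from above (exact sample hits return the
sample time; a series already at or below the level returns its first
sample time). The earliest crossing is the clinically conservative choice
when noise makes the interpolant dip repeatedly.

## Pressure-based decompensation timing

Per occlusion, `delta_ABP = ABP_max(occlusion) - <ABP>(preceding
inter-occlusion segment)`. A hypotensive response is `delta_ABP <= 0`
(failure to rise above the preceding baseline; the threshold is
configurable — the original adjudication was expert-visual with a
comparative reference, so any fixed threshold is an operationalization).
`t_CVD` is the start of the first occlusion of the earliest run of 3
consecutive hypotensive responses. `<ABP>` uses the single immediately
preceding inter-occlusion segment (for the first occlusion, the segment
from recording start), keeping the reference local in time.

## Cohort analyses

Pooled correlations are plain Pearson coefficients over all valid
(animal, window) pairs, the analyte interpolated at each window's center.
The headline structure this reproduces on synthetic cohorts: `m`, `R`, `h`
correlate positively with pH, `sigma` negatively, and the distance `D`
(negatively) correlates more strongly than any single feature — the
aggregation both cancels single-feature noise and removes inter-animal
offsets through self-referencing.

## The synthetic cohort generator

The generator emulates the timed-occlusion labor model: 1–2 h healthy
baseline, then mild / moderate / severe occlusion series (one 1-min
occlusion every 2.5 min), severe terminated by pH < 7.00, then recovery.
Ground truth (`t_CVD`, `t_pH`) is injected, so recovery of these times by
the analysis is a meaningful test. Everything is driven by one seed;
cohorts jitter physiology per animal from a master seed. Defaults were
frozen after pilot simulations against the qualitative anchors stated for
the real cohort (features barely move before the severe series; baseline
`D` fluctuates with sd ≈ 1; `D` reaches ~2 around pH 7.2; the sentinel and
the pressure-based `t_CVD` agree within one window length; entropy falls
while `sigma` rises as acidemia deepens); they are choices of this module,
not measured animal values.

Components, per recording:

* **pH trajectory**: piecewise linear through regime knots, 7.35 at start
  to a nadir of 6.88 at the end of severe (crossing 7.20 about 15 min into
  severe and 7.00 about 60 min later), recovering only to 6.92 within the
  short simulated recovery — blood pH recovers over hours, and a faster
  rebound would also make the late heart-rate features move against the
  still-low pH. Lactate and base excess are affine in the pH fall with
  small measurement noise. Blood samples every 20 min.
* **Acidemia severity** `s(t)`: 0 above pH 7.25, 1 below pH 7.15. The
  threshold shape reflects decompensation as a reserve-exhaustion
  phenomenon concentrated around the pH 7.2 crossing, where `t_CVD` is
  anchored (offset and jitter configurable).
* **Decelerations**: trapezoids with half-cosine ramps (~30 s descent)
  subtracted from the baseline; depth goals ~30 bpm (mild) and ~60 bpm
  (moderate), scaled per animal by a cardiovascular-reactivity factor, and
  down to a floor of 45 bpm in severe (near-complete occlusion). While the
  fetus compensates (`s = 0`) the responses are variable: depth, onset,
  duration, ramp time and the within-deceleration depth profile are
  jittered, about a third of occlusions evoke only a partial response, and
  a small deceleration-proportional variability surge rides on them. As
  `s -> 1` all of this fades and the decelerations become stereotyped deep
  plunges with steeper ramps — the documented loss of adaptive response
  variability near decompensation. Occlusion onsets are exact multiples of
  the 2.5-min period (regime durations jitter in whole periods),
  phase-locked to the 5-min window shift as in the timed protocol.
* **Background variability**: AR(1) noise, marginal sd 8 bpm at baseline,
  modulated by a slow behavioral-state cycle (period ~37 min, ±55%,
  suppressed to a third of that amplitude while occlusions run) and a
  ±1.5 bpm baseline wander. With severity the marginal sd grows (gain
  +0.9, the variability increase seen with rising occlusion strength) and
  the lag-1 coefficient rises 0.88 → 0.96, lowering the entropy rate at
  the long-term lags.
* **Bradycardia**: the baseline declines in proportion to the pH fall
  below 7.28, by 35 bpm at the nadir — progressive terminal bradycardia.
* **Signal loss at deep decelerations**: the missing-data probability
  ramps up steeply once a deceleration exceeds ~85 bpm of depth and the
  loss zone extends ~15 s past the bottom (the transducer re-locks
  slowly). This concentrates missing data in the severe regime, as in the
  real cohort, and — because descents into the loss zone keep their
  interval anchors while ascents out of it lose theirs — it biases the
  surviving increments negative, giving the increment mean and Student
  ratio their dominant systematic decline during severe occlusions.
  Per-regime Bernoulli dropout (defaults 3 / 2 / 4 / 15 / 3 % for
  baseline / mild / moderate / severe / recovery) models ordinary artifact
  loss on top.
* **Floor**: a softplus saturation toward 25 bpm plus 0.05 bpm acquisition
  jitter. A hard clip would create exactly-duplicated samples, which no
  real tachogram has and which degenerate nearest-neighbor distances.
* **ABP**: baseline 40 mmHg with AR(1) noise; hypertensive occlusion bumps
  (up to +12 mmHg, scaled by regime) before the injected `t_CVD`, and a
  persistent hypotensive pattern (−8 mmHg during occlusions) from `t_CVD`
  on.
* **Cohort structure**: per-animal jitters (baseline level, reactivity
  0.75–1.25, noise correlation ±0.04, state-cycle timing, regime durations
  in whole occlusion periods, decompensation offset) derive from one
  master seed; the deceleration depth goals and the variability scale
  share the reactivity factor, so the depth-to-variability ratio — which
  shapes the window features — is a cohort property rather than a
  per-animal accident. The deliberate between-animal heterogeneity
  disperses the raw pooled feature values; the self-referenced distance is
  immune to it, which is precisely why `D` out-correlates every single
  feature on cohort data. Chronically hypoxic animals carry a
  lowered-variability baseline period (factor 0.85).

What the generator does **not** emulate: beat-to-beat (ECG-resolution)
dynamics, accelerations and movement artifacts, uterine-pressure coupling,
baroreflex dynamics linking ABP and FHR sample-by-sample, and any
metabolite dynamics beyond piecewise-linear trends. Tests passing on this
cohort demonstrate that the pipeline recovers injected structure under the
stated noise, dropout and protocol conditions — not clinical performance
on real tachograms.

## Problem sizes and runtime

The nearest-neighbor entropy estimation dominates runtime (two k-d-tree
estimates per window and lag over ~4,700 points). The distance pipeline
therefore defaults to the LT lag band only (23 lags; `AnalysisConfig.
lt_only()`), which is all the distance metric consumes — about 20 s per
5.3 h recording. The full 2–128 sample lag grid remains available for
scale-resolved feature maps. Cohort-level tests and the acceptance script
use 14 recordings of ~5.3 h, the size of the original animal cohort.

## Numerical choices and degenerate inputs

Population (divisor `n`) variance throughout, matching the printed
definitions of the statistics. Lags are integer sample counts; band edges
in seconds are converted by rounding with a 1e-9 tolerance and the LT band
is closed on both ends. Constant windows give `m = sigma = 0` and invalid
`R` and `h`. All-gap windows are invalid everywhere. The entropy
duplicate-distance floor (1e-300) exists only to keep logarithms finite;
estimates are discarded when it fires for more than 1% of points.
`resample_rr` converts R-R intervals (ms) to bpm as `60000/RR` and
linearly interpolates on the uniform grid only across inter-beat gaps of
at most `max_gap` (default 2 s); longer gaps stay invalid. Splines are
deliberately not offered: interpolation across real signal loss fabricates
fast transients that can drive a false sentinel, and every statistic here
tolerates gaps natively.

## Known limitations

The sentinel's timing granularity is the window shift (5 min) and its
detection delay grows with the run-length requirement; the self-reference
assumes a healthy start; the cohort normalization assumes a cohort of
comparable recordings (or externally supplied constants); pooled Pearson
correlations treat overlapping windows as independent pairs, which
overstates effective sample size — they are descriptive here, not
inferential.

Two fragilities of the sentinel deserve emphasis, because the cohort tests
exhibit them. First, the reference `u_0` is a single window: an unlucky
draw (its per-window scatter is a sizable fraction of the cohort
normalization in the trend and Student-ratio components) shifts the whole
trajectory and can hold `D` above threshold long before decompensation.
Second, because consecutive windows overlap by 75%, per-window fluctuation
persists across 3–4 windows, so the 3-consecutive-windows rule filters
isolated spikes but not correlated excursions; in a 14-recording synthetic
cohort one or two animals typically cross the threshold one occlusion
regime early, and the median sentinel-to-decompensation gap (~15–25 min,
about the window length) is a fairer summary of its behavior than the
cohort maximum. Averaging a few early windows for the reference, or
de-overlapping the run rule, would mitigate both — at the cost of changing
the method's definition.
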