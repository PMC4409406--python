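# Methods

This note documents the models, conventions and numerical choices behind
aquatrack, and what the synthetic calibration does and does not show about
real arena recordings.

## The observation model

A single marked animal moves in a square arena (default 100 × 100 cm)
recorded at one frame per second. Each frame shows one bright marker blob
over a noisy background; the tracking stage reduces a frame to at most one
centroid. Everything downstream operates on the resulting 1-Hz coordinate
series in centimetres, origin at the arena's bottom-left corner, y up.

Three filtering rules define the unit of analysis (the *path segment*):

1. **Margin rule.** Points within 10 cm of a wall (distance ≤ margin) are
   discarded: wall-following ("fence") behaviour would bias step and turn
   statistics. A margin excursion splits the track.
2. **Gap rule.** A frame without a detection splits the track. Gaps are
   never bridged: interpolating across unobserved seconds would fabricate
   steps with arbitrary lengths and angles.
3. **Minimum-length rule.** Only segments with ≥ 5 locations enter *any*
   metric. The fractal regression needs that many points to be meaningful,
   and applying the same cut everywhere keeps all metrics on one data basis.

Segments of fewer than 2 points are retained by the segmentation (so that
retained-point bookkeeping is exactly conservative) but can never reach a
metric, which all require 2–3 points minimum and, through the rule above,
effectively 5.

## Resting versus relocation

The positional noise of a stationary marker (water movement, camera
vibration, sensor noise) makes tiny apparent steps; a resting animal also
breathes and shifts its legs. The package follows the standard two-part
calibration: the stationary noise floor is measured by tracking a marker
known not to move (`estimate_noise_floor`, which recommends twice the
largest per-axis frame-to-frame error, floored at 1 mm), and steps below
the resulting threshold (default 0.1 cm) count as **resting**, steps at or
above it as **relocation**. A step exactly at the threshold counts as
relocation, making the two classes exhaustive.

Consequences worth remembering:

* the measured resting fraction is an *upper* bound on true bout-level
  rest: a genuinely moving animal that happens to advance less than 1 mm
  in a second is counted as resting. With exponential step lengths of
  mean 1/λ, that misclassification adds about
  (1 − π_rest)(1 − e^(−λ·0.1)) to the resting fraction — visible in the
  worked example in the README;
* turning angles are computed only between relocation steps adjacent in
  time. A resting interval breaks the chain, because heading during rest
  is unobservable at 1 Hz. The synthetic walker mirrors this: its heading
  persists unchanged through rest bouts.

## Divider-method fractal dimension

Tortuosity is summarised scale-independently by the divider (ruler)
method: walking the polyline with a ruler of length δ gives a measured
length L(δ), and for a fractal path L(δ) = k·δ^(1−D). D is estimated as
1 minus the OLS slope of log L on log δ over 200 log-spaced ruler sizes
(default 0.25–25 cm, i.e. half an isopod body length up to a quarter of
the observation scale).

Numerical choices, each of which matters on coarse 1-Hz paths:

* **Exact chord landing.** Each ruler step ends at the exact interpolated
  point on the polyline at straight-line distance δ from the current
  anchor (first crossing; distance to a fixed point is convex along a
  straight segment, so the crossing segment is found by scanning for the
  first vertex at distance ≥ δ, after skipping all vertices whose *arc*
  distance is below δ, which chord distance cannot exceed). Snapping to
  vertices instead would bias L upward at large δ.
* **Remainder closure.** The tail after the last full step contributes the
  straight distance from the last anchor to the final point. This makes
  L(δ) exactly equal to the true length on a straight path for every δ,
  pinning the D = 1 limit.
* **Traversal averaging.** L is averaged over forward and backward
  traversals before the regression; D per individual is the unweighted
  mean over that individual's eligible segments. This two-direction
  average is this package's concrete reading of a "fractal mean"
  estimator; published implementations may average more traversal
  offsets.
* **Undefined rulers are dropped.** A δ for which no full step fits in
  either direction is excluded from the regression; at least 10 defined
  sizes are required.
* Estimates below D = 0.95 are flagged `suspect` (degenerate path or
  ruler range).

Calibration anchors (all in the test suite and the acceptance script): a
straight line measures D = 1.000 exactly; a level-5 triadic Koch polyline
measures within 0.06 of log 4/log 3 ≈ 1.2619 over rulers inside its
self-similar range; dense planar Brownian motion (10⁵ steps of per-axis
sd 0.1 cm, rulers 1–30 cm, i.e. well above the step scale and below the
path extent) averages D ≈ 1.94 over ten seeds, within the stochastic
scatter of the D = 2 limit. L(δ) is monotone non-increasing between
rulers an octave or more apart (with one ruler length of remainder
slack); adjacent log-spaced rulers alias against the vertex spacing and
may wiggle by several δ, which is why the regression uses many sizes.

## Circular statistics

Turning angles are treated on the circle throughout: 180° and −180° are
the same direction. The summary reports the circular mean (atan2 of mean
sines/cosines), mean resultant length R̄, circular SD √(−2 ln R̄), and κ
from the standard piecewise rational inversion of the Bessel ratio
A(κ) = R̄. The arithmetic SD of the wrapped angles is exported alongside,
labelled, because printed summary tables in this field are ambiguous
about which SD they show.

Treatments are compared with the **Watson–Wheeler** rank test: pooled
angles are ranked around the circle, mapped to uniform scores
β = 2π·rank/N, and W = 2 Σᵢ (Cᵢ² + Sᵢ²)/nᵢ is referred to χ² with
2(k−1) df. Exact ties are broken by deterministic jitter below 10⁻⁶
degrees (far below measurement resolution) because circular ranks require
distinct values. The test's empirical size at α = 0.05 is within
[0.035, 0.065] under a two-group uniform null (2000 replicates, n = 100
per group). Angles are pooled across replicates within a treatment before
testing; the pseudo-replication this entails is a property of the
experimental design and is documented rather than corrected.

Circular boxplot statistics use the data-point circular median (minimum
mean arc deviation, computed in O(n log n) via prefix sums over the
period-extended sorted sample), quartiles of signed arc deviations from
the median, and fences at 1.5 × circular IQR.

## The statistical comparison scheme

Location tests use the *individual* as the unit of replication — each
animal contributes one value per metric (its segments pooled or averaged):

| metric | 2 groups | > 2 groups |
|---|---|---|
| resting time | Welch's t | one-way ANOVA |
| fractal D (log(D−1)) | Welch's t | one-way ANOVA |
| step length | Wilcoxon rank-sum | Kruskal–Wallis |
| turning angle | Watson–Wheeler on pooled angles | same |

log(D−1) maps the [1, 2] dimension scale to the real line before
t/ANOVA; values at or below 1 (possible from estimator noise on very
straight paths) are clipped to 1 + 10⁻⁶ with a logged flag. ANOVA is the
classical one-way form. No multiple-testing correction is applied; each
metric is reported on its own, which matches how such tables are usually
printed and is flagged here as a caveat.

Calibration: on a null scenario (identical walkers in both groups,
n = 20 per group) both the Welch test on resting time and the rank-sum
test on step length reject in 3–7 % of 500 seeded replicates at
α = 0.05; a resting-occupancy effect of 0.3 vs 0.6 is detected (p < 0.05)
in ≥ 90 % of replicates.

## The synthetic walker

`generate_crw` simulates the two-state correlated random walk the
analysis assumes:

| parameter | meaning | default | rationale |
|---|---|---|---|
| `n_steps` | 1-s intervals | 3600 | one hour of recording at 1 Hz |
| `p_move_to_rest`, `p_rest_to_move` | per-second bout transitions | 0.1, 0.2 | stationary resting occupancy 1/3, resting percentages in the 30–40 % range typical of crawling isopods |
| `step_model` | moving step lengths | exponential, rate 1.4 /cm | mean moving step ≈ 0.7 cm, the scale observed for crawlers; a Pareto power law (μ, x_min) provides the heavy-tailed contrast |
| `turn_kappa` | von Mises turn concentration | 5 | strongly forward-biased but visibly tortuous paths |
| `jitter_sd_cm` | positional observation noise | 0.02 | keeps the stationary noise floor below the 0.05 cm detection granularity |
| boundary | specular reflection | — | implemented as the per-axis mirror fold of the unbounded walk, which is exactly specular reflection with mirrored turn signs after each bounce; turn distributions are symmetric, so the folded path is statistically identical |

Bout states are drawn as alternating geometric sojourns (exact for a
first-order chain and fully vectorised). Heading persists through rest;
observed positions are true positions plus Gaussian jitter, so during
rest the measured displacement is jitter only.

`generate_density_experiment` builds labelled cohorts (≥ 2 treatment
levels, ≥ 3 individuals each, per-individual seeds spawned from one seed
sequence); `rest_occupancy_params` solves the move→rest rate for a target
stationary occupancy. `generate_brownian` and `generate_reference_path`
(straight line, triadic Koch polyline up to level 6) provide the analytic
fractal anchors. `render_frames` rasterises a trajectory into 8-bit
frames with a Gaussian blob, i.i.d. Gaussian background noise, and
per-frame occlusion (emulating a fluorescent marker turning away from
the camera); the detector recovers noiseless centroids to well under
0.05 cm RMS at 5 px/cm.

### What the generator does not emulate

Real recordings have correlated background drift (lamp flicker, water
surface ripples), marker shape changes with animal orientation,
body-size-scale displacement during grooming, multi-second behavioural
modes beyond a first-order move/rest chain, and step-turn coupling
(speed-dependent turning). Passing calibration against this generator
therefore demonstrates that the *analysis chain* is correct and unbiased
under its stated assumptions — not that those assumptions exhaust real
animal behaviour. In particular the first-order Markov bout structure is
a modelling choice: the true autocorrelation structure of bout durations
in these species is not established, so only geometric sojourns are
offered.

## Problem sizes used in validation

Validation runs are sized for a desk machine: parameter recovery uses
10⁴-step walks; the Brownian fractal limit uses ten 10⁵-step walks; the
Watson–Wheeler size check uses 2000 replicates of 100 + 100 angles; the
null-calibration and power checks use 600-s recordings with 20
individuals per group (500 and 30 replicates respectively). Recording
length affects only the precision of per-individual metrics, not the
size of the tests, so the shorter-than-an-hour recordings leave the
calibration conclusions unchanged.

## Known limitations

* The divider estimator's small negative bias on Brownian paths
  (≈ 1.94 rather than 2) comes from the finite ruler range interacting
  with the remainder closure; it is well inside the between-seed scatter.
* `fit_step_distribution` compares exactly two one-parameter candidates
  (shifted exponential vs Pareto) above a common cutoff by ΔAIC > 2;
  it is a classification aid, not a full model-selection analysis
  (no truncated power laws, no mixtures).
* The tracking stage handles one marker; simultaneous tracking of
  several marked animals (identity maintenance under crossings) is out
  of scope, as is decoding video containers — frames come as image
  files.
* Welch/ANOVA on per-individual resting fractions treats those fractions
  as approximately normal; with very short recordings or occupancies
  near 0 or 1 a transform would be advisable.
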