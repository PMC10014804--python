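# Methods

## Generative model

Each simulated unit is an inhomogeneous Poisson process whose rate is
piecewise-constant within trial phases:

- **Prepare** (duration U(1.0, 1.5) s) and **Rest** (1.5 s): the unit's
  baseline rate `b`.
- **Go** (2.0 s), unimanual task with target direction θ:
  `r = max(0, b + m_arm · cos(θ − PD_arm))`, where `m_arm` is the cosine
  half-amplitude and `PD_arm` the preferred direction of the arm used.
- **Go**, bimanual task with targets (θ_i, θ_c):
  `r = max(0, b + g_c · m_c^bi · cos(θ_c − PD_c^bi) + g_i · m_i^bi · cos(θ_i − PD_i^bi))`.

Cosine tuning is the standard description of M1 center-out directional
modulation and is the simplest form that yields graded modulation-depth and
preferred-direction structure on a discrete target grid. The additive
two-arm combination with per-arm gains `g_i, g_c ∈ [0, 1]` is a modeling
choice: what is empirically established is *suppression* of each arm's
modulation during bimanual movement (stronger ipsilaterally) and PD
changes, not a combination rule; an additive rule with multiplicative gains
is the minimal model expressing both. Negative instantaneous rates are
clipped to zero before sampling. No refractory period is modeled — the
downstream statistics operate on trial-mean rates, which a dead time of a
few ms would not meaningfully change.

### Population ground-truth distributions (defaults)

| parameter | default | rationale |
|---|---|---|
| baseline `b` | U(4, 16) Hz | typical sorted-unit rates well above the 1 Hz selection threshold |
| shared amplitude | U(2, 8) Hz | modulation depths of a few Hz, comparable to baseline |
| per-arm jitter | amplitude × U(0.7, 1.3) | the two arms' response magnitudes are positively correlated across units, as observed in bilateral M1 recordings |
| contralateral PD | U[0°, 360°) | uniform directional coverage |
| ipsilateral unimanual PD | contra PD + N(0, 30°) | bilaterally congruent unimanual tuning (high unimanual cc) |
| bimanual gains | g_i = 0.4, g_c = 0.8 | asymmetric suppression, ipsilateral side stronger |
| bimanual PD rotation | ±90° on half the units, sign independent per arm | on the 4-direction grid an equal-sign rotation of both arms is a common circular shift that leaves the between-arm correlation unchanged; independent signs are required for rotation to decorrelate the arms |
| inter-trial interval | 0.5 s | paradigm plumbing; configurable |

A session holds one block per requested task; block order and within-block
trial order are seeded permutations; unimanual blocks contain 8 directions
× 8 repetitions and bimanual blocks 16 configurations × 8 repetitions
(256 trials for the default three-task session). A fixed seed makes the
session bit-identical.

### What the simulator does and does not emulate

It emulates the statistical structure the analyses consume: tuned Poisson
units, task blocks, phase timing, asymmetric bimanual suppression and PD
rotation. It does **not** emulate electrode/sorting artifacts, firing-rate
nonstationarity across a session, noise correlations between units,
movement-onset latency within the Go phase, or non-cosine tuning shapes.
Passing recovery tests therefore demonstrates correctness of the analysis
chain under the stated model, not robustness to those real-data features.

## Preprocessing

- 20 ms half-open bins `[t, t+Δ)` aligned to each trial's Prepare onset; a
  trailing partial bin is dropped; spikes exactly on a boundary belong to
  the later bin.
- Gaussian smoothing with SD = 300 ms ("300 ms kernel" is read as the SD;
  the parameter accepts any value, so a reading as full width is expressible
  as `kernel_sd_ms≈75`). The kernel is truncated at ±3 SD and
  edge-renormalized (normalized convolution): a constant rate is preserved
  exactly at trial edges, avoiding boundary droop, at the cost of slightly
  amplifying spike mass whose kernel tail crosses the trial boundary
  (≤ 1e-4 of a spike in the tests). `kernel_sd_ms = 0` disables smoothing
  and is used by the noiseless analytic oracle.
- Bins are assigned to phases by their start time; with jittered Prepare
  durations one 20 ms bin can straddle the Go onset and is counted as
  Prepare. At 20 ms against a 2 s Go window the bias is negligible; the
  oracle tests use bin-aligned phase durations where the assignment is
  exact.
- The baseline is pooled over all Prepare bins of all blocks of the day
  (one baseline per unit); SD uses ddof = 1. Per-trial Go means use the
  full cued 2 s window (no latency exclusion — the cue-to-modulation
  latency is not modeled, and a sub-window is configurable).
- Unit selection (> 1 Hz grand mean over all bins) and task-relatedness
  (modulation ratio > 1) use strict inequalities.

## Tuning statistics

- PD is the literal grid argmax. Exact ties (measure-zero under Poisson
  noise, but possible on noiseless input) break toward the smallest angle
  and are flagged; flagged units are excluded from PD-shift
  classifications. A least-squares cosine fit (`cosine_fit_pd`) is provided
  for off-grid comparisons.
- Bimanual per-arm tuning curves marginalize over the other arm's 4
  directions (the mean of 4 responses per point), using all 16
  configurations symmetrically; conditioning on a fixed other-arm direction
  is the obvious alternative but discards 3/4 of the data per curve.
- The preference index uses each arm's maximum |response| within the task
  (the marginal-curve maxima for the bimanual task). Index exactly 0 counts
  as ipsilateral-preferring in quadrant counts, biasing *against* the
  contralateral-shift conclusion; both-zero maxima give a NaN sentinel and
  the unit is excluded (logged).
- Bilateral correlation is the Pearson r between the two arms' curve
  vectors; constant curves give a NaN sentinel (excluded, logged), not an
  imputed value. "Strong" correlation uses strict `cc > 0.75`.
- "Significant PD shift" defaults to any nonzero circular change on the
  grid (threshold 0°, configurable) — on a 45°/90° grid the smallest real
  shift is one grid step, so any change is resolvable.

## Decoding

- Features: per-trial baseline-subtracted Go-phase mean rate per unit.
- Classifier: `LinearSVC` (squared hinge, L2, primal), one-vs-rest so every
  class has a decision value for Top-N ranking; C = 1 default. The primal
  objective is strictly convex, so converged solutions are unique and LOOCV
  predictions do not depend on trial ordering.
- Features are z-scored per unit with statistics fit on the training folds
  only (flag `standardize`, on by default), making accuracy invariant to
  per-unit affine rescaling.
- Top-N ties break by fixed class order and set a flag; with continuous
  features ties are measure-zero.
- Classes with a single trial raise an error (a LOOCV fold would otherwise
  train without that class).

## Statistics

- "Comparison to the null distribution" is a one-sample t-test against 0
  (a paired t-test against a zero vector is algebraically identical; both
  entry points exist). Zero-variance samples raise rather than returning
  p = NaN.
- No multiple-testing correction by default (per-test α = 0.05), with a
  Holm step-down helper for sensitivity analyses.
- The response scatter fit is OLS of contralateral on ipsilateral per-unit
  maxima with intercept; R² from residual variance; 95% CI on the slope
  from the t distribution with n − 2 df.
- Every mean in the report is accompanied by median and SD.

## Verification scales

Test problem sizes were chosen as the smallest that make each property
statistically decisive: the directional parameter-recovery check uses 20
cohorts of 100 units × 8 repetitions (the planted gain asymmetry yields
paired-t effect sizes far beyond α = 0.05 at n ≈ 70 analyzed units);
decoder chance calibration uses one 64-trial block against the exact
binomial interval; the type-I calibration uses 500 cohorts of 24 units × 4
repetitions of the two unimanual blocks — the null property (index mean 0
under arm-symmetric generation) is scale-free, and 500 cohorts bound the
rejection-rate estimate to ±2.5% at 99% confidence.

## Known limitations

- The argmax PD is grid-quantized; PD-shift distributions are therefore
  multiples of the grid step, unlike fitted-PD analyses.
- Smoothing before baseline estimation correlates adjacent bins, so the
  baseline SD underestimates the raw-bin SD; the modulation-ratio threshold
  of 1 is defined on the smoothed scale.
- LOOCV with shuffled labels is slightly pessimistic (the held-out trial's
  class is under-represented in training); the chance-calibration test
  absorbs this within the exact binomial interval.
- The pipeline analyzes one session at a time; multi-day aggregation is
  left to the caller (tables are concatenable).
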