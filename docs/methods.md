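# Methods

`slantchoice` implements the statistical machinery used to relate single-neuron
spiking in macaque areas CIP and V3A to perception of 3D surface slant: tuning
quantification during fixation, psychometric/neurometric threshold estimation
during a two-alternative slant discrimination task, choice probability with a
permutation null, a partial-correlation decomposition of stimulus vs choice
signals, and sliding-window time courses of all of these. Because the original
recordings are not publicly available, the package ships a synthetic-session
generator that reproduces the statistical structure the analyses assume; every
quantitative claim a green test makes is therefore a claim about recovery of
known generative structure, not about the biology.

## Task and data model

A *fixation session* presents a slanted checkerboard plane at 25 slant–tilt
combinations (slant 0°–60° in 20° steps, tilt 0°–315° in 45° steps; slant 0
collapses all tilts into one frontoparallel condition, hence 25 = 3×8 + 1),
each at least 3 times, with spike counts taken over the 1000-ms stimulus
window (half-open, [0, 1000) ms).

A *discrimination session* presents random-dot planes slanted about the
90°/270° tilt axis. Signed slant uses the convention tilt 90° (top-near) ⇒
negative, tilt 270° (top-far) ⇒ positive. The slant ladder is per-animal
(presets: ±20, ±10, ±5, ±2.5, ±1.25, 0 and ±20, ±9, ±4.05, ±1.83, ±0.82, 0),
each slant shown ≥10 times; plane depth is drawn 70/15/15 from
{0, −2.25, +2.25} cm to defeat local-disparity strategies. The animal reports
slant sign with a saccade (top_far/top_near); correct signs are rewarded, the
ambiguous 0° slant randomly at 50%. All neural analyses use screen-depth
(0 cm) trials only, matching the available statistical power in the original
design.

## Core statistics

**SODI** (surface orientation discrimination index):
`SODI = (R_max − R_min) / (R_max − R_min + 2·√(SSE/(N − M)))`, where R_max and
R_min are the extreme condition means, SSE the pooled within-condition sum of
squared errors, N the trial count and M the number of tested conditions
(M = 25 for the full protocol; `compute_sodi` defaults M to the number of
observed conditions and accepts the protocol value explicitly). SODI is 1 for
perfectly repeatable, modulated responses and 0 for flat tuning.

**Tuned/untuned classification** is a two-step gate: one-way ANOVA over the 25
conditions (p < 0.05), then a Bingham-function fit whose Pearson r with the
condition means must be ≥ 0.8. The second step removes multi-peaked profiles
that pass an ANOVA without being selective for a unique orientation. The
Bingham form used is `R(n) = A·exp(λ₁(v₁·n)² + λ₂(v₂·n)²) + B` on the unit
surface-normal sphere (`n = (sin s cos t, sin s sin t, cos s)`), with
λ₁ ≤ λ₂ ≤ 0 and orthonormal axes v₁, v₂, fit by multi-start trust-region least
squares initialised at the 8 largest observed conditions. With non-positive
concentrations the fitted peak lies exactly at the third axis v₃ = v₁×v₂
(taken on the z ≥ 0 hemisphere), so the preferred slant/tilt is computed in
closed form rather than by grid search — the two agree to grid resolution by
construction. Failed or degenerate fits carry an `r = −inf` sentinel and the
neuron classifies untuned.

Preference maps use the Lambert azimuthal equal-area projection about the
frontoparallel pole, ρ = 2 sin(s/2); population uniformity is tested by χ²
goodness-of-fit over equal-area bins (8 tilt sectors × slant rings with
equal-area edges, ring count chosen so each bin expects ≥ 5 counts).

**Psychometric/neurometric fits.** The proportion of top-far choices vs signed
slant is fit with `P(s) = γ + (1−γ−λ)·Φ((s−μ)/σ)` by binomial maximum
likelihood (L-BFGS-B, multi-start, σ parameterised on the log scale). The
P.S.E. is μ and the threshold is σ; lapse rates are fitted but bounded at 0.1
(standard practice; unbounded lapses destabilise σ — whether the original fits
constrained them is not stated, so this is a package decision). Data with no
modulation yield a `σ = inf` sentinel and a non-converged flag.

The neurometric function uses the ROC area between each non-zero slant's count
distribution and the 0° distribution (rank-sum formulation, ties ½ — equal to
the trapezoid sweep; the equivalence is asserted to 1e−12 in tests). Each ROC
value is oriented as "probability the ideal observer reports positive slant"
using the neuron's fixation-task preference sign (flipped for
negative-preferring neurons), then fit with the same cumulative Gaussian using
per-slant trial counts as weights. Before comparison with behaviour the
neuronal σ is doubled (one-interval behavioural task vs two-distribution ROC
construction); `comparison_threshold = 2σ` holds exactly by construction, and
ratios < 1 are flagged.

**Choice probability.** CP is the ROC area between counts on preferred- vs
nonpreferred-sign choices; the preference sign always comes from the fixation
task (sign reversals against the discrimination data are logged, never acted
on). The grand CP pools across all slants with ≥ 3 choices in each direction
after a balanced per-slant z-score: center = mean of the two
choice-conditional means; scale² = ½·(mean squared deviation from that center
within each choice group). With balanced choice counts this reduces exactly to
the ordinary (ddof = 0) z-score; with imbalance each choice contributes
equally, so imbalance cannot shift the pooled distributions. The exact
constants of the cited normalization are not reprinted in the source study;
these are the package's documented choice. Significance uses a two-sided
permutation test (default 1000 permutations) shuffling choice labels within
each slant (not within slant×depth — only screen-depth trials enter anyway)
with add-one smoothing, `p = (1 + #exceed)/(1 + n_perm)`; the permutation path
is vectorised (balanced re-normalization and rank-sum AUC computed for all
permutations at once).

**Partial correlations.** With F = spike count, S = signed slant, C = choice
(±1; any two-level monotone coding is equivalent and tested so):

    r_FS.C = (r_FS − r_FC·r_SC) / √((1−r_FC²)(1−r_SC²))
    r_FC.S = (r_FC − r_FS·r_SC) / √((1−r_FS²)(1−r_SC²))

Significance uses the t transform on n−3 degrees of freedom (the original
transform is unstated; this is the textbook choice). The 0/0 limit (e.g. F
identically equal to S) is defined as 0. Slant enters linearly by default;
nonlinear recodings are available as a sensitivity hook since the source study
reports invariance to them. Squared partials estimate variance fractions.
Neurons are placed in quadrants by the sign pair (r_FS.C, r_FC.S); populations
split by grand CP ≷ 0.5 get 95% bivariate-normal coverage ellipses
(χ²₂-quantile scaling of the covariance eigendecomposition — the original
ellipse estimator is unstated), with a percentile-bootstrap CI on the
major-axis angle, unwrapped to within ±90° of the point estimate because axis
orientation is axial data.

**Time courses** use 200-ms windows stepped 50 ms with centers 100→1150 ms
(22 windows; reading "starting at 100 ms" as the first *center* is the only
convention consistent with 22 bins, so the first window is [0, 200)). The last
window ends at 1250 ms, just before the median choice time (1271 ms after
onset = 1000-ms stimulus + 271 ms). Windows are not clipped at stimulus
offset. Each metric (grand CP, doubled neurometric threshold, squared
partials) is recomputed per neuron on window-restricted counts; across-bin
inference is a one-way ANOVA with Tukey multiple comparisons against the first
bin, the earliest rejected comparison defining the first significant bin. The
SDF is the per-bin mean rate averaged over trials, then neurons.

**Eye controls.** Per neuron, an ANCOVA (OLS: count ~ choice factor +
covariate) tests dependence on trial-mean vertical eye position, vertical eye
velocity, or vergence, with Bonferroni–Holm correction across neurons within a
covariate family. Detrending subtracts the *marginal* linear regression on the
covariate, so corrected responses have exactly zero linear trend and the
operation is idempotent; CP and neurometric threshold are recomputed on the
corrected (non-integer) responses and compared before/after with paired tests.
Sessions lacking a covariate are skipped with a warning. Slant is available as
an optional ANCOVA factor but is off by default (the original model is
unstated).

## Synthetic sessions

The generator states a world matching the protocol above: Bingham tuning with
baseline 5–15 Hz, amplitude 20–50 Hz and concentrations in (−8, −0.5) sampled
uniformly (chosen to give realistic cortical rates and mostly-tuned neurons);
Poisson counts by default, or rounded/clipped Gaussian counts with a
configurable Fano factor (the count-noise family of the recorded neurons is
uncharacterised, so both are selectable); an observer with sensory σ_b
defaulting to 3.6° (a measured behavioural threshold), bias 0, lapse 0.01.

Choice coupling is a single shared standard-normal component η between the
observer's decision variable, `d = (s − bias)/σ_b + ρη + √(1−ρ²)ν`, and the
neuron's standardized count fluctuation (weight ρ, signed by the neuron's
preference so that coupling is congruent with tuning). Counts are produced by
a Gaussian copula (inverse-CDF of the configured marginal), so the count
distribution is exactly the stated noise model at every ρ, and at ρ = 0 counts
are exactly conditionally independent of choice given the stimulus — the
stated world behind the null-calibration checks. This mechanism is
deliberately agnostic about bottom-up vs top-down origin of choice-related
activity.

When spike times are requested, trials are tiled with 50-ms Poisson
subwindows; after a configurable coupling onset the subwindow rate is
multiplied by `max(0, 1 + g·ρ·sign_pref·η)` (gain g defaults to 0.3 per SD of
shared noise). This time-resolved route is statistically close to, but not
identical with, the copula count route; it exists to give time courses a
controllable coupling latency. The generator is silent after stimulus offset,
so windows fully past 1000 ms are undefined for CP/threshold (NaN) and zero
for the SDF — a stated limitation: real neurons keep firing into the choice
epoch, which is precisely where the original data show late CP growth.

Eye covariates are trial means: unit-normal noise plus an optional additive
choice shift and an optional linear injection into counts (recorded as ground
truth; spike times are dropped when counts are modified, preserving the
count/times invariant).

What green tests do not establish: anything about real CIP/V3A physiology —
population CP levels, threshold medians, tuned fractions, ellipse angles and
the CP-vs-threshold correlation of the source study all depend on the
unavailable recordings and are covered only as direction/shape properties of
constructed populations.

## Numerical choices

- ROC ties count ½ (rank-sum); AUC(a,b) + AUC(b,a) = 1 exactly.
- Permutation p is two-sided with add-one smoothing; never 0, floor 1/(n+1).
- Degenerate permutations (zero balanced variance at a slant) count as
  non-exceeding; slants with zero pooled SD are excluded from the grand CP
  with a warning.
- Cumulative-Gaussian fits run 5 starts over (μ, log σ) with σ bounded in
  [1e−3, 100·span]; unmodulated data short-circuit to the `inf` sentinel.
- Bingham fits use 8 starts; axis order is swapped post hoc to keep λ₁ ≤ λ₂.
- Sessions are plain TSV trial tables plus a JSON sidecar; spike times are
  semicolon-joined `repr` values so round trips are bit-exact; results embed
  the seed and config.
- Child seeds derive as `(seed·1_000_003 + i) mod (2³¹ − 1)`.
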