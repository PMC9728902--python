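# Methods

This note documents the models, conventions, and numerical choices behind
`songseg`, and what the synthetic data generator does and does not emulate.

## Segmentation data model

A segmentation is an ordered list of labeled intervals over one recording.
Intervals are half-open, `[onset, offset)`: abutting syllables are distinct,
never overlapping, which makes frame rasterization unambiguous. All times in
the data model are seconds; the XML interchange format quantizes to samples
(nearest integer, so the symmetric error is at most half a sample at the
48 kHz standard rate, and round trips agree to within one sample). Raven
selection tables are matched on the exact default column names
`Begin Time (s)` / `End Time (s)`; extra columns are ignored, and floats are
parsed round-trip-exactly so write∘read is the identity.

Manual annotation boxes are not expected to overlap, so overlap is an error
by default; `validate_track(..., policy="merge")` opts into fusing
same-label overlapping or abutting segments (union interval, union
frequency box), which preserves total annotated time.

## Audio standardization and spectrograms

Recordings are converted to mono by channel averaging and resampled to
48 kHz with polyphase band-limited resampling (`scipy.signal.resample_poly`);
the contract is tone-frequency preservation, not bit-exactness. Spectrograms
use a 512-sample Hann window stepped by 32 samples with no padding, so the
frame count is exactly `floor((n − 512)/32) + 1` and frame *i* covers
samples `[32i, 32i + 512)`, stamped at the window center. Power is
log-transformed and floored at a log-domain threshold (default 6.25) to
suppress background noise, restricted to 500–15,000 Hz, and z-scored per
spectrogram. Z-scoring is skipped for constant matrices (sd = 0, e.g.
digital silence) to avoid dividing by zero.

Note the threshold lives on the scale of integer-PCM-amplitude audio; for
unit-scaled float audio either rescale the waveform or disable the floor
(`min_power_log=None`).

## Slicing

Segmenters trained on whole files dominated by silence learn to predict
silence, so recordings are cut into slices that are roughly half annotated.
Syllables separated by less than 1.0 s of silence form a cluster; a gap of
*exactly* 1.0 s splits ("at least one second" of silence is a split point).
Clusters are atomic — a slice always contains its whole cluster and is never
shorter than the cluster's extent — so intra-cluster silence counts against
the annotated fraction and sparse clusters can fall below the 50 % target;
conversely, when no padding silence is available the fraction exceeds the
target. Padding is split symmetrically before/after the cluster, clipped at
file boundaries and at the midpoint of the gap to each neighboring cluster
(slices stay disjoint), with unused allowance reassigned to the other side.
Symmetry is the least-informative choice; nothing downstream depends on it.

Species balancing for multi-species training greedily accumulates slices in
a seeded random order until each species first reaches the smallest
species' total seconds, so every total is within one slice-duration of the
floor.

## Evaluation metrics

Evaluation is frame-based at one spectrogram step (32/48000 s ≈ 0.67 ms).
A frame is positive iff its midpoint lies inside a segment; the midpoint
rule is deterministic and unbiased, whereas a ≥50 %-overlap rule has tie
ambiguity. Each segment boundary can mislabel at most one frame, so any
confusion-count fraction differs from the exact interval-overlap value by
at most `(#boundaries) · frame_dur / T`; the test suite asserts this bound
against an independent interval-algebra oracle on randomized tracks.

Accuracy is standard frame accuracy `(TP+TN)/N`; the F-score is the
unweighted harmonic mean of precision and recall (F1). Ratios with zero
denominators (e.g. precision with no positive predictions) are NaN and are
excluded from aggregation rather than coerced. The 0.02 s minimum-duration
filter applies to predicted tracks only — it models the post-hoc removal of
spuriously short predictions, with the boundary kept (exactly 0.02 s
survives). Per-species summaries report both a pooled estimate recomputed
from summed counts (equivalently, the duration-weighted mean) and a
mean ± sample sd (n−1) across recordings, because the two answer different
questions (overall rate vs. per-recording variability).

## Song diversity

Syllable shape vectors emulate an aligned-surface featurization: the
log-power patch of each syllable is bilinearly resampled onto a fixed
25 (time) × 20 (frequency) grid — 500 features — with time normalized per
syllable (duration is removed from shape) and amplitude min-max scaled to
[0, 1] (constant patches map to the zero vector rather than erroring).
Exact reproduction of semilandmark-based pipelines is out of scope; the
grid featurization preserves the analysis downstream of it.

PCA is covariance-based on centered, unscaled features (they share units).
The retained dimension k is the smallest number of leading components whose
cumulative explained-variance ratio reaches the 0.5 threshold. The
pseudo-hypervolume is the product over those k components of a species'
per-component sample sd; it scales as c^k under uniform scaling by c,
exactly like a volume, and is exactly rank-concordant with convex-hull
volume for clusters differing only in scale (asserted against
`hull_volume_oracle`, itself `scipy.spatial.ConvexHull`, for 2–7
dimensions). Resampling draws 50 syllables per species per repetition —
without replacement when available, with replacement otherwise (the choice
is not prescribed anywhere authoritative; without-replacement avoids
artificial sd shrinkage) — over 50 repetitions, max-normalizing within each
repetition. Sampling operates on rows sorted by syllable id so input order
cannot change seeded results.

## Comparative analysis

Divergence tables are symmetric, non-negative, zero-diagonal matrices in
Mya; conspecific comparisons are 0.0. A multi-species model's divergence to
a test species is the weights-proportional mean of its members' pairwise
divergences (equal weights under the balanced design). All regressions are
univariate OLS; training seconds and sample sizes vary over orders of
magnitude and are natural-log transformed (base changes slopes, not
inference, and is not a reported surface). Adjusted R² uses
`1 − (1−R²)(n−1)/(n−2)`; slope p-values are two-sided t with n−2 df; a
constant response returns slope 0 with non-positive adjusted R² rather than
NaN. Undefined metric values are dropped pairwise per regression, never
imputed. The Bonferroni family size m is the number of models actually
fitted, except that a complete 11 × 11 grid uses the conventional m = 121
layout. ANOVA reports the full between/within decomposition; Tukey HSD
uses the studentized-range distribution (`scipy.stats.tukey_hsd`).

## Synthetic data generator

The generator defines the study conditions for every end-to-end test.

**Phylogeny.** A random coalescent-style ultrametric tree: n−1 node ages
drawn uniformly on (0.02·depth, depth] with the root pinned at the maximum
depth (default 85 Mya), so pairwise divergences span (0, 85] like the 1–85
Myr range of real multi-order bird panels. Trait vectors (4 axes) diffuse
from the root with variance `trait_rate` (default 0.02 per Mya) per branch,
giving Var(Δtrait) = 2·rate·d for species at divergence d.

**Species specs.** Traits map deterministically to song parameters:
syllable rate is log-sigmoid-squashed into the observed 0.32–9.13 /s range
(geometric-mean center ≈ 1.7 /s, near the observed mean rate of ~1.9);
duration is a log-normal (σ_log = 0.45) truncated to 0.02–1.99 s whose mean
is tied to rate through a duty cycle in [0.25, 0.45], so fast singers have
short syllables and every rate is packable; the frequency band and the
three-chirp repertoire drift with the remaining axes inside 500–15,000 Hz.

**Songs.** Syllables are placed by a renewal process — truncated-log-normal
durations, exponential extra gaps with a one-frame minimum — with the gap
mean chosen so the mean inter-onset interval is exactly 1/rate. Waveforms
(when rendered) are Hann-windowed linear chirps plus white noise at a
configurable SNR (default 15 dB), peak-normalized. Annotations match
emitted syllables exactly. The experiment-grid and learning-curve drivers
skip waveform rendering entirely: frame/segment evaluation consumes only
annotations, so synthesizing audio there would add cost without changing
any number.

**Degradation model.** Each true syllable is deleted with probability
`clip(a_m + b_m·d)/gain(s)`; survivors get centered Gaussian boundary
jitter (sd `0.002 + 5·10⁻⁵·d` s, clamped to preserve order and one-frame
minimum duration) and are split around a 0.01 s interior gap with
probability `0.02 + 0.001·d`; false positives arrive in true silence as a
Poisson process (`0.05 + 0.002·d` per s), half of them shorter than 0.02 s
so the duration filter is exercised on every run. Defaults
(a_m = 0.02, b_m = 0.004) give a ~2 % miss rate on conspecifics and ~36 %
at 85 Myr before training gain — a decline of the same order as the
cross-order accuracy losses seen with real segmenters, though the affine
form is a modeling convenience, not an empirical law. The training gain
`1 + s/(s + 100)` saturates with training seconds s, mirroring
learning-curve plateaus. The closed-form expectation

    E[SER] = (1 − p_miss_eff)(1 + p_split) − 1 + λ_fp·T_silence/n_true

is verified against Monte-Carlo over 1,000 corruption seeds. For
multi-species models the corruption uses the *minimum* divergence from any
trained species to the test species — a deliberate generator choice that
reproduces the qualitative finding that multi-species models outperform
their mean divergence — while reported divergence columns use the
equal-weight mean, as a balanced training set is summarized.

**Randomness.** Every driver takes one integer seed; internal streams are
split with `numpy.random.SeedSequence`. The corruption model draws its
per-segment uniforms and jitters up front from four dedicated child
streams, so corruptions at different training sizes under one seed are
coupled: more training only ever un-deletes syllables. This makes
learning-curve monotonicity hold per replicate by construction instead of
only in expectation.

**What passing tests do not show.** The generator produces stationary
chirp syllables with white noise; real recordings have nonstationary
backgrounds, overlapping heterospecific song, amplitude modulation, and
annotator inconsistency, none of which are modeled. The degradation model's
error modes are independent across syllables, unlike a real network's
correlated failures. Results on synthetic grids therefore validate the
*measurement machinery* (metrics, statistics, experiment plumbing), not any
claim about how well a particular segmenter generalizes.

## Problem sizes

Default experiment sizes were chosen so the whole suite runs comfortably on
one CPU: grids use 5–6 species, 20–30 s test recordings, and 2–3 recordings
per cell; the Monte-Carlo SER check uses one 60 s track and 1,000 seeds;
null calibration refits 20 independent 36-cell grids. At these sizes every
stochastic assertion has comfortable margin (3 SEs or a ≥ 90 % coverage
floor) without being tuned to any particular seed.

## Known limitations

- The Raven reader targets Raven's default export dialect only; project
  files and renamed columns are unsupported.
- `extract_shape_matrix` skips syllables whose patch is smaller than 2 × 2
  (shorter than two frames or narrower than two frequency bins) rather than
  erroring, so extremely short syllables silently drop out of the diversity
  analysis.
- The pseudo-hypervolume is not rotation-invariant within a species (it is
  computed along pooled PCA axes); that is inherent to the statistic, not a
  defect of the implementation.
- `performance_analysis` fits only univariate models by design; confounding
  between divergence and diversity must be reasoned about outside the tool.
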