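# Methods

This note documents the models, parameter choices and known limitations
behind `saccerp`. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The analysis problem

Free-viewing EEG has no stimulus onsets. Trials are defined by gaze events:
each fixation, together with its temporal context, is one trial, and the
same trial can be time-locked either to the fixation onset or to the onset
of the saccade that brought the eye there. The two alignments contain the
same samples shifted by the trial's saccade duration (the time-shift
duality asserted in the tests). If an early component such as the P100 is
generated at saccade initiation, fixation alignment jitters its apparent
latency by the saccade-duration distribution; saccade alignment does not.
The package's statistics quantify that asymmetry and carry the category
comparison (pedestrian head vs body vs background) through overlap
correction and mass-univariate inference.

## Synthetic session generator (`simulate`)

The generator produces the statistical structure the analysis assumes, with
ground truth for every event, so that each stage can be validated without
recorded data.

**Scanpath.** Fixations and saccades strictly alternate. Each upcoming
fixation draws a stimulus category (defaults 0.816 / 0.152 / 0.031 for
background / body / head, following the observed trial-count ratio
3968 : 741 : 151), and the saccade leading into it draws a duration and
amplitude from per-category log-normal laws. Default medians: durations
76 / 66 / 56 ms and amplitudes 12.119° / 7.212° / 5.35° for
background / body / head; fixation durations 186 / 200 / 178 ms. The two
log-normal draws share a latent Gaussian factor (ρ = 0.8), inducing the
main-sequence correlation between amplitude and duration. Within each
saccade the gaze direction follows a raised-cosine speed profile along the
great circle between the old and new gaze points; fixations hold a world
point fixed and add isotropic tangent-plane jitter (SD 0.05° per sample at
90 Hz).

*Spread parameters.* Published spread values of the kind "0.076 ± 0.003 s"
are across-subject MADs of per-subject medians; they describe cohort
heterogeneity, not trial-to-trial spread. Within-session MADs therefore
have their own defaults chosen as realistic trial-level spreads (saccade
durations 12 / 10 / 8 ms, amplitudes 4 / 2.5 / 1.8°, fixation durations
60 ms), parameterized exactly as MADs of the log-normal laws (the log-sigma
is solved numerically from median and MAD). Between-subject heterogeneity
is a separate dial in `generate_cohort` (default SD 0.2): per-subject
kernel-amplitude factors, category-mix perturbations, and log-normal
jitter of the event medians, all drawn once per subject from seeds derived
from the master seed via `numpy.random.SeedSequence`.

**Head motion.** Observer translation is a sum of three sinusoids per axis
with frequencies in 0.02–0.3 Hz, random phases, and amplitudes scaled so
the summed RMS translational speed equals `head_motion_amp` (default
1 m/s — the scale of slow virtual locomotion; vertical bob is reduced
5-fold). Because the recorded gaze direction points from the moving head to
the fixated world point, this motion adds exactly the compensatory rotation
the detection module must remove. The per-sample head→gaze-point distance
(median 5.209 m, MAD 2.591 m, log-normal) is carried in the trace; the
correction needs it to reconstruct gaze points.

**EEG.** Forward model: `y(t) = Σ_events k_category(t − saccade_onset) +
noise`. All categories share a P100-like positive Gaussian lobe (6 μV peak,
latency 115 ms, width 20 ms) weighted by a posterior channel gain peaked at
PO7/PO8; the head category adds a −3 μV deflection (175 ms, width 35 ms,
support within 0.10–0.25 s) and the body category a −0.5 μV version of the
same shape. Kernels live on [−0.1, 0.5] s; with median inter-saccade
intervals near 260 ms, neighboring responses overlap by construction.
Background noise is 1/f^α (α = 1) with 8 μV RMS per channel, independent
across channels, generated by spectral shaping of white Gaussian noise.
The synthetic montage is a 32-channel 10-20 subset with 2-D layout
coordinates; channel adjacency for cluster statistics is the Delaunay
triangulation of that layout.

**Clock drift.** Gaze timestamps are re-stamped as `t' = offset + rate·t`;
the default rate deviation accumulates 11 ms over a 30-min session.

**What the generator does not emulate.** No blinks, pupil dynamics, ocular
EMG or other preprocessing-stage artifacts (inputs are "preprocessed" by
construction); no smooth pursuit distinct from fixation; no nonlinear or
piecewise clock drift; fixational jitter is white rather than
drift/tremor/microsaccade structured; head rotation is not simulated (the
yaw channel exists but defaults to zero). Passing tests therefore certify
the computational chain and its statistical behavior under the stated
model, not robustness to every artifact of recorded data.

## Gaze-event classification (`gaze`)

Angular velocity is the central-difference great-circle angle between the
directions at samples i−1 and i+1 over their time span, computed with
`atan2(|u×v|, u·v)` (exact zero for identical directions). No pre-smoothing
is applied by default: a 3-sample moving average (available via `smooth=3`)
delays/advances apparent onsets by up to ~1.5 samples at 90 Hz, which is
most of the error budget when onsets must be recovered to ±1 sample.

Thresholds are data-driven per 10-s interval: `median(ω) + λ·robust-SD(ω)`
with λ = 5. The robust scale is `1.4826·MAD(ω)`. A median-of-squares scale
(`sqrt(median(ω²) − median(ω)²)`) is *not* usable here: for a nonnegative
speed series squaring is monotone, so the median of squares equals the
squared median and the estimator collapses to ~0; that form belongs to
signed velocity components. Intervals of only NaNs inherit the previous
threshold; the trailing partial interval merges into its predecessor.

Classification takes maximal supra-threshold runs ≥ 22 ms as saccades,
complements ≥ 50 ms as fixations; sub-minimum runs are absorbed (short
supra runs demoted; short fixations between two saccades merged). Event
boundaries are then placed at the sub-sample threshold crossing by linear
interpolation on the velocity trace, which removes the ±1-sample
quantization of the run boundaries. Tracker dropouts (NaN runs or sampling
holes > 100 ms) become explicit gap events and are never bridged.

Translational-motion correction reconstructs the gaze point
`q = head + dist·direction` and re-expresses it from a fixed vantage (the
median head position): a stable gaze point then maps to a constant
direction regardless of head translation. The fixed vantage distorts
amplitudes when the head wanders far from its median (bounded here by the
oscillatory motion model); for locomotion over large distances a windowed
reference would be needed — a known limitation.

Simulation studies in the tests use a 30-min session: noiseless (no head
motion) detection recovers ≥ 99% of ≥ 1° saccades with onset error ≤ 1 gaze
sample; with 1 m/s head motion the uncorrected hit rate drops to ~0.65 and
correction restores ≥ 95% of the noiseless rate.

## Stream alignment (`alignment`)

Drift is estimated from the two endpoint pairs alone — rate =
Δt_EEG/Δt_eye, offset anchored at the first timestamps — exactly mirroring
how such drifts are corrected in practice; corrected endpoints coincide
with the EEG endpoints by construction and `residual_check` records the
worst anchor deviation. A multi-anchor least-squares variant
(`estimate_drift_multi`) exists for robustness studies; sessions whose
drift is not linear show up as large residuals and should be refused, not
repaired. Event times map to EEG samples by round-half-away-from-zero; the
same model is applied to fixation- and saccade-onset triggers, so their
sample offset is preserved.

## Epoching and averaging (`epochs`)

Named windows: [−0.3, 0.5] s for raw ERP comparison, [−0.5, 1.0] s for
deconvolution. Trials whose window leaves the recording are dropped, never
padded; trials overlapping bad-segment masks are dropped on any overlap by
default (fraction configurable). No baseline correction is applied by
default — a pre-event baseline of a saccade-aligned trial lies inside the
previous fixation's response, so subtracting it mixes trials; a
[−0.3, −0.1] s baseline flag exists for sensitivity analyses. Grand
averages are two-stage (mean within subject, then unweighted mean across
subjects) so high-trial-count subjects cannot dominate the sparse head
category. Duration-sorted trial images use descending saccade duration and
anisotropic Gaussian smoothing (σ = 2 trials × 5 samples by default).

## Stability statistic (`stability`)

Trials are partitioned once into B = 10 equal-count bins by saccade
duration (stable order breaks ties) and the same partition is applied to
both alignments. Per bin and alignment, the half-maximum latency is the
first upward crossing of `reference + (peak − reference)/2` before the
P100 peak, linearly interpolated; the peak is searched in
[0.06, 0.25] s (saccade-aligned) / [0.03, 0.2] s (fixation-aligned) by
default, and the reference is the [−0.2, −0.05] s mean (a zero-reference
flag exists and is used in the simulation studies, whose noise is
zero-mean by construction; the simulated saccade durations also push the
fixation-aligned peak toward the epoch start, so those studies widen the
fixation search window to [0, 0.25] s). The statistic is the sample SD of
latencies across bins per alignment. The paired test compares, by default,
each bin's absolute deviation from its alignment's mean latency
(`method="raw"` pairs the raw latencies instead); df = B − 1. The exact
per-bin quantity entering the published form of this test is not uniquely
determined by its description; both options are provided and documented
rather than certified.

Simulation conditions for the direction result: 20 subjects × 150 trials,
a purely saccade-locked 6 μV P100, white trial noise of 20 μV, saccade
durations normal with mean 55 ms and SD ∈ {10, 30, 50} ms clipped to
[5, 100] ms, at 500 Hz. These cohorts are built directly at the epoch
level (`simulate_stability_cohort`): each trial is one noise realization
on a continuous axis sliced at an integer-sample shift for the two
alignments, preserving the time-shift duality exactly while avoiding
full-session synthesis for 300 replicate cohorts.

## Deconvolution (`deconv`)

Time-expanded stick coding: column (c, τ) is 1 at sample s iff a category-c
saccade onset occurs at s − τ·rate, τ ∈ [−0.5, 1.0] s. No intercept column
(the stick columns absorb the mean response); no amplitude covariate by
default (amplitudes correlate strongly with the durations the alignment
already accounts for). Masked samples are zeroed out of both sides of the
least-squares problem.

The default solver forms the sparse normal equations once and solves them
with a dense Cholesky factorization shared across all channels — exact,
deterministic, and the only way a 32-channel, 900k-sample session fits in
minutes on one CPU (the cross-channel solve is a single triangular
back-substitution per channel). An iterative LSMR path
(atol = btol = 1e-10, iteration cap 20 000) is kept behind
`solver="lsmr"`; tests pin both to a dense `lstsq` oracle. Categories
without events yield NaN ("undefined") kernels; rank deficiency beyond
that falls back to `lstsq` with a warning. Without overlap the solution
provably reduces to per-category epoch averages (tested); with overlap and
zero noise the kernels are recovered to < 1e-6 μV while naive averaging
errs at the μV scale.

## Mass-univariate inference (`tfce`)

Per (channel, time) cell, the one-factor repeated-measures F is
`MS_condition / MS_condition×subject` with df (2, 2(n−1)); zero error
variance flags F = ∞ (or 0 when the condition effect is also zero).

TFCE: `enhanced(v) = Σ_h extent(v, h)^E · h^H · dh` over
h = dh, 2dh, … ≤ map max, with connectivity = channel adjacency plus
temporal adjacency, E = 0.666, H = 1 (the standard recommendation for F
statistics), dh = (observed map max)/100. The connected-component extents
are computed by a union-find over the channel×time grid compiled with
numba; the test suite checks it cell-for-cell against a brute-force BFS
enumerator and against the analytic single-cell limit h²/2.

Permutations shuffle the three condition labels independently within every
subject (the standard repeated-measures exchangeability scheme; the
published description "randomizing data across the three factors" is read
this way and flagged as an interpretation). The per-permutation maximum of
the enhanced map forms the null; `p(v) = (1 + #{null ≥ obs(v)})/(1 + n)`
never returns 0, and the mask is p < α. One numerical subtlety: dh is
fixed from the observed map for comparability, but every permuted map is
enhanced up to its *own* maximum — truncating permuted maps at the
observed height deflates the null maxima and was measurably
anticonservative in null simulations. With ≤ n_perm distinct shufflings
((3!)^subjects) the full set is enumerated instead, with a warning. A null
simulation (200 datasets × 10 subjects × 500 permutations, 6×20 maps)
keeps the family-wise rejection rate inside the 95% binomial band around
0.05. Cluster summaries report connected mask components and, per pairwise
contrast and electrode of the largest cluster, the within-cluster time of
maximal absolute mean difference with its SEM — a reconstruction of the
per-electrode "maximum contribution" display, labeled as such.

## End-to-end study size

The pipeline check simulates 6 subjects × 10-min sessions at default
parameters (paper-like category mix, 8 μV noise, between-subject SD 0.2,
clock drift on), runs detection → drift correction → deconvolution →
TFCE with 300 permutations, and requires the significance mask to cover
≥ 80% of the injected head-vs-background support (cells where the true
kernel difference exceeds half its maximum). These sizes are the package's
documented simulation-study conditions; they were chosen so that each
stage operates in its intended regime (hundreds of head trials per cohort,
overlap everywhere, drift of the realistic magnitude).

## Numerical and degenerate-input conventions

* SD convention: sample SD (ddof = 1) throughout.
* Circular statistics: within-subject circular means via the resultant
  vector, across-subject circular SD = sqrt(−2 ln R̄) in degrees; vanishing
  resultants flag NaN. Viewing-angle convention: 0° = facing the
  pedestrian's face, ±180° = back of the head, clockwise positive.
* Sample mapping rounds half away from zero (documented, tested at the
  boundary).
* Jitter-free, motion-free traces give exactly zero within-fixation
  velocity, hence zero adaptive thresholds — a degenerate configuration
  kept for testing only; default jitter keeps thresholds data-driven.
* All stochastic stages take explicit integer seeds; identical seeds give
  bit-identical outputs (tested for the generator and the permutation
  test).

## Known limitations

* Real per-subject clock drift can be nonlinear; the two-anchor model
  detects (via `residual_check`) but does not repair it.
* The fixed-vantage translational correction assumes bounded head
  excursions; long-range locomotion needs a windowed reference.
* The head-category trial count under the realistic mix is small by
  design; single-subject head kernels are noisy, which is precisely why
  the two-stage averaging and the cohort-level inference exist.
* The published headline magnitudes of the stability statistic
  (~20 vs ~8 ms) are bound to non-deposited human recordings; this package
  reproduces the direction and mechanism on synthetic cohorts, not those
  numbers.
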