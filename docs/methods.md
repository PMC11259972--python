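# Methods

This note documents the models, algorithms, parameter choices, and
known limitations of `hepflow`.  It is written for users who need to
judge what the pipeline computes and what passing its test suite does
and does not establish.

## Montage and electrode adjacency

The study layout is the international 10/20 placement plus the
inferior temporal pair T9/T10 — 23 scalp channels with legacy temporal
naming (T3/T4/T5/T6).  Positions are idealized unit-sphere coordinates
frozen into the package (derived once from the standard 10/05
electrode description, centered on the best-fit sphere and
normalized).  The 2-D layout used for triangulation is the azimuthal
equidistant projection from the vertex.

Electrode neighbors are the union of (a) Delaunay edges of the
projected layout and (b) all channel pairs with 3-D chord distance
≤ 0.9.  Delaunay triangulation alone yields a mean degree of 4.7 on
this layout; the distance augmentation (radius calibrated once and
frozen) brings it to 5.57, matching the ≈5.6 neighbors per electrode
that clinical-EEG neighbor templates typically produce.  An optional
prune cutoff removes over-long Delaunay edges on degenerate layouts.

## Cardiac processing

* **ECG conditioning.** 2nd-order Butterworth band-pass 3–30 Hz,
  applied forward and backward (zero phase) so R-peak latencies are
  not displaced.
* **R-peak detection** is derivative–square–integrate: the squared
  gradient of the filtered trace is smoothed with a 150 ms moving
  window; candidate beats are energy peaks above an adaptive threshold
  (0.5 × a rolling 95th percentile over 10 s), at least 200 ms apart
  (refractory bound); each candidate is refined to the local maximum
  of the polarity-corrected filtered trace within ±80 ms.  Polarity is
  flipped when the dominant deflection is negative.  A flat trace
  yields an empty peak series rather than an error.  The detector is
  deterministic; on generator output at default noise it recovers
  > 99 % of ground-truth beats at ±1 sample.
* **RR statistics.** RR intervals in ms from successive peak gaps;
  HR = 60000/mean(RR); RMSSD = √mean(ΔRR²); the geometric HRV index
  maps relative RR intervals r_i = 2(RR_{i+1} − RR_i)/(RR_{i+1} +
  RR_i) into a return plot (r_i, r_{i+1}) and reports the median
  Euclidean distance to the points' center × 100 (%).  The center is
  the component-wise *mean* of the points; a median center would be a
  defensible alternative, and the choice is recorded here because the
  upstream tooling this index originates from does not specify it.
  The statistic is invariant to rescaling the RR series (machine
  precision) and is computed over the full recording segment.

## EEG preprocessing

* **Filtering.** 50 Hz notch (IIR, Q = 30) followed by a 2nd-order
  Butterworth band-pass 0.16–30 Hz, both zero-phase.  The 0.16 Hz
  high-pass corner keeps slow-potential distortion low; 30 Hz removes
  line/muscle residue above the HEP band.
* **Bad channels.** Two criteria, evaluated before filtering so line
  noise is visible: (a) predictability — for each channel, a
  spherical-spline estimate from all other channels is computed and
  correlated with the channel in 5 s windows; the channel is flagged
  when the median windowed correlation falls below 0.80; (b) line
  noise — 45–55 Hz Welch band power more than 4 population standard
  deviations above the across-channel mean.  The windowing and
  aggregation (5 s, median) are this package's choices; the thresholds
  (0.80, z = 4) follow standard automated-cleaning settings.  If every
  channel is flagged the recording is rejected with a diagnostic.
* **Interpolation.** Perrin-style spherical splines: kernel
  g(x) = (1/4π) Σ_{l=1..7} (2l+1)/(l(l+1))^4 P_l(x) (order m = 4,
  seven series terms, ridge 10⁻⁵ on the kernel diagonal), solved with
  the standard bordered system so constants are reproduced exactly.
  A first-order harmonic field is recovered at a held-out electrode
  within 5 %; error grows with harmonic order, as expected from the
  kernel's smoothness prior.
* **Reference.** Average reference (instantaneous across-channel mean
  subtracted), applied after interpolation so the mean is built from
  valid channels only.  Idempotent, and commutes with the linear
  filters.
* ICA-based artifact correction is deliberately not part of the
  module: `filter_eeg`'s output is an ordinary recording, so an
  external cleaning step can be inserted between filtering and
  interpolation.

## Epoching and inclusion

Epochs span −100…700 ms around each detected R-peak (exactly 161
samples at 200 Hz, endpoints inclusive, time 0 on the R-peak sample).
No baseline correction is applied: the pre-peak interval contains the
previous cardiac cycle's field artifact, and subtracting it would move
that artifact into the epoch.  Rejection flags, in order of recorded
precedence: `boundary` (epoch extends past the recording), `amplitude`
(any EEG sample strictly exceeds 75 μV in absolute value), and
`multi_rpeak` (another detected R-peak in (0, 700] ms after the
reference peak — the succeeding beat's artifact would contaminate the
late window; peaks *before* the reference do not trigger the rule).
The amplitude and multi-peak rules commute.  A subject-condition is
included when the rejected fraction is ≤ 0.25 *and* kept epochs are
strictly > 100, evaluated per condition.  Evoked averages are plain
arithmetic means over kept epochs; the mECG control waveform is the
ECG channel epoched and averaged identically.  Window means (e.g. over
the 200–650 ms window of interest) are inclusive of both endpoints on
the native 5 ms grid.

## Cluster-based permutation inference

Subject-level evoked maps restricted to the 200–650 ms window (91
samples at 200 Hz) enter a two-sided cluster-mass permutation test:

1. Pointwise t-map: one-sample t on per-subject condition differences
   (paired; df = n−1) or pooled-variance two-sample t (independent;
   df = n₁+n₂−2).  Zero-variance points become ±∞ sentinels, excluded
   from clustering with a warning.
2. Forming threshold: the two-tailed critical t at α = 0.05 for the
   design's df.
3. Clusters: connected components of same-sign suprathreshold samples,
   connectivity = same channel & adjacent time samples, or neighboring
   channels & same time sample (no diagonal links, no minimum cluster
   size).  Cluster mass = Σt over members.
4. Null distribution: per permutation (random per-subject sign flips,
   or group-label shuffles preserving group sizes), the maximum
   positive and minimum negative cluster mass are recorded; 1000
   permutations by default.  When the exact permutation space is no
   larger than the requested number (2ⁿ sign flips or C(n, n₁)
   assignments), the test switches to exhaustive enumeration and
   p-values are exact.
5. p-values: Monte-Carlo p = (#{null at least as extreme, same tail}
   + 1)/(N + 1) — the observed statistic counts as one permutation,
   which keeps the test valid at any N (smallest attainable p is
   1/(N+1)).  Exhaustive p-values are plain counts over the full
   enumeration.  Clusters are significant at p < 0.025 per tail
   (0.05 family-wise two-sided).
6. Follow-up per cluster: per-subject amplitudes averaged over the
   cluster's channel-time members, their paired or two-sample t, and
   Cohen's d = t/√n (paired) or d = 2t/√df (independent); the peak is
   the member with the largest |t|.  A zero-variance amplitude set
   reports d as undefined (NaN).

The permutation engine is vectorized across permutations (t-maps for
all sign flips computed as one matrix product) and the observed
clustering was verified to agree member-for-member and mass-for-mass
with an independent implementation (mne's spatio-temporal cluster
test) as well as with a naive BFS + full-enumeration oracle in the
test suite.

## Nonparametric controls

Wilcoxon signed-rank: zero differences dropped, tie-averaged ranks,
Z = (W⁺ − m(m+1)/4)/σ with tie-corrected σ and **no** continuity
correction, signed so pre > post gives positive Z; effect size
r = Z/√(2n) with n the supplied pairs.  Mann–Whitney: U for group A
(ties half), tie-corrected Z without continuity correction, r = Z/√N.
The r conventions reproduce printed (Z, n, r) triples of this
analysis style to two decimals; they are conventions inferred from
such triples, not formulas the upstream literature states explicitly.
Exact two-sided p-values by full enumeration are available for small
samples (and are the internal test oracle); the normal approximation
is used otherwise.  Normality routing uses Shapiro–Wilk at 0.05;
constant samples route nonparametric with a warning.  Medians and
quartiles use linear interpolation, and IQRs are reported as (Q1, Q3)
pairs.

## Synthetic-data generator

The generator emulates a paired clinical hyperventilation study with
two balanced age groups and balanced sex, two 3-minute conditions per
subject at 200 Hz.  What it models:

* **RR series**: Gaussian AR(1) (lag-1 coefficient 0.3) around
  850 ms with 40 ms marginal SD, plus a 15 ms sinusoidal respiratory
  modulation at 0.25 Hz; the post condition multiplies the SD by 0.7,
  reproducing the direction of the post-challenge HRV reduction.
  Non-positive draws (essentially impossible under mean > 2·SD) are
  resampled with a warning.
* **ECG**: a QRST template — five Gaussian bumps (P, Q, R, S, T) at
  fixed latencies/amplitudes relative to R, R normalized to 1 mV
  equivalent (1000 μV) — placed at cumulative RR positions, plus
  15 μV white noise and slow baseline drift.  Ground-truth R-peak
  sample indices travel with the recording.
* **EEG background**: channel-wise 1/f (pink) noise, unit-variance
  per channel, mixed spatially by the Cholesky factor of a
  squared-exponential correlation kernel in chord distance (scale
  1.2, i.e. ≈0.9 correlation at neighboring electrodes).  The scale
  was chosen so clean synthetic channels behave like volume-conducted
  scalp EEG — in particular, they pass the 0.80 predictability
  criterion that automated cleaning presumes of real data.  Marginal
  SD 10 μV.
* **Cardiac field artifact**: the clean ECG template projected into
  every EEG channel through per-subject gains (a fixed dipolar
  spatial pattern × subject-level lognormal multiplier, scale 0.004 →
  ≈4 μV R-wave artifact), shared by both conditions of a subject.
* **HEP component**: a raised-cosine bump in time over 530–560 ms
  after each R-peak, spatial weight 1.0 on Fp1/F3/C3/F7/Fz, 0.5 on
  their graph neighbors, 0 elsewhere; injected in the *pre* condition
  of the *elderly* group by default.  Per-subject amplitudes are
  N(1.0, 1.6²) μV: the mean sets the injected signal, the spread
  makes the between-subject effect size realistic for a marginal
  late-HEP effect (cluster-level d in the 0.5–0.7 range at n = 40).
  Since no amplitude scale for genuine HEP activity versus CFA is
  available a priori, these defaults are justified purely by that
  downstream effect-size calibration.

A second entry point, `simulate_evoked_dataset`, draws subject-level
evoked difference maps directly (same spatial kernel and 1/f
temporal spectrum, unit marginal SD, optional raised-cosine effect).
Permutation-test calibration studies — family-wise error rate and
effect recovery — run at this level: the within-subject averaging
step is exercised separately, and evoked-level simulation is what
makes hundreds of studies tractable.

What the generator does **not** model: epileptiform activity, ocular
or muscle artifacts, respiration traces, drug effects, electrode
drift, or subject-specific evoked topographies beyond the injected
component.  Passing tests on synthetic data therefore demonstrates
algorithmic correctness and statistical calibration under a
known-truth model, not robustness to every failure mode of clinical
recordings.

## Problem sizes used by the test and acceptance runs

Simulation-based checks use sizes chosen to make their Monte-Carlo
error small relative to the quantity under test: the family-wise
error study runs 400 null datasets of 20 paired subjects × 23
channels × 91 samples with 1000 permutations each; the effect-recovery
study runs 100 datasets of 40 subjects, with the injected amplitude
calibrated at run time so the true region-averaged paired effect size
is d = 0.62 (the between-subject SD of the region average is estimated
from 400 noise-only draws).  End-to-end pipeline tests use compact raw
studies (8 subjects per group, 40 s per condition) with a deliberately
strong injected effect so detection is deterministic at small n.

## Numerical choices and edge cases

* Zero-variance t-map points → ±∞ sentinels, excluded from clustering.
* Observed-vs-null mass comparisons use a relative tolerance of 10⁻⁹,
  because the identity permutation recomputes the observed mass
  through a different (vectorized) numerical route.
* 0/0 t-values (no signal, no variance) are set to 0.
* All randomness flows through `numpy` `SeedSequence` spawning: one
  seed determines the study, per-subject streams, and per-design
  permutation draws; identical seeds give byte-identical outputs.
* Recording persistence uses compressed `.npz` (float32); EDF files
  can be read via mne when available.  No EDF writer is provided.

## Known limitations

* The "slow R-peak detection" of the clinical tooling this pipeline
  mirrors is unspecified upstream; the detector here is a standard
  Pan–Tompkins-style construction and will differ in edge cases.
* With strong average-referenced effects, every positive cluster has a
  mirrored negative counterpart; reports should be read jointly.
* Power to detect a *marginal* (d ≈ 0.6) localized late effect under
  realistically correlated noise is intrinsically limited (≈70 % at
  n = 40 in the recovery study): the effect cluster's mass sits near
  the null max-mass distribution's 97.5th percentile.  This is a
  property of the max-mass procedure at these noise conditions, not an
  implementation artifact — the same engine shows nominal family-wise
  error on null data and matches exhaustive enumeration exactly at
  small n.
* The cluster test assumes exchangeability across the permuted unit
  (subjects); it does not model within-subject epoch-count imbalance.
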