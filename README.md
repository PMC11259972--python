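# hepflow

Heartbeat-evoked potential (HEP) analysis for clinical EEG: from raw
multichannel EEG + ECG to cluster-level inference about condition and
group differences in R-peak-locked cortical potentials, with the
cardiac control statistics that such analyses require.

## The problem

The HEP is the scalp EEG potential averaged time-locked to the ECG
R-peak, and is widely used as a neural index of cardiac interoception.
Detecting HEP differences between conditions (for example before and
after a voluntary-hyperventilation challenge) or between groups (age,
sex) faces two obstacles: the cardiac field artifact (CFA) — the
heart's own electrical field contaminating the scalp — and a massive
multiple-comparison problem over channels × time points.  `hepflow`
implements the standard answer to both:

* **Cardiac leg.** ECG band-pass (2nd-order Butterworth, 3–30 Hz,
  zero-phase), derivative–square–integrate R-peak detection with an
  adaptive threshold and 200 ms refractory bound, then RR statistics:
  heart rate (bpm), RMSSD (ms), and a geometric HRV index (%) — the
  median distance to center in the return map of *relative RR
  intervals* r<sub>i</sub> = 2(RR<sub>i+1</sub> −
  RR<sub>i</sub>)/(RR<sub>i+1</sub> + RR<sub>i</sub>).
* **EEG leg.** 50 Hz notch + 0.16–30 Hz band-pass (zero-phase), bad
  channels flagged by low predictability (median windowed correlation
  < 0.80 against a spherical-spline estimate from the other channels)
  or excess 45–55 Hz line-noise power (z > 4 across channels),
  Perrin-style spherical-spline interpolation, average reference.
* **Epoching.** Epochs −100…700 ms around each R-peak (161 samples at
  200 Hz), **no** baseline correction (the pre-peak window contains the
  previous cycle's CFA).  Epochs are rejected if any channel exceeds
  ±75 μV or a second R-peak falls within (0, 700] ms; a
  subject-condition enters the analysis only if ≤ 25 % of epochs were
  rejected *and* more than 100 remain.
* **Inference.** Spatio-temporal cluster-based permutation tests over
  the 200–650 ms window of interest: pointwise t-maps (paired or
  independent), two-tailed cluster-forming threshold at p = 0.05,
  clusters of same-sign neighbors (electrode adjacency ∪ adjacent time
  samples), cluster **mass** = Σt as the test statistic, referred to
  the permutation distribution of the most extreme mass (1000
  permutations; sign flips for paired designs, group shuffles for
  independent ones; exhaustive enumeration when the permutation space
  is small), significant at p < 0.025 per tail.  Follow-up effect
  sizes use d = t/√n (paired) and d = 2t/√df (independent).
* **Controls.** Wilcoxon signed-rank and Mann–Whitney U with
  tie-corrected normal-approximation Z, medians/IQR, and effect sizes
  r = Z/√(2n) (paired) or r = Z/√N (independent).

Because clinical recordings of this kind cannot be redistributed, the
package ships a synthetic-study generator with known ground truth
(QRST-template ECG, AR(1) RR series with respiratory modulation,
spatially correlated 1/f EEG noise, a CFA projection, and an
injectable late frontal HEP component), so the full pipeline is
testable end to end.  See `docs/methods.md` for model details.

## Worked example

```python
from dataclasses import replace
import hepflow as hf

config = hf.SyntheticStudyConfig(
    n_subjects_per_group=8, duration_s=40.0, seed=11,
    hep_effect=replace(hf.HepEffect(), amplitude_uv=6.0, subject_sd_uv=0.5),
)
study = hf.generate_study(config)
bundle = hf.run_study_analysis(
    study, hf.PipelineConfig(min_kept_epochs=10, n_permutations=200, seed=5)
)
for s in bundle["cluster_results"]["paired_elderly"]["summary"][:2]:
    print(
        f"mass={s['mass']:.1f} sign={s['sign']:+d} p={s['p_mc']:.4f} "
        f"window={s['time_span_ms']} t={s['t']:.2f} d={s['d']:.2f}"
    )
```

prints

```
mass=-263.0 sign=-1 p=0.0100 window=(530.0, 570.0) t=-12.04 d=-4.26
mass=251.9 sign=+1 p=0.0100 window=(530.0, 565.0) t=14.96 d=5.29
```

The generator injected a strong (6 μV) pre-condition HEP component at
530–560 ms on frontal channels of the "elderly" group only.  The
paired test on that group recovers a significant positive cluster
covering the injected window (pre > post over frontal electrodes),
together with its average-reference counterpart of opposite sign over
posterior sites; `p = 0.0100` is the Monte-Carlo floor at 200
permutations ((1+1)/201), and `d` is the follow-up paired Cohen's d of
the cluster-averaged amplitudes.  The same bundle carries the
Table-style cardiac controls (`bundle["control_table"]`): HRV and
RMSSD come out higher pre than post, mirroring the generator's lower
post-condition RR variability, while heart rate is unchanged.

A command-line interface covers the same flow stage by stage
(`hepflow simulate | preprocess | epoch | cluster | controls | report |
all`), with cacheable artifacts in a working directory.

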