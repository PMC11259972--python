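"""Study-shaped synthetic EEG+ECG data with known ground truth.

The generator emulates the structure of a paired clinical
hyperventilation study: per subject, one pre- and one post-condition
recording of simultaneous 23-channel EEG and ECG at 200 Hz, with two
balanced age groups and balanced sex.  Each recording contains

* an ECG built from a QRST template (five Gaussian bumps) placed at
  cumulative RR positions, where the RR series is a Gaussian AR(1)
  process with optional respiratory sinusoidal modulation and lower
  variability in the post condition;
* spatially correlated 1/f ("pink") background EEG;
* a cardiac field artifact — the ECG template projected into every
  EEG channel through per-subject channel gains; and
* an optional genuine heartbeat-evoked component: a raised-cosine
  bump in a late time window after each R-peak, spatially smooth over
  a configured electrode neighborhood, injected only in the effect
  condition (and, by default, only in the elderly group).

True R-peak positions travel with each recording so every downstream
stage can be scored against ground truth.  A second, lighter-weight
entry point (`simulate_evoked_dataset`) draws subject-level evoked
difference maps directly — the natural scale for permutation-test
calibration studies, where the within-subject averaging step is not
itself under test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import build_adjacency
from .montage import MontageLayout, default_montage
from .recording import MultichannelRecording

__all__ = [
    "HepEffect",
    "SyntheticStudyConfig",
    "generate_rr_series",
    "generate_subject_recording",
    "generate_study",
    "simulate_evoked_dataset",
    "EvokedEffect",
    "StudyData",
]

CONDITIONS = ("pre", "post")
GROUPS = ("young", "elderly")
SEXES = ("F", "M")

#: QRST template: (latency ms rel. R, amplitude rel. R, Gaussian sigma ms)
QRST_BUMPS = (
    (-220.0, 0.12, 35.0),   # P
    (-25.0, -0.15, 10.0),   # Q
    (0.0, 1.00, 11.0),      # R
    (30.0, -0.25, 12.0),    # S
    (280.0, 0.30, 60.0),    # T
)


@dataclass(frozen=True)
class HepEffect:
    """Ground-truth heartbeat-evoked component injected by the generator."""

    channels: tuple[str, ...] = ("Fp1", "F3", "C3", "F7", "Fz")
    window_ms: tuple[float, float] = (530.0, 560.0)
    amplitude_uv: float = 1.0
    subject_sd_uv: float = 1.6
    neighbor_weight: float = 0.5
    condition: str = "pre"          # condition carrying the larger amplitude
    groups: tuple[str, ...] = ("elderly",)


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Parameters of one synthetic paired study.

    Defaults mirror the study conditions: 20 subjects per age group
    (40 total), 200 Hz, 3-minute segments per condition, resting RR
    around 850 ms with ~40 ms beat-to-beat variability that shrinks by
    a factor 0.7 after hyperventilation, and a ~1 μV late frontal
    evoked component in the pre condition of the elderly group whose
    between-subject spread puts the cluster-level effect size near
    d ≈ 0.6.
    """

    n_subjects_per_group: int = 20
    sample_rate: float = 200.0
    duration_s: float = 180.0
    mean_rr_ms: float = 850.0
    rr_sd_ms: float = 40.0
    post_sd_factor: float = 0.7
    ar_coefficient: float = 0.3
    resp_freq_hz: float = 0.25
    resp_amplitude_ms: float = 15.0
    hep_effect: HepEffect = field(default_factory=HepEffect)
    cfa_gain_scale: float = 0.004
    cfa_subject_sd: float = 0.2     # lognormal sigma of per-subject gain
    noise_sd_uv: float = 10.0
    spectral_exponent: float = 1.0
    spatial_scale: float = 1.2      # chord-distance scale of channel correlation
    ecg_r_amplitude_uv: float = 1000.0
    ecg_noise_uv: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("need at least one subject per group")
        if self.mean_rr_ms <= 0 or self.rr_sd_ms < 0:
            raise ValueError("RR parameters must be positive")
        if self.mean_rr_ms <= 2 * self.rr_sd_ms:
            raise ValueError("mean_rr_ms must exceed 2 * rr_sd_ms")
        if not 0 < self.post_sd_factor <= 1.5:
            raise ValueError("post_sd_factor out of range")
        lo, hi = self.hep_effect.window_ms
        if not (-100.0 <= lo < hi <= 700.0):
            raise ValueError("effect window must lie within [-100, 700] ms")
        montage = default_montage()
        unknown = set(self.hep_effect.channels) - set(montage.labels)
        if unknown:
            raise ValueError(f"effect channels not in montage: {sorted(unknown)}")
        if set(self.hep_effect.groups) - set(GROUPS):
            raise ValueError(f"effect groups must be subset of {GROUPS}")
        if self.hep_effect.condition not in CONDITIONS:
            raise ValueError(f"effect condition must be one of {CONDITIONS}")


def generate_rr_series(
    config: SyntheticStudyConfig, condition: str, rng: np.random.Generator
) -> np.ndarray:
    """RR interval series (ms) covering one condition's duration.

    Gaussian AR(1) around the configured mean with marginal SD
    ``rr_sd_ms`` (scaled by ``post_sd_factor`` in the post condition),
    plus a slow sinusoidal respiratory modulation.  Non-positive draws
    — essentially impossible under the precondition
    ``mean > 2 · sd`` — are resampled with a warning.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    sd = config.rr_sd_ms * (config.post_sd_factor if condition == "post" else 1.0)
    phi = config.ar_coefficient
    n = int(math.ceil(config.duration_s * 1000.0 / config.mean_rr_ms)) + 2
    innov_sd = sd * math.sqrt(max(0.0, 1.0 - phi**2))
    rr = np.empty(n)
    state = 0.0
    for i in range(n):
        state = phi * state + rng.normal(0.0, innov_sd) if i else rng.normal(0.0, sd)
        rr[i] = config.mean_rr_ms + state
    # respiratory modulation on the beat times
    t = np.cumsum(rr) / 1000.0
    rr = rr + config.resp_amplitude_ms * np.sin(
        2 * math.pi * config.resp_freq_hz * t
    )
    bad = rr <= 0
    while np.any(bad):
        warnings.warn("non-positive RR draw resampled", stacklevel=2)
        rr[bad] = config.mean_rr_ms + rng.normal(0.0, sd, size=int(bad.sum()))
        bad = rr <= 0
    return rr


def qrst_waveform(
    positions: np.ndarray, n_samples: int, sample_rate: float, r_amplitude: float
) -> np.ndarray:
    """Sum of QRST templates centered at the given R-peak samples."""
    span_lo = min(lat - 4 * sig for lat, _, sig in QRST_BUMPS)
    span_hi = max(lat + 4 * sig for lat, _, sig in QRST_BUMPS)
    lo = int(math.floor(span_lo * sample_rate / 1000.0))
    hi = int(math.ceil(span_hi * sample_rate / 1000.0))
    t_ms = np.arange(lo, hi + 1) * 1000.0 / sample_rate
    kernel = np.zeros_like(t_ms)
    for lat, amp, sig in QRST_BUMPS:
        kernel += amp * np.exp(-0.5 * ((t_ms - lat) / sig) ** 2)
    kernel *= r_amplitude
    trace = np.zeros(n_samples)
    for p in positions:
        a, b = p + lo, p + hi + 1
        ka, kb = max(0, -a), kernel.size - max(0, b - n_samples)
        trace[max(0, a):min(n_samples, b)] += kernel[ka:kb]
    return trace


def pink_noise(
    n_channels: int, n_samples: int, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance 1/f^exponent noise, independent across channels."""
    white = rng.standard_normal((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    spectrum = np.fft.rfft(white, axis=-1) * scale
    x = np.fft.irfft(spectrum, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _spatial_mixer(montage: MontageLayout, scale: float) -> np.ndarray:
    """Cholesky factor of the channel correlation kernel.

    Squared-exponential in chord distance — volume conduction makes
    neighboring scalp channels highly correlated (≈0.9 at typical
    inter-electrode distance with the default scale) while distant
    sites decorrelate, which is what the correlation-based bad-channel
    criterion presumes of clean data.
    """
    corr = np.exp(-((montage.chord_distances() / scale) ** 2))
    return np.linalg.cholesky(corr + 1e-9 * np.eye(montage.n_channels))


def _effect_weights(montage: MontageLayout, effect: HepEffect) -> np.ndarray:
    """Per-channel spatial weights: 1 on listed channels, ½ on neighbors."""
    adjacency = build_adjacency(montage)
    w = np.zeros(montage.n_channels)
    core = set(effect.channels)
    for label in core:
        w[montage.index(label)] = 1.0
    for label in core:
        for nb in adjacency.neighbors(label):
            if nb not in core:
                w[montage.index(nb)] = max(
                    w[montage.index(nb)], effect.neighbor_weight
                )
    return w


def _raised_cosine(times_ms: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    lo, hi = window_ms
    w = np.zeros_like(times_ms)
    inside = (times_ms >= lo) & (times_ms <= hi)
    w[inside] = 0.5 * (1.0 - np.cos(2 * math.pi * (times_ms[inside] - lo) / (hi - lo)))
    return w


def generate_subject_recording(
    config: SyntheticStudyConfig,
    rr_ms: np.ndarray,
    rng: np.random.Generator,
    *,
    condition: str,
    cfa_gain: np.ndarray | None = None,
    hep_amplitude_uv: float = 0.0,
    montage: MontageLayout | None = None,
) -> MultichannelRecording:
    """Synthesize one condition recording from an RR series.

    The returned recording carries its ground-truth R-peak sample
    indices in ``true_r_peaks``.
    """
    montage = montage or default_montage()
    fs = config.sample_rate
    n_samples = int(round(config.duration_s * fs))
    rr_ms = np.asarray(rr_ms, dtype=float)
    if rr_ms.size == 0:
        raise ValueError("rr series is empty")

    beat_times_ms = 500.0 + np.concatenate([[0.0], np.cumsum(rr_ms)])
    positions = np.round(beat_times_ms * fs / 1000.0).astype(np.int64)
    margin = int(0.5 * fs)
    positions = positions[(positions >= margin) & (positions < n_samples - margin)]
    if positions.size == 0:
        raise ValueError("duration too short for a single beat")

    ecg_clean = qrst_waveform(positions, n_samples, fs, config.ecg_r_amplitude_uv)
    ecg = (
        ecg_clean
        + rng.normal(0.0, config.ecg_noise_uv, n_samples)
        + 100.0 * np.sin(2 * math.pi * 0.3 * np.arange(n_samples) / fs)
    )

    mixer = _spatial_mixer(montage, config.spatial_scale)
    eeg = config.noise_sd_uv * (
        mixer @ pink_noise(montage.n_channels, n_samples, config.spectral_exponent, rng)
    )

    if cfa_gain is None:
        cfa_gain = np.zeros(montage.n_channels)
    eeg += np.outer(np.asarray(cfa_gain, dtype=float), ecg_clean)

    if hep_amplitude_uv != 0.0:
        weights = _effect_weights(montage, config.hep_effect)
        lo, hi = config.hep_effect.window_ms
        lo_s = int(round(lo * fs / 1000.0))
        hi_s = int(round(hi * fs / 1000.0))
        t_ms = np.arange(lo_s, hi_s + 1) * 1000.0 / fs
        bump = hep_amplitude_uv * _raised_cosine(t_ms, (lo, hi))
        patch = np.outer(weights, bump)
        for p in positions:
            a, b = p + lo_s, p + hi_s + 1
            if a >= 0 and b <= n_samples:
                eeg[:, a:b] += patch

    return MultichannelRecording(
        eeg=eeg,
        ecg=ecg,
        sample_rate=fs,
        channel_labels=montage.labels,
        true_r_peaks=positions,
        meta={"condition": condition, "hep_amplitude_uv": hep_amplitude_uv},
    )


@dataclass
class SubjectData:
    subject_id: str
    group_age: str
    sex: str
    seed: int
    hep_amplitude_uv: float
    recordings: dict  # condition -> MultichannelRecording or file path


@dataclass
class StudyData:
    """A full synthetic study: subject recordings plus metadata."""

    config: SyntheticStudyConfig
    montage: MontageLayout
    subjects: list[SubjectData]

    @property
    def manifest(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for cond, rec in s.recordings.items():
                rows.append(
                    {
                        "subject_id": s.subject_id,
                        "group_age": s.group_age,
                        "sex": s.sex,
                        "condition": cond,
                        "path": rec if isinstance(rec, str) else "",
                        "seed": s.seed,
                    }
                )
        return pd.DataFrame(rows)


def generate_study(
    config: SyntheticStudyConfig, out_dir=None, montage: MontageLayout | None = None
) -> StudyData:
    """Generate the full paired study (two recordings per subject).

    Subject counts are balanced across the two age groups, sex is
    balanced within group, and both condition recordings of a subject
    share that subject's cardiac-field-artifact gains.  With
    ``out_dir`` given, recordings are written to compressed ``.npz``
    files as they are produced (memory-light for full-size studies)
    and the manifest references the files.
    """
    from .io import save_recording_npz  # local import to avoid a cycle

    montage = montage or default_montage()
    root_ss = np.random.SeedSequence(config.seed)
    n_total = 2 * config.n_subjects_per_group
    children = root_ss.spawn(n_total)

    axis = np.array([0.3, 0.6, -0.74])
    axis /= np.linalg.norm(axis)
    cfa_pattern = montage.positions @ axis

    subjects: list[SubjectData] = []
    effect = config.hep_effect
    k = 0
    for group in GROUPS:
        for i in range(config.n_subjects_per_group):
            ss = children[k]
            rng = np.random.default_rng(ss)
            subject_id = f"S{k + 1:03d}"
            sex = SEXES[i % 2]
            gain = (
                config.cfa_gain_scale
                * cfa_pattern
                * rng.lognormal(0.0, config.cfa_subject_sd)
            )
            if group in effect.groups:
                amp = rng.normal(effect.amplitude_uv, effect.subject_sd_uv)
            else:
                amp = 0.0
            recordings = {}
            for condition in CONDITIONS:
                rr = generate_rr_series(config, condition, rng)
                rec = generate_subject_recording(
                    config,
                    rr,
                    rng,
                    condition=condition,
                    cfa_gain=gain,
                    hep_amplitude_uv=amp if condition == effect.condition else 0.0,
                    montage=montage,
                )
                if out_dir is not None:
                    path = save_recording_npz(rec, out_dir, subject_id, condition)
                    recordings[condition] = str(path)
                else:
                    recordings[condition] = rec
            subjects.append(
                SubjectData(
                    subject_id=subject_id,
                    group_age=group,
                    sex=sex,
                    seed=int(ss.entropy) if ss.entropy is not None else 0,
                    hep_amplitude_uv=amp,
                    recordings=recordings,
                )
            )
            k += 1
    study = StudyData(config=config, montage=montage, subjects=subjects)
    if out_dir is not None:
        from .io import write_manifest

        write_manifest(study.manifest, out_dir)
    return study


# ---------------------------------------------------------------------------
# evoked-level simulator (for permutation-test calibration studies)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvokedEffect:
    """Effect specification for subject-level evoked difference maps."""

    channels: tuple[str, ...] = ("Fp1", "F3", "C3", "F7", "Fz")
    window_ms: tuple[float, float] = (530.0, 560.0)
    amplitude_uv: float = 0.62
    neighbor_weight: float = 0.5
    subject_sd_uv: float = 0.0


def simulate_evoked_dataset(
    n_subjects: int,
    times_ms: np.ndarray | None = None,
    montage: MontageLayout | None = None,
    noise_sd_uv: float = 1.0,
    spectral_exponent: float = 1.0,
    spatial_scale: float = 1.2,
    effect: EvokedEffect | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-subject evoked condition-difference maps directly.

    Each subject's map is spatially correlated pink noise over the
    montage (marginal SD ``noise_sd_uv`` per channel-time point) plus,
    if ``effect`` is given, a raised-cosine bump in the effect window
    on the listed channels (half weight on their neighbors).  With the
    default unit noise SD, ``effect.amplitude_uv`` is the pointwise
    Cohen's d of the injected difference at the bump center.

    Returns ``(data, times_ms)`` with ``data`` of shape
    ``(n_subjects, n_channels, n_times)``.
    """
    montage = montage or default_montage()
    if times_ms is None:
        times_ms = np.arange(200.0, 650.0 + 1e-9, 5.0)  # 91-sample TOI at 200 Hz
    times_ms = np.asarray(times_ms, dtype=float)
    rng = np.random.default_rng(rng)
    n_ch, n_t = montage.n_channels, times_ms.size
    mixer = _spatial_mixer(montage, spatial_scale)
    data = np.empty((n_subjects, n_ch, n_t))
    for s in range(n_subjects):
        data[s] = noise_sd_uv * (
            mixer @ pink_noise(n_ch, n_t, spectral_exponent, rng)
        )
    if effect is not None:
        hep = HepEffect(
            channels=tuple(effect.channels),
            window_ms=effect.window_ms,
            neighbor_weight=effect.neighbor_weight,
        )
        weights = _effect_weights(montage, hep)
        bump = _raised_cosine(times_ms, effect.window_ms)
        patch = np.outer(weights, bump)
        amps = (
            rng.normal(effect.amplitude_uv, effect.subject_sd_uv, n_subjects)
            if effect.subject_sd_uv > 0
            else np.full(n_subjects, effect.amplitude_uv)
        )
        data += amps[:, None, None] * patch[None]
    return data, times_ms
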