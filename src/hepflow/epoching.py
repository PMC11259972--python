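"""R-peak-locked epoching, artifact rejection, and evoked averaging.

Epochs span −100 to 700 ms around each R-peak (161 samples at 200 Hz)
with no baseline correction — the pre-peak interval contains the tail
of the previous cardiac cycle, so subtracting it would inject cardiac
field artifact into the epoch.  Rejection drops epochs with any sample
exceeding ±75 μV and epochs containing a second R-peak within
(0, 700] ms of the reference peak (the succeeding heartbeat's field
artifact would otherwise masquerade as late evoked activity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cardiac import RPeakSeries
from .recording import MultichannelRecording

KEPT = "kept"
FLAG_AMPLITUDE = "amplitude"
FLAG_MULTI_RPEAK = "multi_rpeak"
FLAG_BOUNDARY = "boundary"

DEFAULT_WINDOW_MS = (-100.0, 700.0)
DEFAULT_TOI_MS = (200.0, 650.0)
AMPLITUDE_LIMIT_UV = 75.0


@dataclass
class EpochSet:
    """R-peak-locked epochs with rejection bookkeeping.

    ``data`` is epochs × channels × time (μV); ``ecg`` carries the ECG
    channel epoched identically (epochs × time).  ``peak_samples``
    records each epoch's source R-peak; ``flags`` holds the rejection
    status per epoch.
    """

    data: np.ndarray
    ecg: np.ndarray
    times_ms: np.ndarray
    peak_samples: np.ndarray
    flags: np.ndarray
    channel_labels: tuple[str, ...]
    sample_rate: float

    def __post_init__(self) -> None:
        if self.data.shape[0] != self.flags.shape[0]:
            raise ValueError("one flag per epoch required")
        valid = {KEPT, FLAG_AMPLITUDE, FLAG_MULTI_RPEAK, FLAG_BOUNDARY}
        if self.flags.size and not set(np.unique(self.flags)) <= valid:
            raise ValueError(f"flags must be subset of {valid}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def kept_mask(self) -> np.ndarray:
        return self.flags == KEPT

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    def kept(self) -> "EpochSet":
        m = self.kept_mask
        return EpochSet(
            self.data[m], self.ecg[m], self.times_ms, self.peak_samples[m],
            self.flags[m], self.channel_labels, self.sample_rate,
        )


@dataclass(frozen=True)
class EvokedWaveform:
    """Per-subject evoked average (channels × time, μV)."""

    data: np.ndarray
    times_ms: np.ndarray
    n_epochs: int
    condition: str
    modality: str  # "HEP" (EEG) or "mECG" (ECG channel)
    channel_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.modality not in ("HEP", "mECG"):
            raise ValueError("modality must be 'HEP' or 'mECG'")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("evoked waveform contains non-finite values")


def epoch_around_rpeaks(
    recording: MultichannelRecording,
    peaks: RPeakSeries,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
) -> EpochSet:
    """Cut one epoch per R-peak; flag boundary-truncated peaks.

    Epochs that would extend past either end of the recording are kept
    in the bookkeeping with flag ``boundary`` but carry zeroed data.
    Time 0 of each epoch is exactly the R-peak sample; no baseline
    subtraction is applied.
    """
    fs = recording.sample_rate
    if abs(peaks.sample_rate - fs) > 1e-9:
        raise ValueError("peak series and recording sample rates differ")
    lo = int(round(window_ms[0] * fs / 1000.0))
    hi = int(round(window_ms[1] * fs / 1000.0))
    n_t = hi - lo + 1
    times_ms = (np.arange(lo, hi + 1)) * 1000.0 / fs

    n_ep = len(peaks)
    data = np.zeros((n_ep, recording.n_channels, n_t))
    ecg = np.zeros((n_ep, n_t))
    flags = np.full(n_ep, KEPT, dtype=object)
    for i, p in enumerate(peaks.peak_samples):
        start, stop = p + lo, p + hi + 1
        if start < 0 or stop > recording.n_samples:
            flags[i] = FLAG_BOUNDARY
            continue
        data[i] = recording.eeg[:, start:stop]
        ecg[i] = recording.ecg[start:stop]
    flags = flags.astype("U12")
    if not np.any(flags == KEPT):
        raise ValueError("no epoch lies fully inside the recording")
    return EpochSet(
        data, ecg, times_ms, peaks.peak_samples.copy(), flags,
        recording.channel_labels, fs,
    )


def reject_epochs(
    epochs: EpochSet,
    peaks: RPeakSeries,
    amplitude_limit_uv: float = AMPLITUDE_LIMIT_UV,
    multi_peak_window_ms: tuple[float, float] = (0.0, 700.0),
) -> EpochSet:
    """Apply the amplitude and second-R-peak rejection rules.

    An epoch is flagged ``amplitude`` when any EEG sample exceeds the
    limit in absolute value (strictly greater than 75 μV by default),
    and ``multi_rpeak`` when another detected R-peak falls within
    (0, 700] ms after the epoch's reference peak.  Earlier flags
    (``boundary``) are preserved; the two rules are independent of
    application order, with the amplitude flag taking precedence in
    the recorded reason when both apply.
    """
    fs = epochs.sample_rate
    lo_ms, hi_ms = multi_peak_window_ms
    all_peaks = peaks.peak_samples
    flags = epochs.flags.copy()
    for i in range(epochs.n_epochs):
        if flags[i] == FLAG_BOUNDARY:
            continue
        ref = epochs.peak_samples[i]
        offsets_ms = (all_peaks - ref) * 1000.0 / fs
        multi = np.any((offsets_ms > lo_ms) & (offsets_ms <= hi_ms))
        over = np.any(np.abs(epochs.data[i]) > amplitude_limit_uv)
        if over:
            flags[i] = FLAG_AMPLITUDE
        elif multi:
            flags[i] = FLAG_MULTI_RPEAK
        else:
            flags[i] = KEPT
    return EpochSet(
        epochs.data, epochs.ecg, epochs.times_ms, epochs.peak_samples,
        flags, epochs.channel_labels, epochs.sample_rate,
    )


@dataclass(frozen=True)
class InclusionDecision:
    """Per-condition subject inclusion verdict with its inputs."""

    included: bool
    n_original: int
    n_rejected: int
    n_kept: int
    rejected_fraction: float
    reason: str


def subject_inclusion(
    n_original: int,
    n_rejected: int,
    max_rejected_fraction: float = 0.25,
    min_kept: int = 100,
) -> InclusionDecision:
    """Include iff rejected/original ≤ 25 % and kept epochs exceed 100.

    Both thresholds are strict as printed: a rejection proportion
    *exceeding* 0.25 excludes, and kept epochs must *exceed* 100
    (exactly 100 is excluded).
    """
    if n_original <= 0:
        raise ValueError("n_original must be positive")
    if not 0 <= n_rejected <= n_original:
        raise ValueError("n_rejected out of range")
    n_kept = n_original - n_rejected
    frac = n_rejected / n_original
    if frac > max_rejected_fraction:
        return InclusionDecision(
            False, n_original, n_rejected, n_kept, frac,
            f"rejected fraction {frac:.3f} exceeds {max_rejected_fraction}",
        )
    if n_kept <= min_kept:
        return InclusionDecision(
            False, n_original, n_rejected, n_kept, frac,
            f"kept epochs {n_kept} do not exceed {min_kept}",
        )
    return InclusionDecision(True, n_original, n_rejected, n_kept, frac, "included")


def average_evoked(
    epochs: EpochSet, modality: str = "HEP", condition: str = ""
) -> EvokedWaveform:
    """Arithmetic mean of kept epochs (EEG for HEP, ECG for mECG)."""
    kept = epochs.kept_mask
    n = int(kept.sum())
    if n == 0:
        raise ValueError("no kept epochs to average")
    if modality == "HEP":
        data = epochs.data[kept].mean(axis=0)
        labels = epochs.channel_labels
    elif modality == "mECG":
        data = epochs.ecg[kept].mean(axis=0)[None, :]
        labels = ("ECG",)
    else:
        raise ValueError("modality must be 'HEP' or 'mECG'")
    return EvokedWaveform(data, epochs.times_ms.copy(), n, condition, modality, labels)


def window_mean(
    evoked: EvokedWaveform,
    window_ms: tuple[float, float] = DEFAULT_TOI_MS,
    channels=None,
    pooled: bool = True,
):
    """Mean amplitude over a time window, endpoints inclusive.

    With ``channels`` given, restrict to that subset first; ``pooled``
    returns a single scalar (mean over channels and samples), else a
    per-channel vector.
    """
    lo, hi = window_ms
    mask = (evoked.times_ms >= lo - 1e-9) & (evoked.times_ms <= hi + 1e-9)
    if not np.any(mask):
        raise ValueError(f"window {window_ms} ms selects no samples")
    data = evoked.data
    if channels is not None:
        idx = [evoked.channel_labels.index(c) for c in channels]
        data = data[idx]
    sel = data[:, mask]
    return float(sel.mean()) if pooled else sel.mean(axis=1)
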