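"""Core container for a synchronized EEG + ECG recording."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MultichannelRecording:
    """Synchronized multichannel EEG matrix plus a single ECG trace.

    Attributes
    ----------
    eeg
        ``(n_channels, n_samples)`` scalp potentials in microvolts.
    ecg
        ``(n_samples,)`` ECG trace in microvolts (ECG-lead scale).
    sample_rate
        Sampling rate in Hz (200 Hz for study-shaped data).
    channel_labels
        EEG channel labels, row order of ``eeg``.
    true_r_peaks
        Optional ground-truth R-peak sample indices (set by the
        synthetic generator; absent for real recordings).
    reference
        Name of the current EEG reference scheme.
    """

    eeg: np.ndarray
    ecg: np.ndarray
    sample_rate: float
    channel_labels: tuple[str, ...]
    true_r_peaks: np.ndarray | None = None
    reference: str = "recording"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.eeg.ndim != 2:
            raise ValueError("eeg must be channels x samples")
        if self.eeg.shape[0] != len(self.channel_labels):
            raise ValueError("eeg row count must match channel_labels")
        if self.ecg.shape != (self.eeg.shape[1],):
            raise ValueError("ecg length must match eeg sample count")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not (np.all(np.isfinite(self.eeg)) and np.all(np.isfinite(self.ecg))):
            raise ValueError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.eeg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def copy_with(self, **updates) -> "MultichannelRecording":
        kwargs = dict(
            eeg=self.eeg,
            ecg=self.ecg,
            sample_rate=self.sample_rate,
            channel_labels=self.channel_labels,
            true_r_peaks=self.true_r_peaks,
            reference=self.reference,
            meta=dict(self.meta),
        )
        kwargs.update(updates)
        return MultichannelRecording(**kwargs)
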