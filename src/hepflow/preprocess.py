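"""EEG preprocessing: filtering, bad channels, interpolation, reference.

Matches an automated clinical-EEG cleaning chain: 50 Hz notch plus
0.16–30 Hz band-pass, correlation- and line-noise-based bad-channel
flagging, spherical-spline interpolation of flagged channels, and
average re-referencing.  Component-based artifact removal (ICA) is
deliberately outside this module; ``filter_eeg``'s output is a plain
recording, so an external cleaning step can be inserted before
interpolation if desired.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import legendre
from scipy import signal

from .montage import MontageLayout
from .recording import MultichannelRecording

__all__ = [
    "filter_eeg",
    "detect_bad_channels",
    "interpolate_channels",
    "rereference_average",
    "spline_matrix",
]


def _filter_matrix(
    data: np.ndarray,
    sample_rate: float,
    notch_hz: float | None,
    band_hz: tuple[float, float],
    order: int,
) -> np.ndarray:
    nyquist = sample_rate / 2.0
    low, high = band_hz
    if not 0.0 < low < high < nyquist:
        raise ValueError(f"band {band_hz} Hz invalid for Nyquist {nyquist} Hz")
    out = data
    if notch_hz is not None:
        if notch_hz >= nyquist:
            raise ValueError(f"notch {notch_hz} Hz at or above Nyquist")
        b, a = signal.iirnotch(notch_hz, Q=30.0, fs=sample_rate)
        out = signal.filtfilt(b, a, out, axis=-1)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=sample_rate,
                        output="sos")
    return signal.sosfiltfilt(sos, out, axis=-1)


def filter_eeg(
    recording: MultichannelRecording,
    notch_hz: float | None = 50.0,
    band_hz: tuple[float, float] = (0.16, 30.0),
    order: int = 2,
) -> MultichannelRecording:
    """Zero-phase 50 Hz notch followed by a 0.16–30 Hz band-pass.

    The high-pass corner at 0.16 Hz removes drift while keeping
    filter-induced distortion of slow evoked components small; the
    30 Hz low-pass removes muscle/line residue above the band where
    heartbeat-evoked activity lives.
    """
    if recording.sample_rate <= 100.0:
        raise ValueError("sample_rate must exceed 100 Hz")
    filtered = _filter_matrix(
        recording.eeg, recording.sample_rate, notch_hz, band_hz, order
    )
    return recording.copy_with(eeg=filtered)


# ---------------------------------------------------------------------------
# spherical splines (Perrin-style)
# ---------------------------------------------------------------------------


def _g_function(cosang: np.ndarray, m: int, n_terms: int) -> np.ndarray:
    """Spline kernel g(cos) = sum_l (2l+1) / (l(l+1))^m P_l(cos) / 4pi."""
    ell = np.arange(1, n_terms + 1, dtype=float)
    coefs = np.zeros(n_terms + 1)
    coefs[1:] = (2.0 * ell + 1.0) / (ell * (ell + 1.0)) ** m
    return legendre.legval(np.clip(cosang, -1.0, 1.0), coefs) / (4.0 * np.pi)


def spline_matrix(
    source_pos: np.ndarray,
    target_pos: np.ndarray,
    m: int = 4,
    n_terms: int = 7,
    regularization: float = 1e-5,
) -> np.ndarray:
    """Linear operator mapping potentials at sources to targets.

    Fits a spherical spline (Legendre order ``m``, series truncated at
    ``n_terms``, ridge ``regularization`` on the kernel diagonal) to
    the source electrodes and evaluates it at the target positions.
    Constants are reproduced exactly: each row of the returned matrix
    sums to one.
    """
    src = np.asarray(source_pos, dtype=float)
    tgt = np.asarray(target_pos, dtype=float)
    k = src.shape[0]
    if k < 4:
        raise ValueError("spherical spline needs at least 4 source electrodes")

    g_ss = _g_function(src @ src.T, m, n_terms)
    g_ts = _g_function(tgt @ src.T, m, n_terms)

    # bordered system: [[G + lam I, 1], [1^T, 0]] [c; c0] = [v; 0]
    a = np.zeros((k + 1, k + 1))
    a[:k, :k] = g_ss + regularization * np.eye(k)
    a[:k, k] = 1.0
    a[k, :k] = 1.0
    inv = np.linalg.solve(a, np.eye(k + 1))
    # rows of mapping: v_t = c0 + g_ts @ c with [c; c0] = inv[:, :k] @ v
    mapping = g_ts @ inv[:k, :k] + inv[k, :k][None, :]
    return mapping


def interpolate_channels(
    recording: MultichannelRecording,
    montage: MontageLayout,
    bad_labels,
    m: int = 4,
    n_terms: int = 7,
    regularization: float = 1e-5,
) -> MultichannelRecording:
    """Replace bad channels by spherical-spline estimates from the rest.

    Good channels are untouched; an empty ``bad_labels`` returns the
    recording unchanged.
    """
    bad = [lb for lb in bad_labels]
    if not bad:
        return recording
    unknown = set(bad) - set(recording.channel_labels)
    if unknown:
        raise KeyError(f"bad labels not in recording: {sorted(unknown)}")
    labels = list(recording.channel_labels)
    bad_idx = np.array([labels.index(lb) for lb in bad])
    good_idx = np.array([i for i in range(len(labels)) if labels[i] not in set(bad)])
    if good_idx.size < 4:
        raise ValueError("need at least 4 good channels to interpolate")
    pos = montage.positions[montage.indices(labels)]
    mapping = spline_matrix(
        pos[good_idx], pos[bad_idx], m=m, n_terms=n_terms,
        regularization=regularization,
    )
    eeg = recording.eeg.copy()
    eeg[bad_idx] = mapping @ eeg[good_idx]
    return recording.copy_with(eeg=eeg)


# ---------------------------------------------------------------------------
# bad-channel detection
# ---------------------------------------------------------------------------


def detect_bad_channels(
    recording: MultichannelRecording,
    montage: MontageLayout,
    correlation_threshold: float = 0.80,
    window_s: float = 5.0,
    line_noise_z: float = 4.0,
    line_band_hz: tuple[float, float] = (45.0, 55.0),
) -> dict:
    """Flag channels by predictability and line-noise criteria.

    A channel is flagged when (a) the median over ~5 s windows of its
    correlation with a spherical-spline prediction from all other
    channels falls below ``correlation_threshold``, or (b) its
    45–55 Hz band power is more than ``line_noise_z`` population
    standard deviations above the across-channel mean.  Returns a
    report dict with the union under ``"bad"``.
    """
    eeg = recording.eeg
    n_ch, n_samp = eeg.shape
    if n_ch < 4:
        raise ValueError("need at least 4 channels")
    labels = list(recording.channel_labels)
    pos = montage.positions[montage.indices(labels)]

    # (a) leave-one-out spline prediction, windowed correlation
    win = max(2, int(round(window_s * recording.sample_rate)))
    n_win = max(1, n_samp // win)
    low_corr = []
    median_corr = {}
    for i in range(n_ch):
        others = np.array([j for j in range(n_ch) if j != i])
        mapping = spline_matrix(pos[others], pos[i:i + 1])
        predicted = (mapping @ eeg[others])[0]
        corrs = []
        for w in range(n_win):
            seg = slice(w * win, (w + 1) * win)
            a, b = eeg[i, seg], predicted[seg]
            sa, sb = a.std(), b.std()
            corrs.append(
                0.0 if sa == 0 or sb == 0
                else float(np.corrcoef(a, b)[0, 1])
            )
        median_corr[labels[i]] = float(np.median(corrs))
        if median_corr[labels[i]] < correlation_threshold:
            low_corr.append(labels[i])

    # (b) line-noise power z-score across the channel population
    freqs, psd = signal.welch(
        eeg, fs=recording.sample_rate, nperseg=min(n_samp, 1024), axis=-1
    )
    band = (freqs >= line_band_hz[0]) & (freqs <= line_band_hz[1])
    power = psd[:, band].mean(axis=1)
    mu, sd = power.mean(), power.std()
    zscores = np.zeros(n_ch) if sd == 0 else (power - mu) / sd
    line = [labels[i] for i in range(n_ch) if zscores[i] > line_noise_z]

    bad = sorted(set(low_corr) | set(line), key=labels.index)
    if len(bad) == n_ch:
        raise RuntimeError(
            "all channels flagged bad — recording unusable; "
            f"median correlations: {median_corr}"
        )
    return {
        "bad": bad,
        "low_correlation": low_corr,
        "line_noise": line,
        "median_correlation": median_corr,
        "line_noise_z": {labels[i]: float(zscores[i]) for i in range(n_ch)},
    }


def rereference_average(recording: MultichannelRecording) -> MultichannelRecording:
    """Subtract the instantaneous across-channel mean from every channel.

    Applied after interpolation so the reference is built from a full
    set of valid channels.  Idempotent.
    """
    eeg = recording.eeg - recording.eeg.mean(axis=0, keepdims=True)
    return recording.copy_with(eeg=eeg, reference="average")
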