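"""Readers and writers: recordings, manifests, tables, result bundles."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .epoching import EvokedWaveform
from .recording import MultichannelRecording

MANIFEST_NAME = "manifest.tsv"
MANIFEST_COLUMNS = ["subject_id", "group_age", "sex", "condition", "path", "seed"]


def save_recording_npz(
    recording: MultichannelRecording, out_dir, subject_id: str, condition: str
) -> Path:
    """Persist a recording as a compressed ``.npz`` matrix bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{subject_id}_{condition}.npz"
    np.savez_compressed(
        path,
        eeg=recording.eeg.astype(np.float32),
        ecg=recording.ecg.astype(np.float32),
        sample_rate=np.array([recording.sample_rate]),
        channel_labels=np.array(recording.channel_labels),
        true_r_peaks=(
            recording.true_r_peaks
            if recording.true_r_peaks is not None
            else np.array([], dtype=np.int64)
        ),
    )
    return path


def load_recording_npz(path) -> MultichannelRecording:
    with np.load(path, allow_pickle=False) as data:
        true_peaks = data["true_r_peaks"]
        return MultichannelRecording(
            eeg=data["eeg"].astype(float),
            ecg=data["ecg"].astype(float),
            sample_rate=float(data["sample_rate"][0]),
            channel_labels=tuple(str(c) for c in data["channel_labels"]),
            true_r_peaks=true_peaks if true_peaks.size else None,
        )


def save_epochs_npz(epochs, path) -> Path:
    """Persist an epoch tensor with a JSON sidecar.

    The ``.npz`` holds the EEG tensor (epochs × channels × time) and
    the identically epoched ECG; the ``.json`` sidecar documents the
    time axis, per-epoch flags, and provenance (source R-peak sample
    of every epoch).
    """
    path = Path(path)
    np.savez_compressed(
        path,
        data=epochs.data.astype(np.float32),
        ecg=epochs.ecg.astype(np.float32),
    )
    sidecar = {
        "times_ms": epochs.times_ms.tolist(),
        "flags": list(epochs.flags),
        "peak_samples": epochs.peak_samples.tolist(),
        "channel_labels": list(epochs.channel_labels),
        "sample_rate": epochs.sample_rate,
    }
    write_json(sidecar, path.with_suffix(".json"))
    return path


def load_epochs_npz(path):
    from .epoching import EpochSet

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as data:
        return EpochSet(
            data=data["data"].astype(float),
            ecg=data["ecg"].astype(float),
            times_ms=np.asarray(sidecar["times_ms"]),
            peak_samples=np.asarray(sidecar["peak_samples"], dtype=np.int64),
            flags=np.asarray(sidecar["flags"], dtype="U12"),
            channel_labels=tuple(sidecar["channel_labels"]),
            sample_rate=float(sidecar["sample_rate"]),
        )


def read_edf_recording(path, ecg_channel: str = "ECG") -> MultichannelRecording:
    """Read a 23-channel EEG + ECG recording from an EDF file.

    Requires ``mne``.  All channels except ``ecg_channel`` are treated
    as EEG; voltages are converted to microvolts.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF files requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    if ecg_channel not in labels:
        raise ValueError(f"ECG channel {ecg_channel!r} not found in {labels}")
    data = raw.get_data() * 1e6  # volts -> microvolts
    ecg_idx = labels.index(ecg_channel)
    eeg_idx = [i for i in range(len(labels)) if i != ecg_idx]
    return MultichannelRecording(
        eeg=data[eeg_idx],
        ecg=data[ecg_idx],
        sample_rate=float(raw.info["sfreq"]),
        channel_labels=tuple(labels[i] for i in eeg_idx),
    )


def write_manifest(manifest: pd.DataFrame, out_dir) -> Path:
    out_dir = Path(out_dir).resolve()
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / MANIFEST_NAME
    manifest = manifest.copy()
    # store paths relative to the manifest directory when possible
    def _relativize(p):
        if not p:
            return p
        try:
            return str(Path(p).resolve().relative_to(out_dir))
        except ValueError:
            return str(p)
    manifest["path"] = manifest["path"].map(_relativize)
    manifest.to_csv(path, sep="\t", index=False, columns=MANIFEST_COLUMNS)
    return path


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return manifest


def export_evoked_tsv(evoked: EvokedWaveform, path) -> Path:
    """Channel × time evoked waveform as TSV (first column = time ms)."""
    path = Path(path)
    frame = pd.DataFrame(
        evoked.data.T, columns=list(evoked.channel_labels)
    )
    frame.insert(0, "time_ms", evoked.times_ms)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def export_tmap_tsv(t_map: np.ndarray, times_ms, channel_labels, path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(np.asarray(t_map).T, columns=list(channel_labels))
    frame.insert(0, "time_ms", np.asarray(times_ms))
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


class _NumpyJSONEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(payload, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True, cls=_NumpyJSONEncoder)
        + "\n"
    )
    return path
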