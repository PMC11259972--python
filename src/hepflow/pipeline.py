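"""End-to-end study analysis: preprocess → epoch → test → report.

Sequences the full heartbeat-evoked-potential pipeline over a study
manifest: per subject-condition ECG conditioning and R-peak detection,
EEG cleaning (bad channels, spherical-spline interpolation, average
reference), R-peak-locked epoching with the rejection and inclusion
rules, evoked averaging (HEP and mECG), then spatio-temporal cluster
permutation tests for the paired condition contrast (total sample and
per age group) and the independent age and sex contrasts within each
condition, plus the nonparametric cardiac control table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cardiac, cluster, controls, epoching, preprocess
from .io import (
    export_tmap_tsv,
    load_recording_npz,
    read_manifest,
    write_json,
)
from .montage import MontageLayout, default_montage
from .recording import MultichannelRecording
from .synthetic import StudyData

CONTROL_MEASURES = ("mecg_toi", "hrv_pct", "rmssd_ms", "hr_bpm")


@dataclass
class PipelineConfig:
    """All tunable settings of the analysis chain."""

    epoch_window_ms: tuple[float, float] = (-100.0, 700.0)
    toi_ms: tuple[float, float] = (200.0, 650.0)
    amplitude_limit_uv: float = 75.0
    max_rejected_fraction: float = 0.25
    min_kept_epochs: int = 100
    eeg_notch_hz: float = 50.0
    eeg_band_hz: tuple[float, float] = (0.16, 30.0)
    ecg_band_hz: tuple[float, float] = (3.0, 30.0)
    correlation_threshold: float = 0.80
    line_noise_z: float = 4.0
    n_permutations: int = 1000
    forming_alpha: float = 0.05
    cluster_alpha: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        for alpha in (self.forming_alpha, self.cluster_alpha):
            if not 0.0 < alpha < 0.5:
                raise ValueError("alphas must lie in (0, 0.5)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be at least 100")
        lo, hi = self.epoch_window_ms
        if not lo < 0.0 < hi:
            raise ValueError("epoch window must bracket the R-peak")
        t0, t1 = self.toi_ms
        if not lo <= t0 < t1 <= hi:
            raise ValueError("TOI must lie inside the epoch window")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("epoch_window_ms", "toi_ms", "eeg_band_hz", "ecg_band_hz"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        for key, value in payload.items():
            if isinstance(value, tuple):
                payload[key] = list(value)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


@dataclass
class SubjectConditionResult:
    """Everything derived from one subject-condition recording."""

    subject_id: str
    condition: str
    inclusion: epoching.InclusionDecision
    hrv: cardiac.HRVSummary | None
    evoked_hep: epoching.EvokedWaveform | None
    evoked_mecg: epoching.EvokedWaveform | None
    report: dict = field(default_factory=dict)


class PipelineError(RuntimeError):
    """Structured stage failure naming the subject and stage."""

    def __init__(self, subject: str, stage: str, message: str):
        super().__init__(f"[{subject}/{stage}] {message}")
        self.subject = subject
        self.stage = stage


def preprocess_recording(
    recording: MultichannelRecording,
    montage: MontageLayout,
    config: PipelineConfig,
) -> tuple[MultichannelRecording, dict]:
    """Bad channels → filter → interpolate → average reference."""
    bad_report = preprocess.detect_bad_channels(
        recording,
        montage,
        correlation_threshold=config.correlation_threshold,
        line_noise_z=config.line_noise_z,
    )
    filtered = preprocess.filter_eeg(
        recording, notch_hz=config.eeg_notch_hz, band_hz=config.eeg_band_hz
    )
    interpolated = preprocess.interpolate_channels(
        filtered, montage, bad_report["bad"]
    )
    rereferenced = preprocess.rereference_average(interpolated)
    report = {
        "bad_channels": bad_report["bad"],
        "low_correlation": bad_report["low_correlation"],
        "line_noise": bad_report["line_noise"],
        "notch_hz": config.eeg_notch_hz,
        "band_hz": list(config.eeg_band_hz),
        "reference": "average",
    }
    return rereferenced, report


def analyze_subject_condition(
    recording: MultichannelRecording,
    montage: MontageLayout,
    config: PipelineConfig,
    subject_id: str = "",
    condition: str = "",
    already_preprocessed: bool = False,
) -> SubjectConditionResult:
    """Run the single-recording pipeline through evoked averaging.

    With ``already_preprocessed`` the EEG cleaning stage is skipped
    (the recording comes from a cached clean store).
    """
    ecg_filtered = cardiac.bandpass_ecg(
        recording.ecg, recording.sample_rate, *config.ecg_band_hz
    )
    peaks = cardiac.detect_r_peaks(ecg_filtered, recording.sample_rate)
    if len(peaks) < 3:
        raise PipelineError(subject_id, "r_peaks", "too few R-peaks detected")
    rr = cardiac.rr_from_peaks(peaks)
    try:
        hrv = cardiac.hrv_summary(rr)
    except cardiac.UndefinedStatisticError:
        hrv = None

    if already_preprocessed:
        clean, preprocess_report = recording, {"cached": True}
    else:
        clean, preprocess_report = preprocess_recording(recording, montage, config)
    epochs = epoching.epoch_around_rpeaks(clean, peaks, config.epoch_window_ms)
    epochs = epoching.reject_epochs(
        epochs, peaks, amplitude_limit_uv=config.amplitude_limit_uv
    )
    usable = epochs.flags != epoching.FLAG_BOUNDARY
    n_original = int(usable.sum())
    n_rejected = int(np.sum(usable & ~epochs.kept_mask))
    decision = epoching.subject_inclusion(
        n_original,
        n_rejected,
        max_rejected_fraction=config.max_rejected_fraction,
        min_kept=config.min_kept_epochs,
    )
    evoked_hep = evoked_mecg = None
    if epochs.n_kept > 0:
        evoked_hep = epoching.average_evoked(epochs, "HEP", condition)
        evoked_mecg = epoching.average_evoked(epochs, "mECG", condition)
    report = {
        "subject_id": subject_id,
        "condition": condition,
        "n_r_peaks": len(peaks),
        "n_epochs_original": n_original,
        "n_epochs_rejected": n_rejected,
        "n_epochs_kept": decision.n_kept,
        "rejected_fraction": decision.rejected_fraction,
        "included": decision.included,
        "inclusion_reason": decision.reason,
        "preprocess": preprocess_report,
    }
    return SubjectConditionResult(
        subject_id, condition, decision, hrv, evoked_hep, evoked_mecg, report
    )


def _load_study(study, montage):
    """Yield (subject_id, group, sex, condition, recording) tuples."""
    if isinstance(study, StudyData):
        for s in study.subjects:
            for condition, rec in s.recordings.items():
                if isinstance(rec, str):
                    rec = load_recording_npz(rec)
                yield s.subject_id, s.group_age, s.sex, condition, rec
    else:  # manifest path
        manifest = read_manifest(study)
        base = Path(study).parent
        for _, row in manifest.iterrows():
            path = Path(row["path"])
            if not path.is_absolute():
                path = base / path
            if not path.exists():
                raise PipelineError(
                    str(row["subject_id"]), "load", f"missing file {path}"
                )
            yield (
                str(row["subject_id"]),
                str(row["group_age"]),
                str(row["sex"]),
                str(row["condition"]),
                load_recording_npz(path),
            )


def _toi_mask(times_ms: np.ndarray, toi_ms) -> np.ndarray:
    lo, hi = toi_ms
    return (times_ms >= lo - 1e-9) & (times_ms <= hi + 1e-9)


def run_study_analysis(
    study,
    config: PipelineConfig | None = None,
    montage: MontageLayout | None = None,
) -> dict:
    """Analyze a full study; returns the results bundle.

    ``study`` is either an in-memory :class:`StudyData` or a path to a
    manifest TSV referencing ``.npz`` recordings.  The bundle contains
    the per-subject study table, evoked waveforms, cluster test
    results for every design, the cardiac control table, and the
    inclusion log.  Deterministic given ``config.seed``.
    """
    config = config or PipelineConfig()
    montage = montage or default_montage()
    adjacency = cluster.build_adjacency(montage)

    per_subject: dict[tuple[str, str], SubjectConditionResult] = {}
    meta: dict[str, dict] = {}
    inclusion_log = []
    for subject_id, group, sex, condition, rec in _load_study(study, montage):
        result = analyze_subject_condition(
            rec, montage, config, subject_id, condition
        )
        per_subject[(subject_id, condition)] = result
        meta[subject_id] = {"group_age": group, "sex": sex}
        inclusion_log.append(result.report)

    rows = []
    for (subject_id, condition), res in sorted(per_subject.items()):
        toi_mean = (
            epoching.window_mean(res.evoked_mecg, config.toi_ms)
            if res.evoked_mecg is not None
            else np.nan
        )
        rows.append(
            {
                "subject_id": subject_id,
                "condition": condition,
                "group_age": meta[subject_id]["group_age"],
                "sex": meta[subject_id]["sex"],
                "included": res.inclusion.included,
                "n_epochs_kept": res.inclusion.n_kept,
                "hr_bpm": res.hrv.hr_bpm if res.hrv else np.nan,
                "rmssd_ms": res.hrv.rmssd_ms if res.hrv else np.nan,
                "hrv_pct": res.hrv.hrv_geometric_pct if res.hrv else np.nan,
                "mecg_toi": toi_mean,
            }
        )
    study_table = pd.DataFrame(rows)

    # subjects included in both conditions enter the paired analyses
    included = {
        sid
        for sid in meta
        if all(
            (sid, c) in per_subject and per_subject[(sid, c)].inclusion.included
            for c in ("pre", "post")
        )
    }
    subjects_in = sorted(included)

    def _evoked_stack(sids, condition):
        maps = []
        for sid in sids:
            ev = per_subject[(sid, condition)].evoked_hep
            mask = _toi_mask(ev.times_ms, config.toi_ms)
            maps.append(ev.data[:, mask])
        return np.array(maps)

    toi_times = None
    if subjects_in:
        ev0 = per_subject[(subjects_in[0], "pre")].evoked_hep
        toi_times = ev0.times_ms[_toi_mask(ev0.times_ms, config.toi_ms)]

    seed_root = np.random.SeedSequence(config.seed)
    design_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ["paired_total", "paired_young", "paired_elderly",
             "age_pre", "age_post", "sex_pre", "sex_post"],
            seed_root.spawn(7),
        )
    }

    cluster_results = {}

    def _run_paired(name, sids):
        if len(sids) < 2:
            return
        diffs = _evoked_stack(sids, "pre") - _evoked_stack(sids, "post")
        res = cluster.cluster_permutation_test(
            diffs,
            adjacency,
            design="paired",
            n_permutations=config.n_permutations,
            forming_alpha=config.forming_alpha,
            cluster_alpha=config.cluster_alpha,
            seed=design_seeds[name],
        )
        cluster_results[name] = {
            "result": res,
            "summary": cluster.cluster_summary(
                res, diffs, "paired", toi_times, montage.labels
            ),
            "n": len(sids),
            "subjects": list(sids),
        }

    def _run_independent(name, sids_a, sids_b, condition):
        if len(sids_a) < 2 or len(sids_b) < 2:
            return
        a = _evoked_stack(sids_a, condition)
        b = _evoked_stack(sids_b, condition)
        res = cluster.cluster_permutation_test(
            (a, b),
            adjacency,
            design="independent",
            n_permutations=config.n_permutations,
            forming_alpha=config.forming_alpha,
            cluster_alpha=config.cluster_alpha,
            seed=design_seeds[name],
        )
        cluster_results[name] = {
            "result": res,
            "summary": cluster.cluster_summary(
                res, (a, b), "independent", toi_times, montage.labels
            ),
            "n": (len(sids_a), len(sids_b)),
            "subjects": list(sids_a) + list(sids_b),
        }

    young = [s for s in subjects_in if meta[s]["group_age"] == "young"]
    elderly = [s for s in subjects_in if meta[s]["group_age"] == "elderly"]
    female = [s for s in subjects_in if meta[s]["sex"] == "F"]
    male = [s for s in subjects_in if meta[s]["sex"] == "M"]

    _run_paired("paired_total", subjects_in)
    _run_paired("paired_young", young)
    _run_paired("paired_elderly", elderly)
    for condition in ("pre", "post"):
        _run_independent(f"age_{condition}", young, elderly, condition)
        _run_independent(f"sex_{condition}", male, female, condition)

    # cardiac-confound follow-up: for each significant paired cluster,
    # compare mECG averaged over the cluster's time window across
    # conditions — a genuine evoked effect should not be mirrored there
    for name, entry in cluster_results.items():
        if not name.startswith("paired"):
            continue
        followups = []
        for summary in entry["summary"]:
            if not summary["significant"]:
                continue
            window = summary["time_span_ms"]
            sids = entry["subjects"]
            pre_means = np.array([
                epoching.window_mean(per_subject[(s, "pre")].evoked_mecg, window)
                for s in sids
            ])
            post_means = np.array([
                epoching.window_mean(per_subject[(s, "post")].evoked_mecg, window)
                for s in sids
            ])
            res = controls.wilcoxon_signed_rank(pre_means, post_means,
                                                method="approx")
            followups.append(
                {
                    "window_ms": window,
                    "Z": res.z,
                    "p": res.p_value,
                    "r": res.r,
                    "median_pre": res.median_pre,
                    "iqr_pre": res.iqr_pre,
                    "median_post": res.median_post,
                    "iqr_post": res.iqr_post,
                }
            )
        entry["mecg_followup"] = followups

    control_table = build_control_table(study_table, subjects_in, meta)

    return {
        "study_table": study_table,
        "per_subject": per_subject,
        "included_subjects": subjects_in,
        "cluster_results": cluster_results,
        "control_table": control_table,
        "inclusion_log": inclusion_log,
        "toi_times_ms": toi_times,
        "config": dataclasses.asdict(config),
        "montage_labels": montage.labels,
    }


def build_control_table(
    study_table: pd.DataFrame, subjects_in, meta
) -> pd.DataFrame:
    """Table-1-style Wilcoxon rows: measure × group, pre vs post."""
    rows = []
    groups = {
        "Total": list(subjects_in),
        "Young": [s for s in subjects_in if meta[s]["group_age"] == "young"],
        "Elderly": [s for s in subjects_in if meta[s]["group_age"] == "elderly"],
    }
    indexed = study_table.set_index(["subject_id", "condition"])
    for measure in CONTROL_MEASURES:
        for group_name, sids in groups.items():
            if len(sids) < 5:
                continue
            pre = np.array([indexed.loc[(s, "pre"), measure] for s in sids])
            post = np.array([indexed.loc[(s, "post"), measure] for s in sids])
            if np.any(~np.isfinite(pre)) or np.any(~np.isfinite(post)):
                continue
            res = controls.wilcoxon_signed_rank(pre, post, method="approx")
            rows.append(
                {
                    "measure": measure,
                    "group": group_name,
                    "n": res.n_pairs,
                    "median_pre": res.median_pre,
                    "iqr_pre": f"{res.iqr_pre[0]:.3g} to {res.iqr_pre[1]:.3g}",
                    "median_post": res.median_post,
                    "iqr_post": f"{res.iqr_post[0]:.3g} to {res.iqr_post[1]:.3g}",
                    "Z": res.z,
                    "r": res.r,
                    "p": res.p_value,
                    "significant": res.p_value < 0.05,
                }
            )
    columns = [
        "measure", "group", "n", "median_pre", "iqr_pre", "median_post",
        "iqr_post", "Z", "r", "p", "significant",
    ]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def report_results(bundle: dict, out_dir) -> Path:
    """Render the bundle as Markdown + TSV + JSON artifacts.

    Regeneration over the same bundle is idempotent (deterministic
    content, fixed file set).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    bundle["study_table"].to_csv(
        out_dir / "study_table.tsv", sep="\t", index=False, float_format="%.6g"
    )
    bundle["control_table"].to_csv(
        out_dir / "control_table.tsv", sep="\t", index=False, float_format="%.6g"
    )
    pd.DataFrame(
        [
            {k: v for k, v in entry.items() if k != "preprocess"}
            for entry in bundle["inclusion_log"]
        ]
    ).to_csv(out_dir / "inclusion_log.tsv", sep="\t", index=False)

    cluster_json = {}
    for name, entry in bundle["cluster_results"].items():
        res = entry["result"]
        cluster_json[name] = {
            "n": entry["n"],
            "df": res.df,
            "threshold_t": res.threshold,
            "n_permutations": res.n_permutations,
            "exhaustive": res.exhaustive,
            "config": res.config,
            "clusters": [
                {k: v for k, v in summary.items() if k != "subject_amplitudes"}
                for summary in entry["summary"]
            ],
        }
        if bundle["toi_times_ms"] is not None:
            export_tmap_tsv(
                res.t_map,
                bundle["toi_times_ms"],
                bundle["montage_labels"],
                out_dir / f"tmap_{name}.tsv",
            )
    write_json(
        {"clusters": cluster_json, "config": bundle["config"]},
        out_dir / "cluster_results.json",
    )

    lines = ["# Heartbeat-evoked potential study report", ""]
    lines.append(
        f"Included subjects (both conditions): {len(bundle['included_subjects'])}"
    )
    lines.append("")
    lines.append("## Cluster permutation tests")
    lines.append("")
    any_cluster = False
    header = (
        "| design | n | cluster | window (ms) | electrodes | mass | p | t | d |"
    )
    for name, entry in bundle["cluster_results"].items():
        significant = [s for s in entry["summary"] if s["significant"]]
        if not significant:
            continue
        if not any_cluster:
            lines.append(header)
            lines.append("|" + "---|" * 9)
            any_cluster = True
        for i, s in enumerate(significant):
            window = f"{s['time_span_ms'][0]:.0f}-{s['time_span_ms'][1]:.0f}"
            electrodes = " ".join(map(str, s["channels"]))
            lines.append(
                f"| {name} | {entry['n']} | {i + 1} | {window} | {electrodes} "
                f"| {s['mass']:.2f} | {s['p_mc']:.4g} | {s['t']:.2f} "
                f"| {s['d']:.2f} |"
            )
    if not any_cluster:
        lines.append("No significant clusters in any design.")
    lines.append("")
    lines.append("## Cardiac control statistics (Wilcoxon signed-rank)")
    lines.append("")
    control = bundle["control_table"]
    if len(control):
        lines.append("| measure | group | n | Mdn pre (IQR) | Mdn post (IQR) "
                     "| Z | r | p |")
        lines.append("|" + "---|" * 8)
        for _, row in control.iterrows():
            lines.append(
                f"| {row['measure']} | {row['group']} | {row['n']} "
                f"| {row['median_pre']:.3g} ({row['iqr_pre']}) "
                f"| {row['median_post']:.3g} ({row['iqr_post']}) "
                f"| {row['Z']:.2f} | {row['r']:.2g} | {row['p']:.3g} |"
            )
    else:
        lines.append("Too few included subjects for control statistics.")
    lines.append("")
    report_path = out_dir / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path
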