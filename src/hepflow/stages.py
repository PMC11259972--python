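"""Cacheable pipeline stages over a working directory.

Each stage writes its artifacts under a workdir and is resumable: a
later stage loads the previous stage's store if present and triggers
it otherwise.  Layout::

    workdir/
      clean/            preprocessed recordings (.npz) + clean manifest
      evoked/           per subject-condition evoked waveforms (.npz)
      study_table.tsv   per subject-condition cardiac metrics + inclusion
      inclusion_log.tsv
      cluster_results.json, tmap_*.tsv
      control_table.tsv
      report.md
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster, epoching, pipeline
from .io import (
    load_recording_npz,
    read_manifest,
    save_recording_npz,
    write_json,
    write_manifest,
)
from .montage import default_montage
from .pipeline import PipelineConfig, PipelineError

CLEAN_DIR = "clean"
EVOKED_DIR = "evoked"


def _iter_manifest(manifest_path):
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    for _, row in manifest.iterrows():
        path = Path(row["path"])
        if not path.is_absolute():
            path = base / path
        yield row, path


def stage_preprocess(manifest_path, workdir, config: PipelineConfig) -> Path:
    """Clean every recording in the manifest into ``workdir/clean``."""
    workdir = Path(workdir)
    clean_dir = workdir / CLEAN_DIR
    montage = default_montage()
    rows = []
    reports = {}
    for row, path in _iter_manifest(manifest_path):
        recording = load_recording_npz(path)
        clean, report = pipeline.preprocess_recording(recording, montage, config)
        out = save_recording_npz(
            clean, clean_dir, str(row["subject_id"]), str(row["condition"])
        )
        reports[f"{row['subject_id']}_{row['condition']}"] = report
        new_row = row.to_dict()
        new_row["path"] = str(out.relative_to(clean_dir))
        rows.append(new_row)
    write_manifest(pd.DataFrame(rows), clean_dir)
    write_json(reports, workdir / "preprocess_reports.json")
    return clean_dir / "manifest.tsv"


def stage_epoch(manifest_path, workdir, config: PipelineConfig) -> Path:
    """Epoch + evoked-average every recording; fills ``workdir/evoked``."""
    workdir = Path(workdir)
    clean_manifest = workdir / CLEAN_DIR / "manifest.tsv"
    if not clean_manifest.exists():
        clean_manifest = stage_preprocess(manifest_path, workdir, config)
    evoked_dir = workdir / EVOKED_DIR
    evoked_dir.mkdir(parents=True, exist_ok=True)
    montage = default_montage()
    rows = []
    log = []
    for row, path in _iter_manifest(clean_manifest):
        recording = load_recording_npz(path)
        res = pipeline.analyze_subject_condition(
            recording,
            montage,
            config,
            subject_id=str(row["subject_id"]),
            condition=str(row["condition"]),
            already_preprocessed=True,
        )
        key = f"{row['subject_id']}_{row['condition']}"
        if res.evoked_hep is not None:
            np.savez_compressed(
                evoked_dir / f"{key}.npz",
                hep=res.evoked_hep.data,
                mecg=res.evoked_mecg.data[0],
                times_ms=res.evoked_hep.times_ms,
                n_epochs=np.array([res.evoked_hep.n_epochs]),
            )
        toi_mean = (
            epoching.window_mean(res.evoked_mecg, config.toi_ms)
            if res.evoked_mecg is not None
            else np.nan
        )
        rows.append(
            {
                "subject_id": str(row["subject_id"]),
                "condition": str(row["condition"]),
                "group_age": str(row["group_age"]),
                "sex": str(row["sex"]),
                "included": res.inclusion.included,
                "n_epochs_kept": res.inclusion.n_kept,
                "hr_bpm": res.hrv.hr_bpm if res.hrv else np.nan,
                "rmssd_ms": res.hrv.rmssd_ms if res.hrv else np.nan,
                "hrv_pct": res.hrv.hrv_geometric_pct if res.hrv else np.nan,
                "mecg_toi": toi_mean,
            }
        )
        log.append({k: v for k, v in res.report.items() if k != "preprocess"})
    table = pd.DataFrame(rows)
    table.to_csv(workdir / "study_table.tsv", sep="\t", index=False,
                 float_format="%.8g")
    pd.DataFrame(log).to_csv(
        workdir / "inclusion_log.tsv", sep="\t", index=False
    )
    return workdir / "study_table.tsv"


def _load_epoch_store(workdir, config):
    workdir = Path(workdir)
    table_path = workdir / "study_table.tsv"
    if not table_path.exists():
        raise PipelineError("-", "cluster", "run the epoch stage first")
    table = pd.read_csv(table_path, sep="\t", dtype={"subject_id": str})
    evoked = {}
    for _, row in table.iterrows():
        key = f"{row['subject_id']}_{row['condition']}"
        path = workdir / EVOKED_DIR / f"{key}.npz"
        if path.exists():
            with np.load(path) as data:
                evoked[(row["subject_id"], row["condition"])] = {
                    "hep": data["hep"],
                    "mecg": data["mecg"],
                    "times_ms": data["times_ms"],
                }
    return table, evoked


def stage_cluster(workdir, config: PipelineConfig) -> Path:
    """Run all cluster permutation designs from the evoked store."""
    workdir = Path(workdir)
    table, evoked = _load_epoch_store(workdir, config)
    montage = default_montage()
    adjacency = cluster.build_adjacency(montage)

    meta = {
        row["subject_id"]: {"group_age": row["group_age"], "sex": row["sex"]}
        for _, row in table.iterrows()
    }
    flags = table.set_index(["subject_id", "condition"])["included"]
    subjects = sorted(
        {
            sid
            for sid in meta
            if all(
                (sid, c) in evoked and bool(flags.get((sid, c), False))
                for c in ("pre", "post")
            )
        }
    )
    if len(subjects) < 2:
        raise PipelineError("-", "cluster", "fewer than 2 included subjects")

    times = evoked[(subjects[0], "pre")]["times_ms"]
    mask = pipeline._toi_mask(times, config.toi_ms)
    toi_times = times[mask]

    def stack(sids, condition):
        return np.array([evoked[(s, condition)]["hep"][:, mask] for s in sids])

    seed_root = np.random.SeedSequence(config.seed)
    names = ["paired_total", "paired_young", "paired_elderly",
             "age_pre", "age_post", "sex_pre", "sex_post"]
    seeds = {
        n: int(c.generate_state(1)[0] % (2**31))
        for n, c in zip(names, seed_root.spawn(len(names)))
    }

    young = [s for s in subjects if meta[s]["group_age"] == "young"]
    elderly = [s for s in subjects if meta[s]["group_age"] == "elderly"]
    male = [s for s in subjects if meta[s]["sex"] == "M"]
    female = [s for s in subjects if meta[s]["sex"] == "F"]

    payload = {}
    for name, spec in {
        "paired_total": ("paired", subjects, None, None),
        "paired_young": ("paired", young, None, None),
        "paired_elderly": ("paired", elderly, None, None),
        "age_pre": ("independent", young, elderly, "pre"),
        "age_post": ("independent", young, elderly, "post"),
        "sex_pre": ("independent", male, female, "pre"),
        "sex_post": ("independent", male, female, "post"),
    }.items():
        design, a, b, condition = spec
        if design == "paired":
            if len(a) < 2:
                continue
            data = stack(a, "pre") - stack(a, "post")
            n = len(a)
        else:
            if len(a) < 2 or len(b) < 2:
                continue
            data = (stack(a, condition), stack(b, condition))
            n = (len(a), len(b))
        res = cluster.cluster_permutation_test(
            data,
            adjacency,
            design=design,
            n_permutations=config.n_permutations,
            forming_alpha=config.forming_alpha,
            cluster_alpha=config.cluster_alpha,
            seed=seeds[name],
        )
        summary = cluster.cluster_summary(
            res, data, design, toi_times, montage.labels
        )
        payload[name] = {
            "n": n,
            "df": res.df,
            "threshold_t": res.threshold,
            "n_permutations": res.n_permutations,
            "exhaustive": res.exhaustive,
            "clusters": [
                {k: v for k, v in s.items() if k != "subject_amplitudes"}
                for s in summary
            ],
        }
    out = write_json(
        {"clusters": payload, "seed": config.seed},
        workdir / "cluster_results.json",
    )
    return out


def stage_controls(workdir, config: PipelineConfig) -> Path:
    """Cardiac control table from the epoch-stage study table."""
    workdir = Path(workdir)
    table_path = workdir / "study_table.tsv"
    if not table_path.exists():
        raise PipelineError("-", "controls", "run the epoch stage first")
    table = pd.read_csv(table_path, sep="\t", dtype={"subject_id": str})
    meta = {
        row["subject_id"]: {"group_age": row["group_age"], "sex": row["sex"]}
        for _, row in table.iterrows()
    }
    flags = table.set_index(["subject_id", "condition"])["included"]
    subjects = sorted(
        {
            sid
            for sid in meta
            if all(bool(flags.get((sid, c), False)) for c in ("pre", "post"))
        }
    )
    control = pipeline.build_control_table(table, subjects, meta)
    control.to_csv(workdir / "control_table.tsv", sep="\t", index=False,
                   float_format="%.6g")
    return workdir / "control_table.tsv"


def stage_report(workdir) -> Path:
    """Assemble the Markdown report from stored stage artifacts."""
    workdir = Path(workdir)
    lines = ["# Heartbeat-evoked potential study report", ""]
    cluster_path = workdir / "cluster_results.json"
    lines.append("## Cluster permutation tests")
    lines.append("")
    any_sig = False
    if cluster_path.exists():
        payload = json.loads(cluster_path.read_text())
        for name, entry in payload["clusters"].items():
            for s in entry["clusters"]:
                if not s["significant"]:
                    continue
                if not any_sig:
                    lines.append("| design | n | window (ms) | electrodes "
                                 "| mass | p | t | d |")
                    lines.append("|" + "---|" * 8)
                    any_sig = True
                window = (f"{s['time_span_ms'][0]:.0f}-"
                          f"{s['time_span_ms'][1]:.0f}")
                lines.append(
                    f"| {name} | {entry['n']} | {window} "
                    f"| {' '.join(map(str, s['channels']))} | {s['mass']:.2f} "
                    f"| {s['p_mc']:.4g} | {s['t']:.2f} | {s['d']:.2f} |"
                )
    if not any_sig:
        lines.append("No significant clusters in any design.")
    lines.append("")
    control_path = workdir / "control_table.tsv"
    lines.append("## Cardiac control statistics")
    lines.append("")
    if control_path.exists():
        control = pd.read_csv(control_path, sep="\t")
        if len(control):
            lines.append(control.to_markdown(index=False))
        else:
            lines.append("Too few included subjects for control statistics.")
    else:
        lines.append("Control table not computed.")
    lines.append("")
    out = workdir / "report.md"
    out.write_text("\n".join(lines))
    return out


def run_all(manifest_path, workdir, config: PipelineConfig) -> Path:
    """simulate-independent full chain: preprocess → ... → report."""
    stage_epoch(manifest_path, workdir, config)
    stage_cluster(workdir, config)
    stage_controls(workdir, config)
    return stage_report(workdir)
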