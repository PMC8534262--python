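"""Reading and writing of recordings, cohorts, feature tables and reports.

Recordings travel as EDF (read via MNE) or CSV (first column = time in
seconds, one column per channel, header row of 10/20 labels, values in
microvolts).  A cohort on disk is one recording file per subject plus a
manifest CSV (subject_id, group, path) and a ground-truth JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import LABEL_COLUMN, BenchmarkReport
from .containers import Recording
from .synthdata import GroundTruth


def write_recording_csv(rec: Recording, path) -> Path:
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame(rec.data.T, columns=rec.channel_names)
    df.insert(0, "time", t)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def read_recording_csv(path, subject_id: str = "", group: str = "") -> Recording:
    df = pd.read_csv(path)
    if df.columns[0].lower() != "time":
        raise ValueError("first CSV column must be 'time' (seconds)")
    t = df.iloc[:, 0].values
    if len(t) < 2:
        raise ValueError("recording too short")
    fs = 1.0 / float(np.median(np.diff(t)))
    return Recording(
        channel_names=list(df.columns[1:]),
        fs=fs,
        data=df.iloc[:, 1:].values.T,
        subject_id=subject_id or Path(path).stem,
        group=group,
    )


def read_recording_edf(path, subject_id: str = "", group: str = "") -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        channel_names=list(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        data=raw.get_data() * 1e6,  # volts -> microvolts
        subject_id=subject_id or Path(path).stem,
        group=group,
    )


def read_recording(path, subject_id: str = "", group: str = "") -> Recording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_recording_edf(path, subject_id, group)
    return read_recording_csv(path, subject_id, group)


def write_cohort(
    recordings: list[Recording], truth: GroundTruth, outdir
) -> Path:
    """One CSV per subject, a manifest CSV, and the ground truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}.csv"
        write_recording_csv(rec, outdir / fname)
        rows.append({"subject_id": rec.subject_id, "group": rec.group, "path": fname})
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    (outdir / "ground_truth.json").write_text(truth.to_json())
    return outdir


def read_cohort(indir) -> tuple[list[Recording], GroundTruth | None]:
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    recs = [
        read_recording(indir / row["path"], row["subject_id"], row["group"])
        for _, row in manifest.iterrows()
    ]
    truth_path = indir / "ground_truth.json"
    truth = GroundTruth.from_json(truth_path.read_text()) if truth_path.exists() else None
    return recs, truth


def write_feature_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, index_label="subject_id")
    return path


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject_id")
    if LABEL_COLUMN not in df.columns:
        raise ValueError(f"feature table lacks a '{LABEL_COLUMN}' column")
    return df


def write_benchmark(report: BenchmarkReport, outdir) -> Path:
    """Metrics table as CSV, full report (params, audit, features) as JSON,
    plus per-model ROC points as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.to_frame().to_csv(outdir / "metrics.csv")
    blob = {
        "mode": report.mode,
        "train_ids": report.train_ids,
        "test_ids": report.test_ids,
        "selected_features": report.selected_features,
        "feature_scores": report.feature_scores,
        "audit": report.audit,
        "models": [
            {
                "kind": r.kind,
                "name": r.name,
                "params": r.params,
                "cv_f1": r.cv_f1,
                "metrics": dataclasses.asdict(r.test.metrics),
                "confusion": r.test.confusion.tolist(),
                "classes": r.test.classes,
                "auc": r.test.auc,
            }
            for r in report.results
        ],
    }
    (outdir / "report.json").write_text(json.dumps(blob, indent=1, default=float))
    roc_rows = []
    for r in report.results:
        if r.test.roc is not None:
            fpr, tpr = r.test.roc
            roc_rows += [
                {"model": r.name, "fpr": f, "tpr": t} for f, t in zip(fpr, tpr)
            ]
    if roc_rows:
        pd.DataFrame(roc_rows).to_csv(outdir / "roc.csv", index=False)
    return outdir
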