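"""Plain-text input/output: cohort bundles, feature tables and grid results.

A cohort bundle is a directory with one CSV matrix (channels x samples,
channel labels as the index) per subject-state recording plus a
``subjects.csv`` table (subject_id, outcome).  EDF recordings can be read
through MNE when it is installed.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import EvalResult, performance_P, results_table
from .recording import EEGRecording


def write_cohort_bundle(directory, recordings, labels, fs: float | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = []
    for pair in recordings:
        for rec in pair:
            frame = pd.DataFrame(rec.data, index=rec.channel_labels)
            frame.to_csv(directory / f"{rec.subject_id}_{rec.state}.csv")
            meta.append({"subject_id": rec.subject_id, "state": rec.state,
                         "fs": rec.fs})
    subjects = pd.DataFrame({
        "subject_id": [pair[0].subject_id for pair in recordings],
        "outcome": np.asarray(labels, dtype=int),
    })
    subjects.to_csv(directory / "subjects.csv", index=False)
    pd.DataFrame(meta).to_csv(directory / "recordings.csv", index=False)


def read_cohort_bundle(directory):
    directory = Path(directory)
    subjects = pd.read_csv(directory / "subjects.csv")
    meta = pd.read_csv(directory / "recordings.csv")
    fs_map = {(r.subject_id, r.state): r.fs for r in meta.itertuples()}
    recordings = []
    for sid in subjects["subject_id"]:
        pair = []
        for state in ("wake", "sleep"):
            frame = pd.read_csv(directory / f"{sid}_{state}.csv", index_col=0)
            pair.append(EEGRecording(
                subject_id=str(sid), state=state, fs=float(fs_map[(sid, state)]),
                data=frame.to_numpy(), channel_labels=list(frame.index),
            ))
        recordings.append(tuple(pair))
    labels = subjects["outcome"].to_numpy(dtype=int)
    return recordings, labels


def read_edf(path, subject_id: str, state: str) -> EEGRecording:
    """Read an EDF recording via MNE (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF files requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return EEGRecording(
        subject_id=subject_id, state=state, fs=float(raw.info["sfreq"]),
        data=raw.get_data() * 1e6,  # volts -> microvolts
        channel_labels=list(raw.ch_names),
    )


def write_feature_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_grid_results(directory, results: list[EvalResult], failures=None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for r in results:
        records.append({
            "config": asdict(r.config),
            "mean_cm": r.mean_cm.tolist(),
            "P": performance_P(r),
            "accuracy_mean": r.accuracy_mean,
            "accuracy_sd": r.accuracy_sd,
            "sensitivity_mean": r.sensitivity_mean,
            "sensitivity_sd": r.sensitivity_sd,
            "specificity_mean": r.specificity_mean,
            "specificity_sd": r.specificity_sd,
            "mse": r.mse,
            "per_rep_accuracies": r.per_rep_accuracies.tolist(),
        })
    payload = {"results": records, "failures": failures or []}
    with open(directory / "grid_results.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    results_table(results).to_csv(directory / "grid_summary.csv", index=False)
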