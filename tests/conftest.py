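import numpy as np
import pandas as pd
import pytest

from qeeg.features import FEATURE_NAMES
from qeeg.recording import CHANNELS_1020, EEGRecording


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240513)


def make_feature_table(n_subjects: int, seed: int = 0,
                       channels=None, shifts=None, labels=None) -> tuple:
    """Fabricate a tidy feature table (no signal generation).

    ``shifts`` maps "feature|state" -> effect size added to SF subjects'
    channel-averaged values; per-channel rows are the average row plus noise.
    """
    rng = np.random.default_rng(seed)
    channels = channels if channels is not None else list(CHANNELS_1020)
    if labels is None:
        labels = (rng.random(n_subjects) < 0.594).astype(int)
    shifts = shifts or {}
    rows = []
    subject_ids = [f"sub-{i:03d}" for i in range(n_subjects)]
    for sid, lab in zip(subject_ids, labels):
        for state in ("wake", "sleep"):
            base = {f: rng.normal() for f in FEATURE_NAMES}
            for f in FEATURE_NAMES:
                base[f] += lab * shifts.get(f"{f}|{state}", 0.0)
            ch_rows = []
            for ch in channels:
                vals = {f: base[f] + 0.1 * rng.normal() for f in FEATURE_NAMES}
                ch_rows.append({"subject_id": sid, "state": state,
                                "channel": ch, **vals})
            avg = {f: float(np.mean([r[f] for r in ch_rows])) for f in FEATURE_NAMES}
            ch_rows.append({"subject_id": sid, "state": state, "channel": "avg",
                            **avg})
            rows.extend(ch_rows)
    table = pd.DataFrame(rows)
    return table, pd.Series(labels, index=subject_ids)


def make_recording(data, fs=256.0, state="wake", subject_id="sub-000"):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    labels = CHANNELS_1020[: data.shape[0]]
    return EEGRecording(subject_id=subject_id, state=state, fs=fs,
                        data=data, channel_labels=list(labels))
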