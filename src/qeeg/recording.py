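"""Container for one subject-state EEG signal block.

A recording is a channels x samples real matrix with a sampling rate and a
vigilance-state tag (wakefulness or sleep).  The default montage is the
19-electrode 10-20 scalp placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Standard 19-channel 10-20 montage labels.
CHANNELS_1020 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
]

STATES = ("wake", "sleep")


@dataclass
class EEGRecording:
    """One subject-state signal block (channels x samples).

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    state : {"wake", "sleep"}
        Vigilance state of the segment.
    fs : float
        Sampling frequency in Hz.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolt-scale units (arbitrary after z-scoring).
    channel_labels : list of str
        One label per row of ``data``.
    """

    subject_id: str
    state: str
    fs: float
    data: np.ndarray
    channel_labels: list[str] = field(default_factory=lambda: list(CHANNELS_1020))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels were given"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Segment length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray, fs: float | None = None) -> "EEGRecording":
        """Return a new recording with replaced samples (same identity)."""
        return EEGRecording(
            subject_id=self.subject_id,
            state=self.state,
            fs=self.fs if fs is None else fs,
            data=data,
            channel_labels=list(self.channel_labels),
        )
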