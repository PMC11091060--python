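"""Signal-conditioning chain applied to each recording before feature
extraction.

Stage order: average reference -> resample to the target rate -> powerline
notch -> zero-phase Butterworth band-pass -> per-channel z-score.  Filtering
is forward-backward, so the effective magnitude response is the square of the
designed 7th-order Butterworth; this avoids phase distortion that would bias
Hjorth and entropy features.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .recording import EEGRecording


@dataclass
class PreprocessConfig:
    target_fs: float = 256.0
    notch_hz: float = 50.0
    notch_q: float = 30.0
    bp_low: float = 0.5
    bp_high: float = 45.0
    bp_order: int = 7
    segment_s: float = 60.0

    def __post_init__(self):
        if not 0.0 < self.bp_low < self.bp_high < self.target_fs / 2.0:
            raise ValueError("need 0 < bp_low < bp_high < target_fs/2")
        if self.bp_order < 1:
            raise ValueError("bp_order must be >= 1")
        if self.segment_s <= 0:
            raise ValueError("segment_s must be positive")


def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the common average: subtract the instantaneous mean
    across channels, so every output sample column sums to zero."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data)


def extract_segment(rec: EEGRecording, cfg: PreprocessConfig | None = None) -> EEGRecording:
    """Keep the leading ``segment_s`` seconds of the recording."""
    cfg = cfg or PreprocessConfig()
    n_keep = int(round(cfg.segment_s * rec.fs))
    if rec.n_samples < n_keep:
        raise ValueError(
            f"recording has {rec.n_samples} samples but "
            f"{n_keep} ({cfg.segment_s} s at {rec.fs} Hz) are required"
        )
    if rec.n_samples == n_keep:
        return rec
    return rec.copy_with(rec.data[:, :n_keep])


def _resample(data: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Polyphase anti-aliased resampling (512 -> 256 Hz is a plain factor-2
    decimation)."""
    if fs == target_fs:
        return data
    frac = Fraction(target_fs / fs).limit_denominator(1000)
    return signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)


def filter_chain(rec: EEGRecording, cfg: PreprocessConfig | None = None) -> EEGRecording:
    """The conditioning chain without the final z-score (useful for measuring
    raw filter gains)."""
    cfg = cfg or PreprocessConfig()
    if rec.fs < 2.0 * cfg.bp_high:
        raise ValueError(
            f"sampling rate {rec.fs} Hz is below the Nyquist requirement "
            f"for a {cfg.bp_high} Hz band edge"
        )
    if not np.all(np.isfinite(rec.data)):
        raise ValueError("input contains NaN or Inf")

    out = rereference_average(rec)
    data = _resample(out.data, rec.fs, cfg.target_fs)

    b, a = signal.iirnotch(cfg.notch_hz, cfg.notch_q, fs=cfg.target_fs)
    data = signal.filtfilt(b, a, data, axis=1)

    sos = signal.butter(
        cfg.bp_order, [cfg.bp_low, cfg.bp_high], btype="bandpass",
        fs=cfg.target_fs, output="sos",
    )
    data = signal.sosfiltfilt(sos, data, axis=1)
    return rec.copy_with(data, fs=cfg.target_fs)


def zscore_channels(rec: EEGRecording) -> EEGRecording:
    sd = rec.data.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cannot z-score a constant channel")
    data = (rec.data - rec.data.mean(axis=1, keepdims=True)) / sd
    return rec.copy_with(data)


def preprocess_recording(rec: EEGRecording, cfg: PreprocessConfig | None = None) -> EEGRecording:
    """Full conditioning chain: average reference, resampling, notch,
    band-pass, per-channel z-score."""
    cfg = cfg or PreprocessConfig()
    return zscore_channels(filter_chain(rec, cfg))
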