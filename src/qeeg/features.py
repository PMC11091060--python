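"""Windowed extraction of the 13 linear and non-linear EEG features.

Per channel and vigilance state the roster is: Welch band power in the five
conventional bands plus total power (6), the three Hjorth parameters
(activity, mobility, complexity), approximate entropy, normalised
permutation entropy, the largest Lyapunov exponent (Rosenstein small-data
algorithm) and the Hurst exponent (bias-corrected rescaled-range analysis).

Features are computed on non-overlapping windows (5 s for band power,
Hjorth and the entropies; 10 s for the Hurst and Lyapunov estimators, which
need longer stretches) and averaged across windows.  A cross-channel mean
row ("avg" channel) is appended per recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.special import gammaln

from ._kernels import apen_phi_counts, lyap_divergence
from .recording import EEGRecording
from .synth import BANDS

#: Canonical order of the 13 features.
FEATURE_NAMES = [
    "psd_delta", "psd_theta", "psd_alpha", "psd_beta", "psd_gamma",
    "psd_total",
    "hjorth_activity", "hjorth_mobility", "hjorth_complexity",
    "apen", "permen", "lle", "hurst",
]


@dataclass
class FeatureConfig:
    """Estimator parameters.

    ``lle_ref_points`` bounds the number of reference trajectories used in
    the Lyapunov divergence average (the nearest-neighbour search still scans
    every embedded point); ``None`` uses every point.
    """

    window_s_short: float = 5.0
    window_s_long: float = 10.0
    apen_m: int = 2
    apen_r_factor: float = 0.2
    pe_order: int = 3
    pe_delay: int = 1
    lle_emb: int = 5
    lle_lag: int | None = 8
    lle_ref_points: int | None = 200
    bands: dict = field(default_factory=lambda: dict(BANDS))

    def __post_init__(self):
        if self.apen_m < 1:
            raise ValueError("apen_m must be >= 1")
        if self.pe_order < 2:
            raise ValueError("pe_order must be >= 2")
        if self.window_s_short <= 0 or self.window_s_long <= 0:
            raise ValueError("window lengths must be positive")


# ---------------------------------------------------------------------------
# Hjorth parameters
# ---------------------------------------------------------------------------

def hjorth(x: np.ndarray):
    """Hjorth activity, mobility and complexity.

    activity = var(x); mobility = sqrt(var(dx)/var(x)); complexity =
    mobility(dx)/mobility(x), with dx the first difference.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("hjorth needs at least 3 samples")
    var0 = x.var()
    if var0 == 0.0:
        raise ValueError("mobility/complexity undefined for a constant series")
    dx = np.diff(x)
    var1 = dx.var()
    if var1 == 0.0:
        raise ValueError("complexity undefined: first difference is constant")
    var2 = np.diff(dx).var()
    mobility = math.sqrt(var1 / var0)
    complexity = math.sqrt(var2 / var1) / mobility
    return var0, mobility, complexity


# ---------------------------------------------------------------------------
# band power
# ---------------------------------------------------------------------------

def band_psd(x: np.ndarray, fs: float, bands: dict | None = None,
             total_range: tuple = (0.5, 45.0)):
    """Welch band powers.

    Returns (dict band -> power, total) where each power is the PSD
    integrated over the band and total integrates over ``total_range``.
    """
    bands = bands or BANDS
    x = np.asarray(x, dtype=float)
    if x.size < 2 * fs:
        raise ValueError("band_psd needs at least 2 s of samples")
    for name, (lo, hi) in bands.items():
        if hi > fs / 2.0:
            raise ValueError(f"band {name!r} upper edge {hi} Hz exceeds Nyquist")
    f, pxx = signal.welch(x, fs=fs, nperseg=min(x.size, int(2 * fs)))

    def integrate(lo, hi):
        mask = (f >= lo) & (f <= hi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(pxx[mask], f[mask]))

    powers = {name: integrate(lo, hi) for name, (lo, hi) in bands.items()}
    total = integrate(*total_range)
    return powers, total


# ---------------------------------------------------------------------------
# approximate entropy (Pincus)
# ---------------------------------------------------------------------------

def approximate_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2,
                        r: float | None = None) -> float:
    """ApEn(m, r, N) = Phi^m(r) - Phi^{m+1}(r) with Chebyshev distance and
    self-matches included.  By default r = r_factor * SD(x); a constant
    series returns 0 by convention."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    n = x.size
    if n < 50:
        raise ValueError("approximate_entropy needs at least 50 samples")
    if r is None:
        r = r_factor * x.std()
    counts_m, counts_m1 = apen_phi_counts(x, m, float(r))
    phi_m = np.mean(np.log(counts_m / counts_m.size))
    phi_m1 = np.mean(np.log(counts_m1 / counts_m1.size))
    return float(phi_m - phi_m1)


# ---------------------------------------------------------------------------
# permutation entropy (Bandt-Pompe)
# ---------------------------------------------------------------------------

def permutation_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Normalised permutation entropy in [0, 1].

    Shannon entropy of the ordinal-pattern distribution divided by
    ln(order!).  Ties are broken by order of occurrence (stable sort).
    """
    x = np.asarray(x, dtype=float)
    n_patterns = x.size - (order - 1) * delay
    if n_patterns < 1 or x.size <= math.factorial(order):
        raise ValueError(
            f"series too short for order={order}, delay={delay} "
            f"permutation entropy"
        )
    idx = np.arange(n_patterns)[:, None] + np.arange(order)[None, :] * delay
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    codes = patterns @ (order ** np.arange(order))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / n_patterns
    h = -np.sum(p * np.log(p))
    return float(h / math.log(math.factorial(order)))


# ---------------------------------------------------------------------------
# largest Lyapunov exponent (Rosenstein)
# ---------------------------------------------------------------------------

def _mean_period_samples(x: np.ndarray) -> float:
    """Mean period in samples from the power-spectrum mean frequency."""
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0)  # cycles / sample
    num = float(np.sum(freqs[1:] * spec[1:]))
    den = float(np.sum(spec[1:]))
    if den <= 0 or num <= 0:
        return 10.0
    return 1.0 / (num / den)


def _delay_embed(x: np.ndarray, emb: int, lag: int) -> np.ndarray:
    m = x.size - (emb - 1) * lag
    if m < 2:
        raise ValueError("series too short for the requested embedding")
    idx = np.arange(m)[:, None] + np.arange(emb)[None, :] * lag
    return np.ascontiguousarray(x[idx])


def first_zero_autocorr(x: np.ndarray, max_lag: int | None = None) -> int:
    """First zero crossing of the autocorrelation (delay heuristic)."""
    x = x - x.mean()
    n = x.size
    max_lag = max_lag or n // 4
    ac = np.correlate(x, x, mode="full")[n - 1: n - 1 + max_lag + 1]
    below = np.nonzero(ac <= 0)[0]
    return int(below[0]) if below.size else max_lag


def largest_lyapunov(
    x: np.ndarray,
    emb: int = 5,
    lag: int | None = None,
    fs: float = 1.0,
    theiler: int | None = None,
    fit_steps: int | None = None,
    n_ref: int | None = None,
) -> float:
    """Largest Lyapunov exponent by the Rosenstein small-data algorithm.

    Delay-embed the series, pair each reference point with its nearest
    neighbour outside a Theiler window of one mean period, track the average
    log divergence <ln d(i)> and return the least-squares slope of its
    initial (pre-saturation) region, in nats per sample.  Multiply by ``fs``
    for nats per second.

    Parameters mirror the estimator's knobs: ``lag`` defaults to the first
    autocorrelation zero crossing; ``fit_steps`` defaults to about half a
    mean period (at least 8 steps); ``n_ref`` subsamples the reference
    points used in the divergence average (the neighbour search always scans
    every embedded point).
    """
    x = np.asarray(x, dtype=np.float64)
    if lag is None:
        lag = max(1, first_zero_autocorr(x))
    y = _delay_embed(x, emb, lag)
    m = y.shape[0]
    if m < 500:
        raise ValueError("largest_lyapunov needs >= 500 embedded points")

    period = _mean_period_samples(x)
    if theiler is None:
        theiler = int(np.ceil(period))
    max_steps = fit_steps if fit_steps is not None else int(
        np.clip(round(4.0 * period), 20, max(20, m // 4))
    )
    max_steps = min(max_steps, m - 2)

    if n_ref is None or n_ref >= m:
        refs = np.arange(m, dtype=np.int64)
    else:
        refs = np.linspace(0, m - 1, n_ref).astype(np.int64)

    sum_logs, counts = lyap_divergence(y, refs, int(theiler), int(max_steps))
    valid = counts > 0
    if not valid[0] or valid.sum() < 3:
        raise ValueError("no valid neighbour pairs for divergence tracking")
    steps = np.nonzero(valid)[0]
    curve = sum_logs[valid] / counts[valid]

    # Fit the initial linear region only: when the curve clearly rises
    # (exponential divergence), stop the fit where it approaches saturation;
    # otherwise (periodic/weakly divergent orbits) fit the whole baseline,
    # which averages out log-distance jitter near the numerical noise floor.
    if fit_steps is None:
        rise = float(curve.max() - curve[0])
        if rise >= 2.0:
            cutoff = np.argmax(curve >= curve.max() - 0.1 * rise)
            end = max(int(cutoff), 8)
            steps, curve = steps[: end + 1], curve[: end + 1]
    slope = float(np.polyfit(steps, curve, 1)[0])
    return slope


# ---------------------------------------------------------------------------
# Hurst exponent (corrected rescaled range)
# ---------------------------------------------------------------------------

def _expected_rs(n: int) -> float:
    """Anis-Lloyd expected R/S of an i.i.d. series of length n (with the
    small-sample (n - 1/2)/n adjustment)."""
    i = np.arange(1, n)
    s = float(np.sum(np.sqrt((n - i) / i)))
    if n <= 340:
        front = math.exp(gammaln((n - 1) / 2.0) - gammaln(n / 2.0)) / math.sqrt(math.pi)
    else:
        front = 1.0 / math.sqrt(n * math.pi / 2.0)
    return (n - 0.5) / n * front * s


def hurst_rs(x: np.ndarray, min_block: int = 8, n_sizes: int = 10) -> float:
    """Hurst exponent by bias-corrected rescaled-range (R/S) analysis.

    The series is split into non-overlapping blocks at logarithmically
    spaced sizes; the mean rescaled range per size is compared against the
    Anis-Lloyd expectation for a memoryless series, and
    H = 1/2 + slope of log[(R/S)_n / E(R/S)_n] vs log n.  The correction
    removes the small-sample upward bias of the raw R/S slope (a white-noise
    input estimates H near 0.5 instead of ~0.55-0.6).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 256:
        raise ValueError("hurst_rs needs at least 256 samples")
    max_block = n // 4
    sizes = np.unique(
        np.round(
            np.logspace(np.log10(min_block), np.log10(max_block), n_sizes)
        ).astype(int)
    )
    sizes = sizes[sizes >= 4]

    log_sizes, log_ratio = [], []
    for size in sizes:
        nb = n // size
        blocks = x[: nb * size].reshape(nb, size)
        dev = blocks - blocks.mean(axis=1, keepdims=True)
        walk = np.cumsum(dev, axis=1)
        rng_ = walk.max(axis=1) - walk.min(axis=1)
        sd = blocks.std(axis=1, ddof=1)
        ok = sd > 0
        if not np.any(ok):
            continue  # all blocks degenerate at this size
        rs = float(np.mean(rng_[ok] / sd[ok]))
        log_sizes.append(math.log(size))
        log_ratio.append(math.log(rs) - math.log(_expected_rs(int(size))))
    if len(log_sizes) < 3:
        raise ValueError("too few non-degenerate block sizes for R/S analysis")
    slope = float(np.polyfit(log_sizes, log_ratio, 1)[0])
    return 0.5 + slope


# ---------------------------------------------------------------------------
# windowed extraction
# ---------------------------------------------------------------------------

def _window_view(x: np.ndarray, w: int) -> np.ndarray:
    """Non-overlapping windows (trailing remainder dropped)."""
    nw = x.size // w
    if nw < 1:
        raise ValueError("series shorter than one window")
    return x[: nw * w].reshape(nw, w)


def _channel_features(x: np.ndarray, fs: float, cfg: FeatureConfig) -> dict:
    w_short = int(round(cfg.window_s_short * fs))
    w_long = int(round(cfg.window_s_long * fs))

    shorts = _window_view(x, w_short)
    acc = {name: [] for name in FEATURE_NAMES}
    for win in shorts:
        powers, total = band_psd(win, fs, cfg.bands)
        for band, val in powers.items():
            acc[f"psd_{band}"].append(val)
        acc["psd_total"].append(total)
        act, mob, comp = hjorth(win)
        acc["hjorth_activity"].append(act)
        acc["hjorth_mobility"].append(mob)
        acc["hjorth_complexity"].append(comp)
        acc["apen"].append(
            approximate_entropy(win, cfg.apen_m, cfg.apen_r_factor)
        )
        acc["permen"].append(
            permutation_entropy(win, cfg.pe_order, cfg.pe_delay)
        )

    longs = _window_view(x, w_long)
    for win in longs:
        acc["hurst"].append(hurst_rs(win))
        acc["lle"].append(
            largest_lyapunov(
                win, emb=cfg.lle_emb, lag=cfg.lle_lag, fs=fs,
                n_ref=cfg.lle_ref_points,
            )
        )
    return {name: float(np.mean(vals)) for name, vals in acc.items()}


def extract_features(rec: EEGRecording, cfg: FeatureConfig | None = None) -> pd.DataFrame:
    """Extract the 13-feature vector per channel plus the cross-channel mean.

    Returns a tidy frame with columns (subject_id, state, channel) followed
    by the 13 feature columns; the "avg" channel row is the arithmetic mean
    of the channel rows.
    """
    cfg = cfg or FeatureConfig()
    rows = []
    for label, x in zip(rec.channel_labels, rec.data):
        try:
            feats = _channel_features(x, rec.fs, cfg)
        except Exception as exc:  # tag failures with their channel
            raise RuntimeError(
                f"feature extraction failed on channel {label!r} "
                f"of {rec.subject_id}/{rec.state}: {exc}"
            ) from exc
        rows.append({"subject_id": rec.subject_id, "state": rec.state,
                     "channel": label, **feats})
    table = pd.DataFrame(rows)
    avg = {
        "subject_id": rec.subject_id, "state": rec.state, "channel": "avg",
        **{name: table[name].mean() for name in FEATURE_NAMES},
    }
    return pd.concat([table, pd.DataFrame([avg])], ignore_index=True)
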