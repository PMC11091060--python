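"""Synthetic EEG cohort generator.

Builds wake/sleep scalp-EEG cohorts with plantable group differences between
seizure-free (SF) and non-seizure-free (NSF) subjects so that the whole
outcome-prediction pipeline can be exercised and validated without patient
recordings.

Each channel is a sum of independent components:

* a fractional Gaussian noise (fGn) term whose Hurst exponent carries the
  long-range-dependence contrast,
* a broadband 1/f ("pink") background,
* an amplitude-modulated 10 Hz alpha oscillation (random phase per channel),
* band-limited 20-40 Hz noise that raises Hjorth mobility predictably,
* optional extra narrow-band components.

Group/state differences enter only through the component parameters
(``hurst_target``, ``alpha_amp``, ``hf_amp``).  Between-subject variability
comes from subject-level jitter of every component amplitude and of the Hurst
exponent; the jitter factors are drawn once per subject and shared between
the wake and sleep recordings, which mimics stable individual differences in
background EEG composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import CHANNELS_1020, EEGRecording

GROUPS = ("SF", "NSF")
STATES = ("wake", "sleep")

#: Conventional EEG frequency bands in Hz.
BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: Frequency ranges of the generator's narrow-band components.  The delta
#: component occupies the upper delta range only: the lowest octave is
#: reserved for the broadband fGn/white mixture so that band-power levels can
#: be shaped without disturbing the long-range-dependence structure the Hurst
#: contrast is planted in.
COMPONENT_BANDS = {
    "delta": (1.8, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "beta_lo": (13.0, 19.0),
    "beta_mid": (19.0, 24.0),
    "beta_hi": (24.0, 30.0),
    "gamma": (30.0, 45.0),
    "gamma_lo": (30.0, 36.0),
    "gamma_hi": (39.0, 45.0),
}


# ---------------------------------------------------------------------------
# fractional Gaussian noise
# ---------------------------------------------------------------------------

def fgn_autocovariance(hurst: float, lags: np.ndarray) -> np.ndarray:
    """Theoretical unit-variance fGn autocovariance
    gamma(k) = 0.5 (|k+1|^2H - 2|k|^2H + |k-1|^2H)."""
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1.0) ** h2 - 2.0 * k ** h2 + np.abs(k - 1.0) ** h2)


def simulate_fgn(hurst: float, n: int, seed=None) -> np.ndarray:
    """Simulate fractional Gaussian noise with exact target autocovariance.

    Uses circulant embedding (Davies-Harte): the covariance sequence is
    embedded in a circulant matrix diagonalised by the FFT, so the sampled
    series has exactly the theoretical autocovariance.  If the embedding is
    not non-negative definite (rare for plain fGn) the generator falls back
    to Cholesky factorisation of the Toeplitz covariance.

    Parameters
    ----------
    hurst : float in (0, 1)
    n : int >= 16
        Series length.
    seed : int, SeedSequence or Generator, optional

    Returns
    -------
    ndarray, shape (n,) -- zero-mean, unit-variance fGn.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"hurst must lie in (0, 1), got {hurst}")
    n = int(n)
    if n < 16:
        raise ValueError(f"need n >= 16 samples for fGn synthesis, got {n}")
    rng = np.random.default_rng(seed)

    gamma = fgn_autocovariance(hurst, np.arange(n + 1))
    # circulant first row: gamma(0..n), gamma(n-1..1)
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    m = row.size  # = 2n
    if lam.min() < -1e-8 * lam.max():
        return _fgn_cholesky(gamma[:-1], rng)
    lam = np.clip(lam, 0.0, None)

    w = np.zeros(m, dtype=complex)
    w[0] = np.sqrt(lam[0]) * rng.standard_normal()
    w[n] = np.sqrt(lam[n]) * rng.standard_normal()
    a = rng.standard_normal(n - 1)
    b = rng.standard_normal(n - 1)
    w[1:n] = np.sqrt(lam[1:n] / 2.0) * (a + 1j * b)
    w[n + 1:] = np.conj(w[1:n][::-1])
    x = np.fft.fft(w) / np.sqrt(m)
    return x.real[:n]


def _fgn_cholesky(gamma: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    from scipy.linalg import cholesky, toeplitz

    n = gamma.size
    if n > 4096:
        raise ValueError(
            "circulant embedding failed and series is too long for the "
            "Cholesky fallback"
        )
    chol = cholesky(toeplitz(gamma), lower=True)
    return chol @ rng.standard_normal(n)


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------

@dataclass
class StateEffects:
    """Component parameters of one (group, state) cell.

    ``alpha_amp``, ``hf_amp``, ``base_amp`` and ``fgn_amp`` are relative
    amplitudes (the absolute scale is irrelevant once recordings are
    z-scored); ``band_amps`` adds optional extra narrow-band components.
    """

    hurst_target: float
    alpha_amp: float
    hf_amp: float
    base_amp: float = 1.0
    fgn_amp: float = 0.8
    white_amp: float = 0.0
    vlf_amp: float = 0.0
    am_depth: float = 0.0
    hf_tone_amp: float = 0.0
    hf_tone_freq: float = 35.0
    fast_prob: float = 0.0
    fast_gains: dict = field(default_factory=dict)
    fast_block_s: float = 5.0
    fast_norm_prob: float | None = None
    band_amps: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.hurst_target < 1.0:
            raise ValueError("hurst_target must lie in (0, 1)")
        if not 0.0 <= self.fast_prob <= 1.0:
            raise ValueError("fast_prob must lie in [0, 1]")
        for name, amp in [
            ("alpha_amp", self.alpha_amp),
            ("hf_amp", self.hf_amp),
            ("base_amp", self.base_amp),
            ("fgn_amp", self.fgn_amp),
            ("white_amp", self.white_amp),
            ("vlf_amp", self.vlf_amp),
            ("am_depth", self.am_depth),
            ("hf_tone_amp", self.hf_tone_amp),
            *self.band_amps.items(),
        ]:
            if amp < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroupEffects:
    """Map (group, state) -> StateEffects for SF/NSF x wake/sleep."""

    table: dict

    def __post_init__(self):
        for key in self.table:
            group, state = key
            if group not in GROUPS or state not in STATES:
                raise ValueError(f"invalid (group, state) key {key!r}")

    def for_cell(self, group: str, state: str) -> StateEffects:
        try:
            return self.table[(group, state)]
        except KeyError:
            raise KeyError(f"no effects defined for group={group!r}, state={state!r}")


@dataclass
class CohortConfig:
    """Synthetic cohort description.

    ``sf_rate`` defaults to the 59.4 % seizure-free base rate of the study
    cohort; recordings default to 60 s of 19-channel EEG at 256 Hz.
    Subject-level jitter standard deviations control between-subject
    variability of the Hurst exponent (additive, Gaussian) and of every
    component amplitude (multiplicative, log-normal).
    """

    n_patients: int
    effects: GroupEffects
    sf_rate: float = 0.594
    fs: float = 256.0
    duration: float = 60.0
    n_channels: int = 19
    seed: int = 0
    hurst_jitter_sd: float = 0.12
    amp_jitter_sd: float = 0.28
    fast_jitter_sd: float = 0.07
    gamma_tilt_jitter_sd: float = 2.0

    def __post_init__(self):
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        if not 0.0 < self.sf_rate < 1.0:
            raise ValueError("sf_rate must lie in (0, 1)")
        n_samp = self.duration * self.fs
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("duration x fs must give an integer sample count")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def channel_labels(self) -> list[str]:
        if self.n_channels <= len(CHANNELS_1020):
            return CHANNELS_1020[: self.n_channels]
        return CHANNELS_1020 + [
            f"EX{i}" for i in range(self.n_channels - len(CHANNELS_1020))
        ]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: Baseline (group-free) component parameters of the reference preset.
_REF_BASE = dict(
    hurst_target=0.62, base_amp=0.0, fgn_amp=1.0, white_amp=0.55,
    am_depth=0.35, alpha_amp=0.45, hf_amp=0.22,
    fast_prob=0.30,
    fast_gains={"delta": 1.8, "gamma_hi": 2.2, "gamma_lo": 1.4,
                "theta": 0.55, "alpha": 0.7, "beta_mid": 0.55, "hf": 1.5},
    band_amps={"delta": 0.60, "theta": 0.50, "alpha": 0.30,
               "beta_lo": 0.23, "beta_mid": 0.23, "beta_hi": 0.23,
               "gamma_lo": 0.18, "gamma_hi": 0.18},
)

#: Calibrated SF-minus-NSF contrasts per state, in knob space (Hurst
#: additive; amplitudes as log-factors; btilt/gtilt are power-preserving
#: upward tilts inside the beta/gamma bands).  Derived once from a measured
#: feature-response Jacobian so that the planted contrasts land in the four
#: outcome-associated features while the remaining channel-averaged features
#: stay inside their between-subject noise.
_REF_CONTRASTS = {
    "sleep": {"hurst": 0.179, "white": -0.036, "alpha": 0.44, "hf": 0.38,
              "delta": -0.068, "theta": -0.070, "beta": -0.082,
              "gamma": 0.046, "alphaband": -0.337, "btilt": 1.15,
              "gtilt": 0.268},
    "wake": {"hurst": -0.1062, "white": -0.195, "alpha": 0.0394,
             "alphaband": 0.1923, "hf": -0.0255, "delta": 0.0939,
             "theta": 0.0991, "beta": 0.2046, "gamma": 0.2534,
             "btilt": 0.0, "gtilt": 0.0},
}


def _effects_from_contrast(theta: dict, sign: float) -> StateEffects:
    """Apply half of a knob-space contrast to the reference baseline."""
    t = {k: sign * 0.5 * v for k, v in theta.items()}
    ba = dict(_REF_BASE["band_amps"])
    for band, knob in [("delta", "delta"), ("theta", "theta"),
                       ("alpha", "alphaband")]:
        ba[band] = ba[band] * float(np.exp(t.get(knob, 0.0)))
    # gamma: overall scale + power-preserving up-tilt
    gt = t.get("gtilt", 0.0)
    gscale = float(np.exp(t.get("gamma", 0.0)) / np.sqrt(np.cosh(2.0 * gt)))
    ba["gamma_lo"] *= gscale * float(np.exp(-gt))
    ba["gamma_hi"] *= gscale * float(np.exp(gt))
    # beta: overall scale + up-tilt across the three sub-bands
    bt = t.get("btilt", 0.0)
    lo, mid, hi = np.exp(-bt), 1.0, np.exp(bt)
    norm = float(np.sqrt(3.0 / (lo**2 + mid**2 + hi**2)))
    bscale = float(np.exp(t.get("beta", 0.0))) * norm
    ba["beta_lo"] *= bscale * float(lo)
    ba["beta_mid"] *= bscale
    ba["beta_hi"] *= bscale * float(hi)
    return StateEffects(
        hurst_target=float(np.clip(_REF_BASE["hurst_target"] + t.get("hurst", 0.0),
                                   0.05, 0.95)),
        base_amp=_REF_BASE["base_amp"],
        fgn_amp=_REF_BASE["fgn_amp"],
        white_amp=_REF_BASE["white_amp"] * float(np.exp(t.get("white", 0.0))),
        am_depth=_REF_BASE["am_depth"],
        alpha_amp=_REF_BASE["alpha_amp"] * float(np.exp(t.get("alpha", 0.0))),
        hf_amp=_REF_BASE["hf_amp"] * float(np.exp(t.get("hf", 0.0))),
        fast_prob=float(np.clip(_REF_BASE["fast_prob"] + t.get("fast", 0.0), 0.0, 1.0)),
        fast_gains=dict(_REF_BASE["fast_gains"]),
        fast_norm_prob=_REF_BASE["fast_prob"],
        band_amps=ba,
    )


def reference_effects() -> GroupEffects:
    """Preset with group contrasts planted in exactly four features.

    Directions follow the study's findings: relative to NSF subjects, SF
    subjects have a higher sleep Hurst exponent, a lower wake Hurst exponent,
    more sleep alpha power and higher sleep Hjorth mobility.  Magnitudes are
    a design choice, calibrated once against the feature extractor so that
    each planted contrast is detectable by the logistic screen at n = 200
    while the remaining channel-averaged features stay within their
    between-subject noise.
    """
    table = {}
    for state in STATES:
        theta = _REF_CONTRASTS[state]
        table[("SF", state)] = _effects_from_contrast(theta, +1.0)
        table[("NSF", state)] = _effects_from_contrast(theta, -1.0)
    return GroupEffects(table)


def null_effects() -> GroupEffects:
    """Preset with no group differences (both groups share NSF parameters)."""
    ref = reference_effects()
    return GroupEffects(
        {
            (g, s): ref.for_cell("NSF", s)
            for g in GROUPS
            for s in STATES
        }
    )


# ---------------------------------------------------------------------------
# signal components
# ---------------------------------------------------------------------------

def _unit_sd(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink(rng: np.random.Generator, n: int) -> np.ndarray:
    """Broadband 1/f-power background via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** -0.5
    return _unit_sd(np.fft.irfft(spec * amp, n))


def _narrowband(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return _unit_sd(signal.sosfiltfilt(sos, rng.standard_normal(n)))


def _spectral_band(rng: np.random.Generator, n: int, fs: float,
                   lo: float, hi: float) -> np.ndarray:
    """Band-limited noise by FFT masking (robust for very low bands)."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < lo) | (f > hi)] = 0.0
    return _unit_sd(np.fft.irfft(spec, n))


def _am_tone(rng: np.random.Generator, n: int, fs: float,
             freq: float) -> np.ndarray:
    """Amplitude-modulated sinusoid with random phase (waxing/waning
    oscillation)."""
    t = np.arange(n) / fs
    phase = rng.uniform(0.0, 2.0 * np.pi)
    env_phase = rng.uniform(0.0, 2.0 * np.pi)
    env = 1.0 + 0.4 * np.sin(2.0 * np.pi * 0.3 * t + env_phase)
    return _unit_sd(env * np.sin(2.0 * np.pi * freq * t + phase))


def _alpha_wave(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """10 Hz alpha oscillation (amplitude-modulated, random phase)."""
    return _am_tone(rng, n, fs, 10.0)


@dataclass
class SubjectFactors:
    """Per-subject multiplicative amplitude jitters and additive Hurst offset,
    shared between the subject's wake and sleep recordings (stable individual
    differences in background composition)."""

    hurst_offset: float = 0.0
    fast_offset: float = 0.0
    gamma_tilt: float = 0.0
    alpha: float = 1.0
    hf: float = 1.0
    base: float = 1.0
    fgn: float = 1.0
    white: float = 1.0
    vlf: float = 1.0
    am: float = 1.0
    hf_tone: float = 1.0
    bands: dict = field(default_factory=dict)

    @classmethod
    def draw(cls, rng: np.random.Generator, config: CohortConfig) -> "SubjectFactors":
        s = config.amp_jitter_sd
        return cls(
            hurst_offset=rng.normal(0.0, config.hurst_jitter_sd),
            fast_offset=rng.normal(0.0, config.fast_jitter_sd),
            gamma_tilt=rng.normal(0.0, config.gamma_tilt_jitter_sd),
            alpha=float(np.exp(rng.normal(0.0, s))),
            hf=float(np.exp(rng.normal(0.0, s))),
            base=float(np.exp(rng.normal(0.0, s))),
            fgn=float(np.exp(rng.normal(0.0, s))),
            white=float(np.exp(rng.normal(0.0, s))),
            vlf=float(np.exp(rng.normal(0.0, 1.5 * s))),
            am=float(np.exp(rng.normal(0.0, 1.5 * s))),
            hf_tone=float(np.exp(rng.normal(0.0, s))),
            bands={b: float(np.exp(rng.normal(0.0, s))) for b in BANDS},
        )


# ---------------------------------------------------------------------------
# recording / cohort generation
# ---------------------------------------------------------------------------

def _episode_profiles(rng: np.random.Generator, eff: StateEffects,
                      p_fast: float, n: int, fs: float) -> dict:
    """Per-sample gain profiles realising slow/fast micro-episodes.

    Consecutive blocks of ``fast_block_s`` seconds are independently labelled
    "fast" with probability ``p_fast``; during fast episodes each component
    listed in ``fast_gains`` is scaled by its gain.  Every profile is
    smoothed (0.25 s Hann ramp) and normalised by its realised RMS, so the
    channel's time-averaged power per component -- and hence every band-power
    feature -- is invariant to the realised episode share.  What the share
    moves is the mix of window-level spectra, i.e. the window-averaged Hjorth
    and entropy statistics.
    """
    if not eff.fast_gains or p_fast <= 0.0:
        return {}
    block = max(1, int(round(eff.fast_block_s * fs)))
    n_blocks = int(np.ceil(n / block))
    fast = rng.random(n_blocks) < p_fast
    mask = np.repeat(fast, block)[:n].astype(float)
    ramp = np.hanning(max(3, int(0.25 * fs)))
    ramp /= ramp.sum()
    smooth = np.convolve(mask, ramp, mode="same")
    # normalise against a fixed reference episode share so the slow/fast mode
    # identities are preserved (a realised-share normalisation would make the
    # two pure states indistinguishable)
    p_ref = eff.fast_norm_prob if eff.fast_norm_prob is not None else eff.fast_prob
    profiles = {}
    for name, gain in eff.fast_gains.items():
        prof = 1.0 + (gain - 1.0) * smooth
        norm = np.sqrt(p_ref * gain ** 2 + (1.0 - p_ref))
        profiles[name] = prof / norm
    return profiles


def generate_recording(
    subject_id: str,
    state: str,
    group: str,
    effects: GroupEffects,
    config: CohortConfig,
    seed,
    factors: SubjectFactors | None = None,
) -> EEGRecording:
    """Generate one subject-state recording.

    Channels share the subject/group/state parameters but get independent
    noise realisations and phases (no spatial covariance is modelled).
    """
    eff = effects.for_cell(group, state)
    if factors is None:
        factors = SubjectFactors()
    rng = np.random.default_rng(seed)
    n = config.n_samples
    fs = config.fs
    hurst = float(np.clip(eff.hurst_target + factors.hurst_offset, 0.05, 0.95))
    p_fast = float(np.clip(eff.fast_prob + factors.fast_offset, 0.0, 1.0))

    data = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        profiles = _episode_profiles(rng, eff, p_fast, n, fs)

        def add(x, name, amp, component):
            if amp <= 0:
                return x
            gain = profiles.get(name)
            if gain is None:
                return x + amp * component
            return x + amp * component * gain

        x = np.zeros(n)
        x = add(x, "base", eff.base_amp * factors.base, _pink(rng, n))
        x = add(x, "fgn", eff.fgn_amp * factors.fgn, simulate_fgn(hurst, n, rng))
        x = add(x, "alpha", eff.alpha_amp * factors.alpha, _alpha_wave(rng, n, fs))
        x = add(x, "hf", eff.hf_amp * factors.hf, _narrowband(rng, n, fs, 20.0, 40.0))
        if eff.white_amp > 0:
            x = add(x, "white", eff.white_amp * factors.white,
                    rng.standard_normal(n))
        if eff.hf_tone_amp > 0:
            x = add(x, "tone", eff.hf_tone_amp * factors.hf_tone,
                    _am_tone(rng, n, fs, eff.hf_tone_freq))
        if eff.vlf_amp > 0:
            x = add(x, "vlf", eff.vlf_amp * factors.vlf,
                    _spectral_band(rng, n, fs, 0.05, 0.45))
        gt = factors.gamma_tilt
        gnorm = 1.0 / np.sqrt(np.cosh(2.0 * gt)) if gt else 1.0
        gamma_tilt_gain = {"gamma_lo": gnorm * np.exp(-gt),
                           "gamma_hi": gnorm * np.exp(gt)}
        for band, amp in eff.band_amps.items():
            lo, hi = COMPONENT_BANDS[band]
            amp = amp * factors.bands.get(band, 1.0) * gamma_tilt_gain.get(band, 1.0)
            x = add(x, band, amp, _narrowband(rng, n, fs, lo, hi))
        depth = eff.am_depth * factors.am
        if depth > 0:
            t = np.arange(n) / fs
            phase = rng.uniform(0.0, 2.0 * np.pi)
            x *= 1.0 + min(depth, 0.9) * np.sin(2.0 * np.pi * 0.12 * t + phase)
        data[ch] = x
    data *= 10.0  # microvolt-ish scale
    return EEGRecording(
        subject_id=subject_id,
        state=state,
        fs=fs,
        data=data,
        channel_labels=config.channel_labels(),
    )


def draw_outcomes(n_patients: int, sf_rate: float, seed) -> np.ndarray:
    """Draw binary outcome labels (SF = 1, NSF = 0) i.i.d. with P(SF) = sf_rate."""
    rng = np.random.default_rng(seed)
    return (rng.random(n_patients) < sf_rate).astype(int)


def generate_cohort(config: CohortConfig):
    """Generate a full cohort: two recordings (wake, sleep) per subject.

    Returns
    -------
    recordings : list of (EEGRecording, EEGRecording)
        One (wake, sleep) pair per subject.
    labels : ndarray of int
        Outcome per subject, SF = 1 / NSF = 0.
    """
    root = np.random.SeedSequence(config.seed)
    label_ss, subject_root = root.spawn(2)
    labels = draw_outcomes(config.n_patients, config.sf_rate, label_ss)
    subject_seeds = subject_root.spawn(config.n_patients)

    recordings = []
    for i, (label, sseq) in enumerate(zip(labels, subject_seeds)):
        group = "SF" if label == 1 else "NSF"
        subject_id = f"sub-{i + 1:04d}"
        factor_ss, wake_ss, sleep_ss = sseq.spawn(3)
        factors = SubjectFactors.draw(np.random.default_rng(factor_ss), config)
        wake = generate_recording(
            subject_id, "wake", group, config.effects, config, wake_ss, factors
        )
        sleep = generate_recording(
            subject_id, "sleep", group, config.effects, config, sleep_ss, factors
        )
        recordings.append((wake, sleep))
    return recordings, labels
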