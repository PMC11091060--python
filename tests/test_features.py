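"""Estimator unit tests against independent oracles and closed forms."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from qeeg.features import (FEATURE_NAMES, FeatureConfig, approximate_entropy,
                           band_psd, extract_features, hjorth, hurst_rs,
                           largest_lyapunov, permutation_entropy)
from qeeg.synth import simulate_fgn
from tests.conftest import make_recording


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def apen_bruteforce(x, m, r):
    """Direct double-loop template counting (Pincus definition)."""
    x = list(x)
    n = len(x)

    def phi(mm):
        logs = []
        for i in range(n - mm + 1):
            c = 0
            for j in range(n - mm + 1):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    c += 1
            logs.append(math.log(c / (n - mm + 1)))
        return sum(logs) / len(logs)

    return phi(m) - phi(m + 1)


def permen_bruteforce(x, order, delay):
    """Ordinal-pattern histogram via explicit enumeration."""
    n_pat = len(x) - (order - 1) * delay
    counts = {}
    for i in range(n_pat):
        window = [x[i + k * delay] for k in range(order)]
        pattern = tuple(sorted(range(order), key=lambda k: (window[k], k)))
        counts[pattern] = counts.get(pattern, 0) + 1
    p = np.array(list(counts.values())) / n_pat
    return float(-(p * np.log(p)).sum() / math.log(math.factorial(order)))


class TestApproximateEntropy:
    def test_matches_bruteforce_on_short_series(self, rng):
        for _ in range(100):
            n = int(rng.integers(60, 160))
            x = rng.standard_normal(n)
            r = 0.2 * x.std()
            fast = approximate_entropy(x, 2, 0.2)
            slow = apen_bruteforce(x, 2, r)
            assert abs(fast - slow) < 1e-12

    def test_constant_series_is_zero(self):
        assert approximate_entropy(np.ones(100)) == 0.0

    def test_noise_more_irregular_than_sawtooth(self, rng):
        diffs = []
        saw = np.tile(np.linspace(-1, 1, 25), 40)
        saw = (saw - saw.mean()) / saw.std()
        for _ in range(20):
            noise = rng.standard_normal(1000)
            diffs.append(approximate_entropy(noise) - approximate_entropy(saw))
        assert np.mean(diffs) > 0


class TestPermutationEntropy:
    def test_matches_bruteforce(self, rng):
        for _ in range(100):
            n = int(rng.integers(30, 400))
            order = int(rng.integers(3, 5))
            delay = int(rng.integers(1, 3))
            if n <= math.factorial(order) or n - (order - 1) * delay < 1:
                continue
            x = rng.standard_normal(n)
            assert permutation_entropy(x, order, delay) == pytest.approx(
                permen_bruteforce(list(x), order, delay), abs=1e-12)

    def test_monotone_series_has_zero_entropy(self):
        assert permutation_entropy(np.arange(100.0)) == 0.0

    def test_iid_noise_near_maximal(self, rng):
        assert permutation_entropy(rng.random(10000), 3, 1) >= 0.99

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            permutation_entropy(np.arange(5.0), order=3, delay=10)

    @settings(max_examples=25, deadline=None)
    @given(arrays(float, st.integers(20, 200),
                  elements=st.floats(-1e6, 1e6, allow_nan=False)))
    def test_normalized_range(self, x):
        h = permutation_entropy(x, 3, 1)
        assert 0.0 <= h <= 1.0 + 1e-12


class TestHjorth:
    def test_unit_variance_activity(self, rng):
        x = rng.standard_normal(5000)
        z = (x - x.mean()) / x.std()
        activity, _, _ = hjorth(z)
        assert activity == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("freq,amp", [(5.0, 1.0), (20.0, 3.0), (37.0, 0.2)])
    def test_sinusoid_complexity_is_one(self, freq, amp):
        t = np.arange(2560) / 256.0
        _, _, comp = hjorth(amp * np.sin(2 * np.pi * freq * t))
        assert comp == pytest.approx(1.0, abs=1e-3)

    def test_mobility_monotone_in_frequency(self):
        t = np.arange(2560) / 256.0
        mob = {f: hjorth(np.sin(2 * np.pi * f * t))[1] for f in (5.0, 20.0)}
        assert mob[20.0] > mob[5.0]

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            hjorth(np.full(100, 3.14))


class TestBandPSD:
    def test_pure_alpha_concentrated(self, rng):
        t = np.arange(1280) / 256.0
        x = np.sin(2 * np.pi * 10.0 * t) + 1e-3 * rng.standard_normal(1280)
        powers, total = band_psd(x, 256.0)
        assert powers["alpha"] / total >= 0.95

    def test_white_noise_parseval(self, rng):
        # at fs = 90 Hz the 0.5-45 Hz range spans the whole spectrum
        x = rng.standard_normal(9000)
        _, total = band_psd(x, 90.0, bands={"all": (0.5, 45.0)})
        assert total == pytest.approx(x.var(), rel=0.10)

    def test_zero_signal(self):
        powers, total = band_psd(np.zeros(1280), 256.0)
        assert total == 0.0 and all(v == 0.0 for v in powers.values())

    def test_band_beyond_nyquist_rejected(self, rng):
        with pytest.raises(ValueError, match="Nyquist"):
            band_psd(rng.standard_normal(1280), 64.0)


class TestLargestLyapunov:
    def test_logistic_map_ln2(self):
        x = np.empty(5000)
        x[0] = 0.3
        for i in range(4999):
            x[i + 1] = 4.0 * x[i] * (1.0 - x[i])
        lle = largest_lyapunov(x, emb=2, lag=1)
        assert lle == pytest.approx(math.log(2.0), abs=0.07)

    @pytest.mark.parametrize("freq", [5.0, 20.0])
    def test_sinusoid_non_divergent(self, freq):
        t = np.arange(4096) / 256.0
        lle = largest_lyapunov(np.sin(2 * np.pi * freq * t), emb=5, lag=8, fs=256.0)
        assert lle <= 0.01

    def test_deterministic(self, rng):
        x = rng.standard_normal(3000)
        a = largest_lyapunov(x, emb=5, lag=4)
        b = largest_lyapunov(x, emb=5, lag=4)
        assert a == b


class TestHurst:
    def test_white_noise_half(self, rng):
        est = [hurst_rs(rng.standard_normal(65536)) for _ in range(20)]
        assert np.mean(est) == pytest.approx(0.5, abs=0.05)

    def test_fgn_recovery_grid(self):
        errs = []
        for h in (0.3, 0.5, 0.7):
            est = [hurst_rs(simulate_fgn(h, 15360, seed)) for seed in range(10)]
            errs.append(abs(np.mean(est) - h))
        assert max(errs) < 0.1

    def test_linear_trend_persistent(self):
        assert hurst_rs(np.arange(4096.0)) >= 0.9

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            hurst_rs(np.arange(100.0))


class TestRegularityOrdering:
    def test_noise_chaos_periodic(self, rng):
        """ApEn and PermEn rank: noise > chaotic map > periodic signal."""
        n = 1280
        t = np.arange(n) / 256.0
        periodic = np.sin(2 * np.pi * 10 * t)
        logistic = np.empty(n)
        logistic[0] = 0.3
        for i in range(n - 1):
            logistic[i + 1] = 4 * logistic[i] * (1 - logistic[i])
        noise = rng.standard_normal(n)
        series = [(s - s.mean()) / s.std() for s in (noise, logistic, periodic)]
        for fn in (lambda x: approximate_entropy(x),
                   lambda x: permutation_entropy(x)):
            vals = [fn(s) for s in series]
            assert vals[0] > vals[1] > vals[2]


class TestExtractFeatures:
    def test_rows_and_average(self, rng):
        rec = make_recording(rng.standard_normal((3, 2560)), fs=256.0)
        table = extract_features(rec)
        assert len(table) == 4  # 3 channels + avg
        assert list(table.columns[3:]) == FEATURE_NAMES
        avg = table[table.channel == "avg"][FEATURE_NAMES].to_numpy()[0]
        mean = table[table.channel != "avg"][FEATURE_NAMES].to_numpy().mean(axis=0)
        np.testing.assert_allclose(avg, mean, atol=1e-9)
        assert not table[FEATURE_NAMES].isna().any().any()

    def test_identical_channels_identical_rows(self, rng):
        x = rng.standard_normal(2560)
        rec = make_recording(np.vstack([x, x]), fs=256.0)
        table = extract_features(rec)
        a, b = table[table.channel != "avg"][FEATURE_NAMES].to_numpy()
        np.testing.assert_array_equal(a, b)

    def test_window_counts(self):
        cfg = FeatureConfig()
        assert int(60.0 // cfg.window_s_short) == 12
        assert int(60.0 // cfg.window_s_long) == 6
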