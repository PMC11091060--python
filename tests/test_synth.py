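import numpy as np
import pytest

from qeeg.features import band_psd, hjorth, hurst_rs
from qeeg.preprocess import PreprocessConfig, preprocess_recording
from qeeg.synth import (CohortConfig, GroupEffects, StateEffects,
                        draw_outcomes, fgn_autocovariance,
                        generate_cohort, generate_recording, null_effects,
                        reference_effects, simulate_fgn)


def small_config(effects=None, **kw):
    defaults = dict(n_patients=6, effects=effects or reference_effects(),
                    duration=4.0, n_channels=3, seed=0)
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestFGn:
    def test_deterministic(self):
        a = simulate_fgn(0.7, 1024, seed=42)
        b = simulate_fgn(0.7, 1024, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_h_half_is_white(self):
        # gamma(k) = 0 for k >= 1 when H = 1/2
        gamma = fgn_autocovariance(0.5, np.arange(1, 50))
        np.testing.assert_allclose(gamma, 0.0, atol=1e-12)
        x = simulate_fgn(0.5, 16384, seed=1)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) < 0.05

    def test_sample_autocovariance_matches_theory(self):
        h = 0.75
        xs = [simulate_fgn(h, 4096, seed=s) for s in range(30)]
        emp = np.mean([np.mean(x[:-8] * x[8:]) for x in xs])
        assert emp == pytest.approx(fgn_autocovariance(h, np.array([8]))[0],
                                    abs=0.02)

    def test_hurst_recovery(self):
        est = [hurst_rs(simulate_fgn(0.7, 65536, seed=s)) for s in range(20)]
        assert np.mean(est) == pytest.approx(0.7, abs=0.1)

    @pytest.mark.parametrize("bad_h", [0.0, 1.0, -0.2, 1.4])
    def test_invalid_hurst_rejected(self, bad_h):
        with pytest.raises(ValueError):
            simulate_fgn(bad_h, 256)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            simulate_fgn(0.5, 8)


class TestGenerateRecording:
    def test_sample_count(self):
        cfg = CohortConfig(n_patients=4, effects=reference_effects(),
                           duration=60.0, fs=256.0, n_channels=2, seed=0)
        rec = generate_recording("s1", "wake", "SF", cfg.effects, cfg, seed=1)
        assert rec.n_samples == 15360
        assert rec.n_channels == 2
        assert np.all(np.isfinite(rec.data))

    def test_alpha_knob_raises_alpha_power(self):
        base = StateEffects(hurst_target=0.6, alpha_amp=0.4, hf_amp=0.3,
                            base_amp=0.0, fgn_amp=1.0)
        boosted = StateEffects(hurst_target=0.6, alpha_amp=0.8, hf_amp=0.3,
                               base_amp=0.0, fgn_amp=1.0)
        diffs = []
        for seed in range(20):
            vals = []
            for eff in (base, boosted):
                ge = GroupEffects({("SF", "wake"): eff})
                cfg = CohortConfig(n_patients=4, effects=ge, duration=8.0,
                                   n_channels=2, seed=0)
                rec = generate_recording("s", "wake", "SF", ge, cfg, seed=seed)
                rec = preprocess_recording(rec, PreprocessConfig(segment_s=8.0))
                powers, _ = band_psd(rec.data[0], 256.0)
                vals.append(powers["alpha"])
            diffs.append(vals[1] - vals[0])
        assert np.mean(diffs) > 0
        assert np.mean(np.array(diffs) > 0) > 0.9

    def test_hf_knob_raises_mobility(self):
        base = StateEffects(hurst_target=0.6, alpha_amp=0.4, hf_amp=0.2,
                            base_amp=0.0, fgn_amp=1.0)
        boosted = StateEffects(hurst_target=0.6, alpha_amp=0.4, hf_amp=0.4,
                               base_amp=0.0, fgn_amp=1.0)
        diffs = []
        for seed in range(20):
            vals = []
            for eff in (base, boosted):
                ge = GroupEffects({("SF", "sleep"): eff})
                cfg = CohortConfig(n_patients=4, effects=ge, duration=8.0,
                                   n_channels=2, seed=0)
                rec = generate_recording("s", "sleep", "SF", ge, cfg, seed=seed)
                rec = preprocess_recording(rec, PreprocessConfig(segment_s=8.0))
                vals.append(hjorth(rec.data[0])[1])
            diffs.append(vals[1] - vals[0])
        assert np.mean(diffs) > 0
        assert np.mean(np.array(diffs) > 0) > 0.9

    def test_hurst_knob_raises_hurst_estimate(self):
        diffs = []
        for seed in range(20):
            vals = []
            for h in (0.55, 0.75):
                eff = StateEffects(hurst_target=h, alpha_amp=0.2, hf_amp=0.15,
                                   base_amp=0.0, fgn_amp=1.0)
                ge = GroupEffects({("SF", "sleep"): eff})
                cfg = CohortConfig(n_patients=4, effects=ge, duration=10.0,
                                   n_channels=2, seed=0)
                rec = generate_recording("s", "sleep", "SF", ge, cfg, seed=seed)
                rec = preprocess_recording(rec, PreprocessConfig(segment_s=10.0))
                vals.append(hurst_rs(rec.data[0]))
            diffs.append(vals[1] - vals[0])
        assert np.mean(diffs) > 0

    def test_missing_cell_rejected(self):
        ge = GroupEffects({("SF", "wake"):
                           StateEffects(hurst_target=0.6, alpha_amp=1, hf_amp=1)})
        cfg = CohortConfig(n_patients=4, effects=ge, duration=2.0,
                           n_channels=1, seed=0)
        with pytest.raises(KeyError):
            generate_recording("s", "sleep", "SF", ge, cfg, seed=0)


class TestGenerateCohort:
    def test_two_recordings_per_subject(self):
        recordings, labels = generate_cohort(small_config(n_patients=10))
        assert len(recordings) == 10
        assert len(labels) == 10
        assert set(labels) <= {0, 1}
        for wake, sleep in recordings:
            assert wake.state == "wake" and sleep.state == "sleep"
            assert wake.subject_id == sleep.subject_id

    def test_bit_reproducible(self):
        r1, l1 = generate_cohort(small_config(seed=7))
        r2, l2 = generate_cohort(small_config(seed=7))
        np.testing.assert_array_equal(l1, l2)
        for (w1, s1), (w2, s2) in zip(r1, r2):
            np.testing.assert_array_equal(w1.data, w2.data)
            np.testing.assert_array_equal(s1.data, s2.data)

    def test_seed_changes_data(self):
        r1, _ = generate_cohort(small_config(seed=1))
        r2, _ = generate_cohort(small_config(seed=2))
        assert not np.array_equal(r1[0][0].data, r2[0][0].data)

    def test_sf_rate_binomial(self):
        labels = draw_outcomes(2000, 0.594, seed=3)
        assert labels.mean() == pytest.approx(0.594, abs=0.03)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            small_config(n_patients=2)
        with pytest.raises(ValueError):
            small_config(sf_rate=1.5)
        with pytest.raises(ValueError):
            small_config(duration=1.0001)


class TestPresets:
    def test_reference_directions(self):
        eff = reference_effects()
        assert (eff.for_cell("SF", "sleep").hurst_target
                > eff.for_cell("NSF", "sleep").hurst_target)
        assert (eff.for_cell("SF", "wake").hurst_target
                < eff.for_cell("NSF", "wake").hurst_target)
        assert (eff.for_cell("SF", "sleep").alpha_amp
                > eff.for_cell("NSF", "sleep").alpha_amp)
        assert (eff.for_cell("SF", "sleep").hf_amp
                > eff.for_cell("NSF", "sleep").hf_amp)

    def test_null_preset_symmetric(self):
        eff = null_effects()
        for state in ("wake", "sleep"):
            assert eff.for_cell("SF", state) == eff.for_cell("NSF", state)
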