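"""Auditory-periphery front-end: tuning, transduction, adaptation, synchrony."""

import numpy as np
import pytest

from neurosid.an_periphery import (
    ANConfig,
    c1_filter,
    control_path_level,
    ihc_transduce,
    measure_bw10,
    middle_ear_filter,
    pure_tone,
    q10_base,
    rate_level_curve,
    simulate_periphery,
    synapse_adapt,
    vector_strength,
)
from neurosid.signal_io import AudioSignal

FS = 100_000.0


@pytest.fixture(scope="module")
def cfg_1k():
    return ANConfig(cfs=np.array([1000.0]))


def _single_fiber_rate(freq, level_db=70.0, duration=0.3, sr="high", cfg=None):
    cfg = cfg or ANConfig(cfs=np.array([float(freq)]))
    sig = pure_tone(freq, duration, FS, level_db)
    me = middle_ear_filter(sig, FS)
    env = control_path_level(me.samples, float(cfg.cfs[0]), cfg)
    bm = c1_filter(me.samples, float(cfg.cfs[0]), env, cfg)
    return synapse_adapt(ihc_transduce(bm, cfg), sr, cfg)


class TestMiddleEar:
    def test_near_unity_at_1khz(self):
        tone = pure_tone(1000, 0.2, FS, 70)
        out = middle_ear_filter(tone, FS)
        assert 0.7 <= out.rms() / tone.rms() <= 1.0

    def test_band_edges_attenuated(self):
        for freq in (50.0, 20000.0):
            tone = pure_tone(freq, 0.2, FS, 70)
            out = middle_ear_filter(tone, FS)
            tail = out.samples[out.samples.size // 2:]
            ratio = np.sqrt(np.mean(tail**2)) / tone.rms()
            assert 20 * np.log10(ratio) <= -20

    def test_dc_removed(self):
        sig = AudioSignal(np.full(20_000, 0.5), FS)
        out = middle_ear_filter(sig, FS)
        assert abs(out.samples[-5000:].mean()) < 1e-3 * 0.5

    def test_impulse_response_decays(self):
        x = np.zeros(5000)
        x[0] = 1.0
        out = middle_ear_filter(AudioSignal(x, FS), FS)
        e = out.samples**2
        assert e[-500:].sum() < 0.01 * e.sum()

    def test_wrong_rate_rejected(self):
        with pytest.raises(ValueError):
            middle_ear_filter(pure_tone(1000, 0.1, 20_000, 70), FS)


class TestControlPath:
    def test_silence_floored_at_zero(self, cfg_1k):
        env = control_path_level(np.zeros(10_000), 1000.0, cfg_1k)
        np.testing.assert_array_equal(env, 0.0)

    def test_on_cf_tone_level_calibrated(self, cfg_1k):
        sig = pure_tone(1000, 0.3, FS, 70)
        env = control_path_level(sig.samples, 1000.0, cfg_1k)
        assert env[-5000:].mean() == pytest.approx(70.0, abs=3.0)

    def test_linearity_in_db(self, cfg_1k):
        e60 = control_path_level(pure_tone(1000, 0.3, FS, 60).samples, 1000.0, cfg_1k)
        e70 = control_path_level(pure_tone(1000, 0.3, FS, 70).samples, 1000.0, cfg_1k)
        assert (e70[-5000:].mean() - e60[-5000:].mean()) == pytest.approx(10.0, abs=0.5)

    def test_smooth_no_big_jumps(self, cfg_1k):
        sig = pure_tone(1000, 0.1, FS, 80)
        env = control_path_level(sig.samples, 1000.0, cfg_1k)
        assert np.max(np.abs(np.diff(env))) < 6.0

    def test_cf_out_of_range_rejected(self, cfg_1k):
        with pytest.raises(ValueError):
            control_path_level(np.zeros(100), 50.0, cfg_1k)


class TestC1Filter:
    def test_q10_map_value_at_1khz(self):
        assert q10_base(1000.0) == pytest.approx(2.93, abs=0.01)

    def test_off_cf_attenuation_one_octave(self, cfg_1k):
        def response(freq):
            sig = pure_tone(freq, 0.2, FS, 40)
            env = control_path_level(sig.samples, 1000.0, cfg_1k)
            bm = c1_filter(sig.samples, 1000.0, env, cfg_1k)
            return np.sqrt(np.mean(bm[bm.size // 2:] ** 2))

        assert 20 * np.log10(response(500.0) / response(1000.0)) <= -20

    def test_compressive_growth_above_threshold(self, cfg_1k):
        def out_db(level):
            sig = pure_tone(1000, 0.2, FS, level)
            env = control_path_level(sig.samples, 1000.0, cfg_1k)
            bm = c1_filter(sig.samples, 1000.0, env, cfg_1k)
            return 20 * np.log10(np.sqrt(np.mean(bm[bm.size // 2:] ** 2)))

        growth = (out_db(85.0) - out_db(65.0)) / 20.0
        assert growth < 1.0

    @pytest.mark.parametrize("scale,expected", [(0.25, 4.0), (2.0, 0.5)])
    def test_bandwidth_knob(self, scale, expected):
        base = measure_bw10(1000.0, ANConfig(cfs=np.array([1000.0]), q10_scale=1.0))
        scaled = measure_bw10(1000.0, ANConfig(cfs=np.array([1000.0]), q10_scale=scale))
        assert scaled / base == pytest.approx(expected, rel=0.10)


class TestIhc:
    def test_zero_in_zero_out(self, cfg_1k):
        out = ihc_transduce(np.zeros(1000), cfg_1k)
        np.testing.assert_allclose(out, 0.0)

    def test_asymmetry_ratio_three_to_one(self, cfg_1k):
        # static nonlinearity before the low-pass: probe with DC steps
        pos = np.log1p(cfg_1k.ihc_b * 0.01)
        x = np.full(30_000, 0.01)
        up = ihc_transduce(x, cfg_1k)[-100:].mean()
        down = ihc_transduce(-x, cfg_1k)[-100:].mean()
        assert up / -down == pytest.approx(3.0, rel=1e-6)
        assert up == pytest.approx(pos, rel=1e-3)

    def test_ac_dc_ratio_falls_with_frequency(self):
        def ac_dc(freq):
            cfg = ANConfig(cfs=np.array([float(freq)]))
            sig = pure_tone(freq, 0.2, FS, 70)
            env = control_path_level(sig.samples, float(freq), cfg)
            bm = c1_filter(sig.samples, float(freq), env, cfg)
            pot = ihc_transduce(bm, cfg)
            tail = pot[pot.size // 2:]
            dc = tail.mean()
            ac = np.sqrt(np.mean((tail - dc) ** 2))
            return ac / dc

        assert ac_dc(500.0) > ac_dc(4000.0)


class TestSynapse:
    def test_silence_gives_spont_rate(self, cfg_1k):
        for sr, spont in zip(("high", "med", "low"), cfg_1k.sr_spont):
            rate = synapse_adapt(np.zeros(50_000), sr, cfg_1k)
            assert rate[-100:].mean() == pytest.approx(spont, abs=1e-9)

    def test_onset_exceeds_steady_state(self):
        rate = _single_fiber_rate(1000.0, level_db=70.0, duration=0.3)
        onset = rate[: int(0.010 * FS)].mean()
        steady = rate[-int(0.050 * FS):].mean()
        assert onset / steady >= 1.5

    def test_rate_level_compression(self):
        levels = [45.0, 50.0, 55.0, 75.0, 80.0, 85.0]
        rl = rate_level_curve(1000.0, levels)
        slope50 = (rl[2] - rl[0]) / 10.0
        slope80 = (rl[5] - rl[3]) / 10.0
        assert slope80 < slope50

    def test_step_increments_compress(self):
        rl = rate_level_curve(1000.0, [40.0, 70.0, 90.0])
        assert (rl[1] - rl[0]) > (rl[2] - rl[1])

    def test_unknown_sr_class_rejected(self, cfg_1k):
        with pytest.raises(ValueError):
            synapse_adapt(np.zeros(10), "ultra", cfg_1k)


class TestSimulatePeriphery:
    def test_silence_gives_weighted_spont(self):
        cfg = ANConfig(cfs=np.array([500.0, 1000.0, 2000.0]))
        sig = AudioSignal(np.zeros(30_000) + 1e-12, FS)
        out = simulate_periphery(sig, cfg)
        expected = sum(w * s for w, s in zip(cfg.sr_weights, cfg.sr_spont))
        np.testing.assert_allclose(out.rates[-100:], expected, atol=1e-6)

    def test_tonotopy_500hz_tone(self):
        # probed at a moderate level: at high levels the saturating synapse
        # flattens the AC-power profile across the skirt (synchrony spread)
        cfg = ANConfig()
        sig = pure_tone(500, 0.25, FS, 55)
        out = simulate_periphery(sig, cfg)
        tail = out.rates[out.rates.shape[0] // 2:]
        ac_power = ((tail - tail.mean(axis=0)) ** 2).mean(axis=0)
        best_cf = cfg.cfs[np.argmax(ac_power)]
        nearest = cfg.cfs[np.argmin(np.abs(cfg.cfs - 500.0))]
        assert best_cf == nearest

    def test_deterministic(self):
        cfg = ANConfig(cfs=np.array([500.0, 1500.0]))
        sig = pure_tone(700, 0.1, FS, 65)
        a = simulate_periphery(sig, cfg)
        b = simulate_periphery(sig, cfg)
        np.testing.assert_array_equal(a.rates, b.rates)

    def test_rates_nonnegative_finite(self, rng):
        cfg = ANConfig(cfs=np.array([250.0, 1000.0, 4000.0]))
        sig = AudioSignal(0.02 * rng.standard_normal(40_000), FS)
        out = simulate_periphery(sig, cfg)
        assert np.all(out.rates >= 0)
        assert np.all(np.isfinite(out.rates))


class TestVectorStrength:
    def test_constant_rate_near_zero(self):
        rate = np.full(100_000, 50.0)  # >= 100 cycles of 500 Hz at 100 kHz
        assert vector_strength(rate, 500.0, FS) < 0.02

    def test_rectified_sine_quarter_pi(self):
        # analytic oracle: half-wave rectified sine has VS = pi/4
        t = np.arange(200_000) / FS
        rate = np.maximum(0.0, np.sin(2 * np.pi * 500.0 * t))
        assert vector_strength(rate, 500.0, FS) == pytest.approx(np.pi / 4, abs=1e-3)

    def test_rolloff_500_above_4000(self):
        vs = {}
        for f in (500.0, 4000.0):
            rate = _single_fiber_rate(f)
            vs[f] = vector_strength(rate[rate.size // 3:], f, FS)
        assert vs[500.0] > vs[4000.0]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            vector_strength(np.zeros(100), 500.0, FS)


def test_config_validation():
    with pytest.raises(ValueError, match="sr_weights"):
        ANConfig(cfs=np.array([1000.0]), sr_weights=(0.5, 0.2, 0.2))
    with pytest.raises(ValueError, match="q10_scale"):
        ANConfig(cfs=np.array([1000.0]), q10_scale=0.0)
    with pytest.raises(ValueError, match="fs_model"):
        ANConfig(cfs=np.array([8000.0]), fs_model=100_000.0)
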