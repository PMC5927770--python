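"""Generator correctness: Hill curve, binomial moments, pool dynamics,
trace synthesis, and scenario determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import quantalysis as q
from quantalysis.simulate import (generate_scenario, kernel_peak_delay,
                                  mean_train_trajectory, psp_kernel,
                                  substream)


class TestReleaseProbability:
    def test_zero_calcium_gives_zero(self):
        assert q.release_probability_at(q.ReleaseModel(), 0.0) == 0.0

    @pytest.mark.parametrize("hill", [0.5, 1.0, 2.0, 4.0])
    def test_half_saturation(self, hill):
        m = q.ReleaseModel(p_max=0.8, ca_half=1.3, hill=hill)
        assert q.release_probability_at(m, 1.3) == pytest.approx(0.4)

    def test_hand_checked_value(self):
        # 0.6 * 3^2 / (1.5^2 + 3^2) = 0.6 * 9 / 11.25 = 0.48
        m = q.ReleaseModel(p_max=0.6, ca_half=1.5, hill=2.0)
        assert q.release_probability_at(m, 3.0) == pytest.approx(0.48)

    def test_negative_calcium_rejected(self):
        with pytest.raises(ValueError):
            q.release_probability_at(q.ReleaseModel(), -0.1)

    @given(st.floats(0.01, 20), st.floats(0.01, 20))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_and_bounded(self, ca1, ca2):
        m = q.ReleaseModel(p_max=0.85, ca_half=1.7, hill=2.2)
        lo, hi = sorted((ca1, ca2))
        p_lo = q.release_probability_at(m, lo)
        p_hi = q.release_probability_at(m, hi)
        assert 0 <= p_lo <= p_hi <= m.p_max


class TestEvokedAmplitudes:
    def test_saturated_deterministic(self):
        m = q.ReleaseModel(n_sites=20, p_max=1.0, ca_half=1.0, hill=1.0,
                           q_mean=0.5, q_cv=0.0)
        amps = q.draw_evoked_amplitudes(m, 1e9, 50, seed=0)
        assert np.allclose(amps, 20 * 0.5)

    def test_zero_probability_gives_zero(self):
        m = q.ReleaseModel()
        assert np.all(q.draw_evoked_amplitudes(m, 0.0, 20, seed=0) == 0)

    def test_binomial_moments(self):
        # N=100, p=0.3, Q=1, q_cv=0: mean 30, variance N p (1-p) = 21
        m = q.ReleaseModel(n_sites=100, p_max=0.3, ca_half=1.0, hill=1.0,
                           q_mean=1.0, q_cv=0.0)
        amps = q.draw_evoked_amplitudes(m, 1e12, 100_000, seed=3)
        se_mean = np.sqrt(21 / amps.size)
        assert abs(amps.mean() - 30) < 3 * se_mean
        se_var = 21 * np.sqrt(2 / (amps.size - 1))
        assert abs(amps.var(ddof=1) - 21) < 4 * se_var

    def test_quantal_variability_inflates_variance(self):
        # Var = N p (1-p) Q^2 + N p Q^2 cv^2 (independent gamma quanta)
        n, p, Q, cv = 80, 0.4, 0.7, 0.35
        m = q.ReleaseModel(n_sites=n, p_max=p, ca_half=1.0, hill=1.0,
                           q_mean=Q, q_cv=cv)
        amps = q.draw_evoked_amplitudes(m, 1e12, 100_000, seed=4)
        expected = n * p * (1 - p) * Q**2 + n * p * Q**2 * cv**2
        assert amps.var(ddof=1) == pytest.approx(expected, rel=0.03)

    def test_seed_reproducibility(self):
        m = q.ReleaseModel()
        a = q.draw_evoked_amplitudes(m, 1.5, 100, seed=9)
        b = q.draw_evoked_amplitudes(m, 1.5, 100, seed=9)
        assert np.array_equal(a, b)


class TestTrain:
    def test_no_release(self):
        pool = q.PoolModel(pool_size=100, release_fraction=0.0)
        tr = q.simulate_train(q.ReleaseModel(), pool, 3.0, seed=0)
        assert np.all(tr.amplitudes == 0)

    def test_single_shot_depletion(self):
        m = q.ReleaseModel(q_mean=0.5, q_cv=0.0)
        pool = q.PoolModel(pool_size=200, release_fraction=1.0,
                           replenish_rate=0.0)
        tr = q.simulate_train(m, pool, 3.0, n_stim=10, seed=0)
        assert tr.amplitudes[0] == pytest.approx(200 * 0.5)
        assert np.all(tr.amplitudes[1:] == 0)

    def test_steady_state_matches_mean_dynamics(self):
        m = q.ReleaseModel(q_mean=1.0, q_cv=0.0)
        pool = q.PoolModel(pool_size=500, release_fraction=0.25,
                           replenish_rate=60 * 31.25)
        expected = mean_train_trajectory(pool, 30, 60.0)[17:30].mean()
        tails = [q.simulate_train(m, pool, 3.0, n_stim=30, freq=60.0,
                                  seed=s).amplitudes[17:30].mean()
                 for s in range(30)]
        assert np.median(tails) == pytest.approx(expected, rel=0.05)

    def test_quanta_conservation(self):
        pool = q.PoolModel(pool_size=300, release_fraction=0.4,
                           replenish_rate=900.0)
        tr = q.simulate_train(q.ReleaseModel(), pool, 3.0, n_stim=40,
                              freq=60.0, seed=2)
        total_budget = pool.pool_size + 40 * pool.replenish_rate / 60.0
        assert tr.released.sum() <= total_budget


class TestTraceSynthesis:
    def test_flat_when_empty(self, quiet_config):
        tr = q.synthesize_trace([], quiet_config, seed=0)
        assert np.all(tr.samples == 0)

    def test_unit_peak_event(self, quiet_config):
        tr = q.synthesize_trace([(0.5, 3.0)], quiet_config, seed=0)
        peak_t = 0.5 + kernel_peak_delay(quiet_config.kernel_rise,
                                         quiet_config.kernel_decay)
        assert tr.samples.max() == pytest.approx(3.0, rel=1e-3)
        assert abs(np.argmax(tr.samples) / tr.sampling_rate - peak_t) < 5e-4

    def test_tevc_sign_and_holding(self):
        cfg = q.RecordingConfig(duration=1.0, noise_sd=0.0, mini_rate=0.0,
                                mode="tevc")
        tr = q.synthesize_trace([(0.5, 2.0)], cfg, seed=0)
        assert tr.samples.min() == pytest.approx(cfg.holding - 2.0, rel=1e-3)

    def test_integral_additivity(self, quiet_config):
        # total area equals number of events x single-kernel area
        fs = quiet_config.sampling_rate
        kt = np.arange(int(0.15 * fs)) / fs
        kernel_area = np.trapezoid(
            psp_kernel(kt, quiet_config.kernel_rise,
                       quiet_config.kernel_decay), dx=1 / fs)
        events = [(0.05 + 0.08 * i, 1.0) for i in range(20)]
        tr = q.synthesize_trace(events, quiet_config, seed=0)
        assert np.trapezoid(tr.samples, dx=1 / fs) == pytest.approx(
            20 * kernel_area, rel=1e-3)

    def test_event_outside_duration_rejected(self, quiet_config):
        with pytest.raises(ValueError, match="outside"):
            q.synthesize_trace([(5.0, 1.0)], quiet_config, seed=0)

    def test_minis_require_release_model(self):
        cfg = q.RecordingConfig(duration=1.0, mini_rate=1.0)
        with pytest.raises(ValueError, match="release_model"):
            q.synthesize_trace([], cfg, seed=0)


class TestScenario:
    def test_wild_type_symmetric(self):
        scen = q.wild_type_scenario()
        (m6r, m6p), (m7r, m7p) = scen.muscles["m6"], scen.muscles["m7"]
        assert vars(m6r) == vars(m7r) and vars(m6p) == vars(m7p)

    def test_knockdown_template_contrasts(self):
        scen = q.knockdown_scenario()
        kd_r, kd_p = scen.muscles["m6"]
        wt_r, wt_p = scen.muscles["m7"]
        assert kd_r.q_mean < wt_r.q_mean
        assert kd_p.pool_size > wt_p.pool_size
        assert kd_r.n_sites > wt_r.n_sites

    def test_generation_is_deterministic(self, tmp_path):
        scen = q.knockdown_scenario(seed=11)
        scen.recording.duration = 2.0
        scen.n_sweeps_per_level = 3
        m1 = generate_scenario(scen, tmp_path / "a")
        m2 = generate_scenario(scen, tmp_path / "b")
        assert m1.drop(columns="path").equals(m2.drop(columns="path"))
        for pa, pb in zip(sorted((tmp_path / "a").iterdir()),
                          sorted((tmp_path / "b").iterdir())):
            assert pa.read_bytes() == pb.read_bytes()

    def test_refuses_overwrite(self, tmp_path):
        scen = q.wild_type_scenario(seed=1)
        scen.recording.duration = 1.0
        scen.n_sweeps_per_level = 2
        generate_scenario(scen, tmp_path / "d")
        with pytest.raises(FileExistsError):
            generate_scenario(scen, tmp_path / "d")

    def test_substreams_independent(self):
        a = substream(3, "m6", "evoked", 1.5).normal(size=4)
        b = substream(3, "m7", "evoked", 1.5).normal(size=4)
        c = substream(3, "m6", "evoked", 1.5).normal(size=4)
        assert np.array_equal(a, c)
        assert not np.array_equal(a, b)
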