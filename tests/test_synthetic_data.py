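import numpy as np
import pytest

from boldhrf.acquisition import preset_9p4t
from boldhrf.errors import ConfigurationError, InvalidArgumentError
from boldhrf.synthetic_data import (
    HrfModel,
    NoiseModel,
    evaluate_train,
    make_hrf_kernel,
    simulate_roi_run,
    simulate_session,
    simulate_volume_run,
    trial_response,
)


class TestKernel:
    def test_all_zero_amplitudes_give_zero_curve(self):
        m = HrfModel(amplitude_percent=0.0, ring_amplitude_percent=0.0)
        k = make_hrf_kernel(m, 0.1, 25)
        assert k.shape == (251,)
        assert np.all(k == 0.0)

    def test_peak_time_is_literal_argmax(self):
        m = HrfModel(amplitude_percent=1.0, peak_time_seconds=5.0)
        k = make_hrf_kernel(m, 0.01, 30)
        assert 0.01 * np.argmax(k) == pytest.approx(5.0, abs=0.01)
        assert k.max() == pytest.approx(1.0, rel=0.01)
        assert k[0] == 0.0

    def test_undershoot_depth_matches_dense_grid_oracle(self):
        m = HrfModel(
            amplitude_percent=1.0,
            peak_time_seconds=5.0,
            dispersion_seconds=2.0,
            undershoot_ratio=0.3,
            undershoot_delay_seconds=10.0,
        )
        dense = make_hrf_kernel(m, 1e-3, 40)
        peak_idx = np.argmax(dense)
        assert dense[peak_idx:].min() == pytest.approx(-0.3, abs=0.01)

    def test_kernel_decays_to_zero_by_three_trial_periods(self):
        m = HrfModel(
            amplitude_percent=1.0,
            undershoot_ratio=0.3,
            ring_amplitude_percent=0.2,
        )
        k = make_hrf_kernel(m, 0.05, 3 * 26.25)
        assert abs(k[-1]) < 1e-6 * m.amplitude_percent

    def test_invalid_grid_rejected(self):
        m = HrfModel()
        with pytest.raises(InvalidArgumentError):
            make_hrf_kernel(m, 0.0, 20)
        with pytest.raises(InvalidArgumentError):
            make_hrf_kernel(m, 0.1, -5)
        with pytest.raises(InvalidArgumentError):
            make_hrf_kernel(m, 0.1, 2.0)  # shorter than peak time

    def test_generator_is_amplitude_additive(self):
        """Superposing two models' kernels equals the summed-amplitude kernel."""
        a = HrfModel(amplitude_percent=0.4, peak_time_seconds=5.0)
        b = HrfModel(amplitude_percent=0.8, peak_time_seconds=5.0)
        tot = HrfModel(amplitude_percent=1.2, peak_time_seconds=5.0)
        ka = make_hrf_kernel(a, 0.05, 30)
        kb = make_hrf_kernel(b, 0.05, 30)
        kt = make_hrf_kernel(tot, 0.05, 30)
        assert np.allclose(ka + kb, kt, atol=1e-12)

    def test_trial_response_peak_is_literal_amplitude(self):
        m = HrfModel(amplitude_percent=0.73)
        _, resp = trial_response(m, 2.0)
        assert resp.max() == pytest.approx(0.73, rel=1e-9)


class TestRoiRun:
    def test_zero_amplitude_zero_noise_is_constant(self, acq_uhf, quiet_noise):
        m = HrfModel(amplitude_percent=0.0)
        run = simulate_roi_run(acq_uhf, m, quiet_noise, baseline_intensity=1000.0)
        assert len(run) == acq_uhf.volumes_per_run
        assert np.all(run.values == 1000.0)

    def test_noiseless_run_equals_baseline_times_train(
        self, acq_uhf, plain_model, quiet_noise
    ):
        run = simulate_roi_run(acq_uhf, plain_model, quiet_noise, 1000.0)
        train = evaluate_train(acq_uhf.volume_times(), acq_uhf, plain_model)
        assert np.allclose(run.values, 1000.0 * (1 + train / 100.0))

    def test_trial_onset_volumes_sit_at_baseline(
        self, acq_uhf, plain_model, quiet_noise
    ):
        """The kernel starts at zero, so each trial-onset volume is baseline."""
        run = simulate_roi_run(acq_uhf, plain_model, quiet_noise, 1000.0)
        onset_vols = (
            acq_uhf.leadin_volumes
            + np.arange(acq_uhf.n_trials_per_run) * acq_uhf.samples_per_trial
        )
        assert np.allclose(run.values[onset_vols], 1000.0, atol=1e-6)

    def test_white_noise_sd_calibrated(self, acq_uhf):
        """Sample SD of a signal-free run matches the nominal percent SD."""
        m = HrfModel(amplitude_percent=0.0)
        sds = []
        for seed in range(50):
            noise = NoiseModel(white_sd_percent=0.5, seed=seed)
            run = simulate_roi_run(acq_uhf, m, noise, 1000.0)
            sds.append(100.0 * (run.values / 1000.0 - 1.0).std())
        assert np.mean(sds) == pytest.approx(0.5, abs=0.1)

    def test_identical_seed_bit_identical(self, acq_uhf, plain_model):
        noise = NoiseModel(white_sd_percent=1.0, ar1_coefficient=0.4,
                           drift_amplitude_percent=0.5, seed=99)
        a = simulate_roi_run(acq_uhf, plain_model, noise)
        b = simulate_roi_run(acq_uhf, plain_model, noise)
        assert np.array_equal(a.values, b.values)

    def test_session_has_independent_runs_and_truth(self, acq_uhf, plain_model):
        noise = NoiseModel(white_sd_percent=0.5, seed=7)
        runs = simulate_session(acq_uhf, plain_model, noise)
        assert len(runs) == acq_uhf.n_runs
        assert not np.array_equal(runs[0].values, runs[1].values)
        assert runs[0].meta["truth"] is plain_model
        again = simulate_session(acq_uhf, plain_model, noise)
        for r1, r2 in zip(runs, again):
            assert np.array_equal(r1.values, r2.values)

    def test_rician_floor_changes_distribution(self, acq_uhf):
        m = HrfModel(amplitude_percent=0.0)
        gauss = NoiseModel(white_sd_percent=1.0, seed=5)
        rice = NoiseModel(white_sd_percent=1.0, rician_floor=2.0, seed=5)
        g = simulate_roi_run(acq_uhf, m, gauss).values
        r = simulate_roi_run(acq_uhf, m, rice).values
        assert r.mean() > g.mean()  # magnitude noise biases upward


class TestVolumeRun:
    def test_single_voxel_matches_roi_run(self, plain_model, quiet_noise):
        acq = preset_9p4t(n_runs=1).with_(
            n_slices=1, slice_offsets=(0.0,), n_trials_per_run=2
        )
        labels = np.ones((1, 1, 1), dtype=int)
        vol, _ = simulate_volume_run(acq, labels, {1: plain_model}, quiet_noise)
        roi = simulate_roi_run(acq, plain_model, quiet_noise)
        assert np.allclose(vol[0, 0, 0], roi.values)

    def test_slice_offset_shifts_sampled_curve(self, plain_model, quiet_noise):
        """The later-acquired slice samples the response ahead by tr/2; a
        dense-interpolation oracle recovers that lag."""
        from scipy.interpolate import CubicSpline

        acq = preset_9p4t(n_runs=1).with_(n_slices=2, slice_offsets=(0.0, 0.625))
        labels = np.ones((1, 1, 2), dtype=int)
        vol, _ = simulate_volume_run(acq, labels, {1: plain_model}, quiet_noise)
        s0, s1 = vol[0, 0, 0], vol[0, 0, 1]
        t = acq.volume_times()
        spline = CubicSpline(t, s1)
        lags = np.linspace(-1.25, 1.25, 501)
        sse = [((spline(t[20:340] + L) - s0[20:340]) ** 2).sum() for L in lags]
        best = lags[int(np.argmin(sse))]
        # s1(t) = f(t + 0.625) so it matches s0 when evaluated 0.625 s earlier
        assert best == pytest.approx(-0.625, abs=0.01)

    def test_empty_mask_is_not_an_error(self, quiet_noise):
        acq = preset_9p4t(n_runs=1).with_(n_slices=2, n_trials_per_run=1)
        labels = np.zeros((2, 2, 2), dtype=int)
        vol, out_labels = simulate_volume_run(acq, labels, {}, quiet_noise)
        assert vol.shape == (2, 2, 2, acq.volumes_per_run)
        assert np.all(out_labels == 0)

    def test_unknown_label_raises_configuration_error(self, plain_model, quiet_noise):
        acq = preset_9p4t(n_runs=1).with_(n_slices=1, slice_offsets=(0.0,),
                                          n_trials_per_run=1)
        labels = np.full((1, 1, 1), 7, dtype=int)
        with pytest.raises(ConfigurationError):
            simulate_volume_run(acq, labels, {1: plain_model}, quiet_noise)


class TestNoiseModelValidation:
    @pytest.mark.parametrize(
        "bad",
        [
            {"white_sd_percent": -0.1},
            {"ar1_coefficient": 1.0},
            {"drift_period_seconds": 0.0},
            {"rician_floor": -1.0},
        ],
    )
    def test_invalid_noise_rejected(self, bad):
        with pytest.raises(InvalidArgumentError):
            NoiseModel(**bad)
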