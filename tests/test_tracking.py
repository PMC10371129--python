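"""Echo tracking: reference building, delay estimation, displacement recovery."""

import dataclasses

import numpy as np
import pytest

from mrar import (
    AcquisitionConfig,
    CoagulationTrajectory,
    assemble_matrix,
    build_reference,
    delay_to_displacement,
    estimate_delay,
    simulate_run,
    track_measurement,
)
from mrar.simulate import echo_pulse

from conftest import dho_trajectory


def brute_force_ncc_lag(reference, echo_segment, max_lag):
    """Independent exhaustive integer-lag normalized cross-correlation scan."""
    n = len(reference)
    best_lag, best_c = None, -np.inf
    for lag in range(-max_lag, max_lag + 1):
        window = echo_segment[lag + max_lag : lag + max_lag + n]
        denom = np.linalg.norm(reference) * np.linalg.norm(window)
        c = float(reference @ window) / denom if denom > 0 else 0.0
        if c > best_c:
            best_c, best_lag = c, lag
    return best_lag, best_c


def bandlimited_shift(x, shift_samples):
    f = np.fft.fftfreq(len(x))
    return np.real(np.fft.ifft(np.fft.fft(x) * np.exp(-2j * np.pi * f * shift_samples)))


@pytest.fixture
def reference_echo():
    cfg = AcquisitionConfig()
    t = np.arange(400) / cfg.sampling_rate
    return cfg, echo_pulse(cfg, t, 2.0e-6)


class TestEstimateDelay:
    def test_autocorrelation_zero_delay_unit_peak(self, reference_echo):
        cfg, ref = reference_echo
        est = estimate_delay(ref, ref, 0.1e-6, cfg.sampling_rate)
        assert est.delay == pytest.approx(0.0, abs=1e-12)
        assert est.peak == pytest.approx(1.0, abs=1e-9)
        assert not est.low_confidence

    def test_integer_shift_recovered_exactly(self, reference_echo):
        cfg, ref = reference_echo
        echo = np.roll(ref, 3)
        est = estimate_delay(ref, echo, 0.1e-6, cfg.sampling_rate)
        assert est.delay * cfg.sampling_rate == pytest.approx(3.0, abs=1e-9)

    def test_matches_brute_force_scan_on_seeded_pairs(self, reference_echo):
        cfg, ref = reference_echo
        rng = np.random.default_rng(2024)
        max_lag = int(round(0.1e-6 * cfg.sampling_rate))
        for _ in range(100):
            shift = int(rng.integers(-8, 9))
            noisy = np.roll(ref, shift) + rng.normal(0, 0.05, len(ref))
            segment = np.pad(noisy, max_lag)
            oracle_lag, _ = brute_force_ncc_lag(ref, segment, max_lag)
            est = estimate_delay(ref, noisy, 0.1e-6, cfg.sampling_rate)
            assert abs(est.delay * cfg.sampling_rate - oracle_lag) <= 0.5

    def test_subsample_shift_within_tenth_of_sample(self, reference_echo):
        cfg, ref = reference_echo
        echo = bandlimited_shift(ref, 2.5)
        est = estimate_delay(ref, echo, 0.1e-6, cfg.sampling_rate)
        assert abs(est.delay * cfg.sampling_rate - 2.5) < 0.1

    def test_low_confidence_flag_on_uncorrelated_input(self, reference_echo):
        cfg, ref = reference_echo
        rng = np.random.default_rng(5)
        est = estimate_delay(ref, rng.normal(size=len(ref)), 0.1e-6, cfg.sampling_rate)
        assert est.low_confidence


class TestDelayToDisplacement:
    def test_ten_ns_is_7_4_um_at_1480(self):
        assert delay_to_displacement(10e-9, 1480.0) == pytest.approx(7.4e-6, rel=1e-12)

    def test_zero_and_sign_symmetry(self):
        assert delay_to_displacement(0.0, 1480.0) == 0.0
        assert delay_to_displacement(-10e-9, 1480.0) == pytest.approx(-7.4e-6, rel=1e-12)

    def test_positive_sound_speed_required(self):
        with pytest.raises(ValueError):
            delay_to_displacement(1e-9, 0.0)


class TestBuildReference:
    def test_identical_baselines_reproduce_any_row(self, clean_config):
        archive, _ = simulate_run(clean_config, [dho_trajectory()])
        rec = archive.measurements(0)[0]
        ref = build_reference(rec, clean_config)
        row = rec.baseline_alines[0]
        np.testing.assert_allclose(
            ref.samples, row[ref.gate_start : ref.gate_start + len(ref.samples)], rtol=1e-12
        )

    def test_averaging_reduces_jitter_variance(self):
        cfg = AcquisitionConfig(
            total_duration=0.0, n_channels=1, noise_snr_db=np.inf, amplitude_jitter=0.05
        )
        archive, _ = simulate_run(cfg, [dho_trajectory()], seed=3)
        rec = archive.measurements(0)[0]
        ref = build_reference(rec, cfg)
        rows = rec.baseline_alines[:, ref.gate_start : ref.gate_start + len(ref.samples)]
        spread_single = np.mean(np.var(rows, axis=0))
        spread_mean = np.mean((ref.samples - rows.mean(axis=0)) ** 2)
        assert spread_mean == 0.0 and spread_single > 0.0

    def test_zero_baseline_pulses_rejected(self, clean_config):
        archive, _ = simulate_run(clean_config, [dho_trajectory()])
        rec = archive.measurements(0)[0]
        rec2 = dataclasses.replace(
            rec,
            alines=rec.detection_alines,
            pulse_roles=np.array(["detection"] * clean_config.n_detection_pulses),
        )
        with pytest.raises(ValueError, match="baseline"):
            build_reference(rec2, clean_config)


class TestTrackMeasurement:
    def test_static_surface_tracks_to_zero(self, dho_config):
        traj = dho_trajectory(amp=1e-12)  # essentially motionless
        archive, _ = simulate_run(dho_config, [traj])
        trace = track_measurement(archive.measurements(0)[0], dho_config)
        assert np.max(np.abs(trace.displacement)) < 1e-8

    def test_dho_recovered_noise_free(self, dho_config):
        archive, truth = simulate_run(dho_config, [dho_trajectory(f=300.0, amp=20e-6)])
        trace = track_measurement(archive.measurements(0)[0], dho_config)
        err = trace.displacement - truth.channel(0).displacement_true[0]
        assert np.sqrt(np.mean(err**2)) < 0.05e-6

    def test_dho_recovered_at_30db_snr(self):
        cfg = AcquisitionConfig(total_duration=0.0, n_channels=1, noise_snr_db=30.0, seed=8)
        archive, truth = simulate_run(cfg, [dho_trajectory(f=300.0, amp=20e-6)])
        trace = track_measurement(archive.measurements(0)[0], cfg)
        err = trace.displacement - truth.channel(0).displacement_true[0]
        assert np.sqrt(np.mean(err**2)) < 1e-6

    def test_linearity_in_programmed_amplitude(self, dho_config):
        recovered = {}
        for alpha in (0.1, 1.0, 2.0):
            archive, _ = simulate_run(dho_config, [dho_trajectory(amp=alpha * 10e-6)])
            trace = track_measurement(archive.measurements(0)[0], dho_config)
            recovered[alpha] = trace.displacement
        for alpha in (0.1, 2.0):
            scale = np.linalg.norm(recovered[alpha]) / np.linalg.norm(recovered[1.0])
            assert scale == pytest.approx(alpha, rel=0.01)

    def test_invariance_under_amplitude_jitter(self):
        base = AcquisitionConfig(total_duration=0.0, n_channels=1, noise_snr_db=np.inf,
                                 amplitude_jitter=0.0)
        jit = dataclasses.replace(base, amplitude_jitter=0.05)
        a0, _ = simulate_run(base, [dho_trajectory()], seed=4)
        a1, _ = simulate_run(jit, [dho_trajectory()], seed=4)
        t0 = track_measurement(a0.measurements(0)[0], base)
        t1 = track_measurement(a1.measurements(0)[0], jit)
        rms = np.sqrt(np.mean((t0.displacement - t1.displacement) ** 2))
        assert rms < 0.1e-6


class TestAssembleMatrix:
    def test_rows_sorted_by_observation_time(self, clean_config):
        archive, _ = simulate_run(clean_config, [dho_trajectory()])
        traces = [track_measurement(r, clean_config) for r in archive.measurements(0)]
        m1 = assemble_matrix(traces)
        m2 = assemble_matrix(traces[::-1])
        np.testing.assert_array_equal(m1.matrix, m2.matrix)
        assert np.all(np.diff(m1.observation_times) > 0)
        assert m1.matrix.shape[0] == 3  # T = 0, 6, 12

    def test_missing_measurement_becomes_flagged_gap(self, clean_config):
        archive, _ = simulate_run(clean_config, [dho_trajectory()])
        traces = [track_measurement(r, clean_config) for r in archive.measurements(0)]
        expected = np.array([t.observation_time_T for t in traces])
        m = assemble_matrix([traces[0], traces[2]], expected_times=expected)
        assert m.gap.tolist() == [False, True, False]
        assert np.all(np.isnan(m.matrix[1]))

    def test_mixed_channels_rejected(self, clean_config):
        archive, _ = simulate_run(clean_config, [dho_trajectory()])
        traces = [track_measurement(r, clean_config) for r in archive.measurements(0)]
        other = dataclasses.replace(traces[1], channel_id=7)
        with pytest.raises(ValueError, match="channel"):
            assemble_matrix([traces[0], other])
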