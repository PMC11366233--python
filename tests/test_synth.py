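"""Generator contracts: reproducibility, waveform morphology, sensor models,
stance-only logging and session structure."""

from __future__ import annotations

import numpy as np
import pytest

from grfest import synth
from grfest.preprocess import compute_cop_trace
from grfest.synth import G


class TestCohort:
    def test_seed_reproducibility(self):
        assert synth.generate_cohort(2, seed=7) == synth.generate_cohort(2, seed=7)

    def test_masses_within_truncation_bounds(self):
        cfg = synth.CohortConfig()
        cohort = synth.generate_cohort(1000, seed=1, config=cfg)
        masses = np.array([p.mass for p in cohort])
        assert masses.min() >= cfg.mass_bounds[0] and masses.max() <= cfg.mass_bounds[1]

    def test_rearfoot_fraction_matches_configuration(self):
        cfg = synth.CohortConfig()
        cohort = synth.generate_cohort(1000, seed=1, config=cfg)
        frac_rear = np.mean([p.footstrike < 1.0 / 3.0 for p in cohort])
        assert abs(frac_rear - cfg.footstrike_props[0]) < 0.05

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            synth.CohortConfig(mass_sd=-1.0)
        with pytest.raises(ValueError):
            synth.generate_cohort(0, seed=1)

    def test_protocol_covers_three_gradients_and_speeds(self, profile):
        protocol = synth.generate_protocol(profile)
        gradients = {c.gradient for c in protocol}
        speeds = {round(c.speed, 3) for c in protocol}
        assert gradients == {1.0, 6.0, -4.0}
        assert len(speeds) >= 3


class TestGrfForwardModel:
    def test_flat_gradient_net_ap_impulse_zero(self, profile):
        rng = np.random.default_rng(0)
        cond = synth.Condition(speed=11.0, gradient=0.0, duration=30.0)
        _, gap = synth.generate_grf(profile, cond, 0.25, rng, noise_sd_bw=0.0)
        assert abs(np.trapezoid(gap)) / np.abs(gap).max() < 1e-10

    def test_forefoot_has_no_impact_transient(self, condition):
        fore = synth.ParticipantProfile("P", 70.0, 11.0, 270.0, 1.0, 0.03, 0)
        rng = np.random.default_rng(0)
        gv, _ = synth.generate_grf(fore, condition, 0.25, rng, noise_sd_bw=0.0)
        early = gv[: int(0.3 * len(gv))]
        # strictly rising into the active peak: no local maximum before 30%
        assert np.all(np.diff(early) >= -1e-12)

    def test_easy_speed_peak_in_physiological_band(self, profile):
        rng = np.random.default_rng(0)
        cond = synth.Condition(speed=profile.easy_speed, gradient=0.0, duration=30.0)
        gv, _ = synth.generate_grf(profile, cond, 0.25, rng, noise_sd_bw=0.0)
        assert 2.0 <= gv.max() / (profile.mass * G) <= 3.0

    def test_peak_increases_with_speed(self, profile):
        rng = np.random.default_rng(0)
        peaks = []
        for speed in (9.0, 11.0, 14.0):
            cond = synth.Condition(speed=speed, gradient=0.0, duration=30.0)
            gv, _ = synth.generate_grf(profile, cond, 0.25, rng, noise_sd_bw=0.0)
            peaks.append(gv.max())
        assert peaks[0] < peaks[1] < peaks[2]

    def test_gradient_shifts_braking_propulsion_balance(self, profile):
        rng = np.random.default_rng(0)
        imps = {}
        for grad in (-4.0, 0.0, 6.0):
            cond = synth.Condition(speed=11.0, gradient=grad, duration=30.0)
            _, gap = synth.generate_grf(profile, cond, 0.25, rng, noise_sd_bw=0.0)
            imps[grad] = np.trapezoid(gap)
        assert imps[-4.0] < imps[0.0] < imps[6.0]  # uphill -> net propulsion

    def test_zero_at_endpoints_and_nonnegative(self, profile, condition):
        rng = np.random.default_rng(0)
        gv, gap = synth.generate_grf(profile, condition, 0.3, rng, noise_sd_bw=0.0)
        assert gv[0] == gv[-1] == 0.0 and gap[0] == gap[-1] == 0.0
        assert np.all(gv >= 0.0)

    def test_invalid_duration_rejected(self, profile, condition):
        rng = np.random.default_rng(0)
        for bad in (-0.1, 0.0, 0.05, 0.7):
            with pytest.raises(ValueError):
                synth.generate_grf(profile, condition, bad, rng)


class TestPressureModel:
    def test_zero_force_zero_output(self, profile, geometry):
        cfg = synth.SessionConfig(fsr_noise_sd=0.0)
        rng = np.random.default_rng(0)
        raw, _ = synth.generate_pressures(np.zeros(100), profile, geometry, rng, cfg)
        assert np.all(raw == 0.0)

    def test_degenerate_kernel_hits_single_sensor(self, profile, geometry):
        cfg = synth.SessionConfig(fsr_noise_sd=0.0, kernel_width_mm=0.0)
        rng = np.random.default_rng(0)
        k = 5
        centroid = np.tile(geometry.sensor_coords[k], (50, 1))
        raw, _ = synth.generate_pressures(
            np.full(50, 500.0), profile, geometry, rng, cfg, centroid=centroid
        )
        active = np.flatnonzero(raw.any(axis=0))
        assert list(active) == [k]

    def test_force_conservation_under_inverse_transform(self, profile, geometry):
        cfg = synth.SessionConfig(fsr_noise_sd=0.0)
        rng = np.random.default_rng(3)
        gv = np.abs(rng.normal(800.0, 300.0, 200))
        raw, _ = synth.generate_pressures(gv, profile, geometry, rng, cfg)
        total = synth.invert_fsr(raw, cfg.fsr_a, cfg.fsr_b).sum(axis=1)
        assert np.allclose(total, gv, rtol=1e-6)

    def test_cop_of_inverted_forces_tracks_true_centroid(self, profile, geometry):
        cfg = synth.SessionConfig(fsr_noise_sd=0.0)
        rng = np.random.default_rng(4)
        cond = synth.Condition(11.0, 0.0, 30.0)
        gv, _ = synth.generate_grf(profile, cond, 0.25, rng, noise_sd_bw=0.0)
        raw, centroid = synth.generate_pressures(gv, profile, geometry, rng, cfg)
        forces = synth.invert_fsr(raw, cfg.fsr_a, cfg.fsr_b)
        mid = slice(25, len(gv) - 25)  # kernel truncation distorts near-zero-force tails
        cop = compute_cop_trace(forces[mid], geometry)
        err = np.linalg.norm(cop - centroid[mid], axis=1)
        # discrete 16-sensor grid quantizes the weighted mean: errors stay
        # within the spatial kernel width
        assert err.max() < cfg.kernel_width_mm
        assert np.median(err) < cfg.kernel_width_mm / 2.0

    def test_too_few_sensors_rejected(self, profile):
        with pytest.raises(ValueError):
            synth.InsoleGeometry(sensor_coords=np.array([[0.0, 10.0]]), insole_length=270.0)

    def test_negative_force_rejected(self, profile, geometry):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            synth.generate_pressures(np.array([-1.0, 0.0]), profile, geometry, rng)


class TestImuModel:
    def test_free_fall_convention(self, profile):
        cfg = synth.SessionConfig(accel_noise_sd_g=0.0, accel_wobble_g=0.0)
        rng = np.random.default_rng(0)
        accel = synth.generate_imu(np.zeros(500), np.zeros(500), profile, rng, cfg)
        assert np.allclose(accel[:, 2], -1.0)
        assert np.allclose(accel[:, :2], 0.0)

    def test_clipping_contract(self, profile):
        cfg = synth.SessionConfig(accel_noise_sd_g=0.0, accel_wobble_g=0.0)
        rng = np.random.default_rng(0)
        huge = np.full(300, 100.0 * profile.mass * G)
        accel = synth.generate_imu(huge, huge, profile, rng, cfg)
        assert accel.max() <= 30.0 and accel.min() >= -30.0

    def test_vertical_axis_tracks_grf(self, profile, condition):
        cfg = synth.SessionConfig(accel_noise_sd_g=0.0)
        rng = np.random.default_rng(1)
        gv, gap = synth.generate_grf(profile, condition, 0.25, rng, noise_sd_bw=0.0)
        accel = synth.generate_imu(gv, gap, profile, rng, cfg)
        t_in = np.arange(len(gv)) / synth.FORCE_FS
        t_out = np.arange(len(accel)) / synth.IMU_FS
        gv_up = np.interp(t_out, t_in, gv)
        r = np.corrcoef(gv_up, accel[:, 2])[0, 1]
        assert r > 0.9


class TestPressureLogging:
    def test_constant_contact_gives_window_count_and_value(self):
        x = np.full(1000, 3.25)
        times, logged = synth.emulate_pressure_logging(x, [(0.1, 0.2)])
        assert len(logged) == 5
        assert np.allclose(logged, 3.25)

    def test_linear_ramp_window_means(self):
        # ramp 0 -> 1 over a 40 ms contact: two windows of 20 samples each;
        # analytic means of samples k/39 for k in [0..19] and [20..39]
        x = np.zeros(2000)
        ramp = np.linspace(0.0, 1.0, 40)
        x[1000:1040] = ramp
        _, logged = synth.emulate_pressure_logging(x, [(1.0, 1.04)])
        assert len(logged) == 2
        assert np.allclose(logged, [ramp[:20].mean(), ramp[20:].mean()])

    def test_no_samples_outside_intervals(self):
        rng = np.random.default_rng(0)
        x = rng.random(3000)
        times, logged = synth.emulate_pressure_logging(x, [(0.5, 0.75), (1.5, 1.8)])
        inside = ((times >= 0.5) & (times < 0.75)) | ((times >= 1.5) & (times < 1.8))
        assert inside.all()

    def test_subwindow_interval_yields_partial_sample(self):
        x = np.full(1000, 2.0)
        times, logged = synth.emulate_pressure_logging(x, [(0.1, 0.111)])
        assert len(logged) == 1 and logged[0] == 2.0

    def test_unsorted_intervals_rejected(self):
        with pytest.raises(ValueError):
            synth.emulate_pressure_logging(np.zeros(100), [(0.05, 0.08), (0.0, 0.03)])


class TestSession:
    def test_seed_reproducibility(self, profile, condition):
        a = synth.generate_session(profile, condition, seed=3)
        b = synth.generate_session(profile, condition, seed=3)
        assert np.array_equal(a.force.vertical, b.force.vertical)
        assert np.array_equal(a.pressure.values, b.pressure.values)
        assert np.array_equal(a.imu.accel, b.imu.accel)
        assert a.device_offsets == b.device_offsets

    def test_truth_intervals_sorted_nonoverlapping(self, session):
        iv = session.truth.contact_intervals
        assert np.all(iv[:, 1] > iv[:, 0])
        assert np.all(iv[1:, 0] >= iv[:-1, 1])

    def test_pressure_only_inside_contacts(self, session):
        # every logged pressure timestamp (device clock) maps into a truth interval
        t_master = session.pressure.times + session.device_offsets["pressure"]
        iv = session.truth.contact_intervals
        ok = [
            np.any((iv[:, 0] - 1e-9 <= t) & (t < iv[:, 1] + 1e-9)) for t in t_master
        ]
        assert all(ok)

    def test_devices_disagree_on_first_contact(self, profile, condition):
        # pressure device starts 1.5 s after the force device: it must miss
        # the leading truth contacts that the force stream records
        s = synth.generate_session(
            profile, condition, seed=2, offset_shifts={"pressure": 1.5, "imu": 0.0}
        )
        iv = s.truth.contact_intervals

        def first_contact(dev: str) -> int:
            start = s.device_offsets[dev]
            return int(np.argmax(iv[:, 0] >= start))

        assert first_contact("force") == 0
        assert first_contact("pressure") >= 1
        # and the logged pressure stream indeed lacks those leading contacts
        n_pressure_contacts = 1 + int(np.sum(np.diff(s.pressure.times) > 0.03))
        assert n_pressure_contacts < len(iv)
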