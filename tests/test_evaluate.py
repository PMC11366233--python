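"""Agreement metrics, Bland-Altman, PFI and the LOSO driver."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import integrate, stats

from grfest import evaluate, features, model
from grfest.evaluate import (
    bland_altman,
    contact_metrics,
    cop_error_profile,
    pfi,
    run_loso,
    touchdown_cop_y,
)
from grfest.features import apply_standardizer, fit_standardizer
from grfest.model import ModelConfig, TrainedEstimator, build_model


def oracle_metrics(measured, estimated):
    """Straight-from-definition re-implementation, term by term."""
    diff = estimated - measured
    rmse = np.sqrt(sum(d * d for d in diff) / len(diff))
    rrmse = 100.0 * rmse / (max(measured) - min(measured))
    r = stats.pearsonr(measured, estimated).statistic
    peak = 100.0 * (max(estimated) - max(measured)) / max(measured)
    imp_m = integrate.trapezoid(measured)
    imp_e = integrate.trapezoid(estimated)
    impulse = 100.0 * (imp_e - imp_m) / imp_m
    return rmse, rrmse, r, peak, impulse


class TestContactMetrics:
    def test_perfect_agreement(self):
        m = np.sin(np.linspace(0, np.pi, 400)) * 2.5
        res = contact_metrics(m, m.copy(), mass=70.0)
        assert res.rmse_bw == 0.0 and res.rrmse == 0.0
        assert res.peak_diff_pct == 0.0 and res.impulse_diff_pct == 0.0
        assert res.pearson_r == pytest.approx(1.0)

    def test_constant_offset_gives_ten_percent_rrmse(self):
        m = np.linspace(1.0, 2.0, 400)  # range exactly 1.0
        res = contact_metrics(m, m + 0.1, mass=70.0)
        assert res.rrmse == pytest.approx(10.0)

    def test_matches_definition_oracle_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            m = rng.normal(2.0, 0.5, 100) + np.sin(np.linspace(0, np.pi, 100))
            e = m + rng.normal(0.0, 0.2, 100)
            res = contact_metrics(m, e, mass=70.0)
            rmse_o, rrmse_o, r_o, peak_o, imp_o = oracle_metrics(m, e)
            assert res.rmse_bw == pytest.approx(rmse_o)
            assert res.rrmse == pytest.approx(rrmse_o)
            assert res.pearson_r == pytest.approx(r_o)
            assert res.peak_diff_pct == pytest.approx(peak_o)
            assert res.impulse_diff_pct == pytest.approx(imp_o)

    def test_anteroposterior_peaks(self):
        t = np.linspace(0, 1, 400)
        m = -0.3 * np.sin(2 * np.pi * t)
        e = m.copy()
        e[np.argmin(m)] -= 0.05  # deeper braking trough
        res = contact_metrics(m, e, mass=70.0, component="grf_ap")
        assert res.peak_braking_diff_bw == pytest.approx(-0.05)
        assert res.peak_braking_diff_n == pytest.approx(-0.05 * 70.0 * 9.81)
        assert res.peak_propulsive_diff_bw == pytest.approx(0.0)

    def test_flat_measured_trace_rejected(self):
        with pytest.raises(ValueError):
            contact_metrics(np.full(400, 2.0), np.zeros(400), mass=70.0)


class TestBlandAltman:
    def test_perfect_agreement(self):
        m = np.linspace(2.0, 3.0, 10)
        res = bland_altman(m, m.copy())
        assert res.bias == 0.0 and res.loa_low == 0.0 and res.loa_high == 0.0
        assert res.slope == pytest.approx(0.0)

    def test_normal_differences_closed_form(self):
        rng = np.random.default_rng(11)
        m = rng.uniform(2.0, 3.0, 10_000)
        d = rng.normal(0.2, 0.1, 10_000)
        res = bland_altman(m, m + d)
        assert res.bias == pytest.approx(0.2, abs=0.01)
        assert res.loa_low == pytest.approx(0.2 - 1.96 * 0.1, abs=0.01)
        assert res.loa_high == pytest.approx(0.2 + 1.96 * 0.1, abs=0.01)
        coverage = np.mean((d >= res.loa_low) & (d <= res.loa_high))
        assert coverage == pytest.approx(0.95, abs=0.01)

    def test_proportional_bias_slope(self):
        m = np.linspace(1.5, 3.5, 200)
        d = 0.3 * (m - 2.5)  # 0.3 BW change in error per BW of measured force
        res = bland_altman(m, m + d)
        assert res.slope == pytest.approx(0.3)
        assert res.bias == pytest.approx(0.0, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class _SingleChannelNet:
    """Toy estimator interface: output = weight * channel `ch` of the input."""

    def __init__(self, ch: int, weight: float = 1.0):
        self.ch, self.weight = ch, weight

    def predict(self, x):
        return self.weight * x[:, :, self.ch]


def _stub_estimator(ch: int, weight: float = 1.0) -> TrainedEstimator:
    return TrainedEstimator(net=_SingleChannelNet(ch, weight), config=ModelConfig())


class TestPfi:
    def _features(self, rng, n=20):
        vals = rng.standard_normal((n, 400, 26))
        return features.FeatureMatrix(values=vals, standardized=True)

    def test_ignored_channel_is_exactly_one(self):
        rng = np.random.default_rng(0)
        fm = self._features(rng)
        est = _stub_estimator(ch=0)
        targets = fm.values[:, :, 0].copy()
        res = pfi(est, fm, targets + 0.5, channel="insole_length", n_reps=5, seed=1)
        assert res.pfi == 1.0
        assert np.all(res.per_rep == 1.0)

    def test_ignored_channel_on_real_network(self, small_features):
        # zero the input weights of one channel in both LSTM directions:
        # the network provably cannot see it
        fm, tg = small_features
        std = fit_standardizer(fm)
        z = apply_standardizer(std, fm)
        est = build_model(
            ModelConfig(lstm_hidden=8, linear2_size=4, linear3_size=4, seed=2), dtype="float64"
        )
        ch = z.channel("insole_length")
        est.net.params["Wx_f"][ch, :] = 0.0
        est.net.params["Wx_b"][ch, :] = 0.0
        res = pfi(est, z, tg, channel="insole_length", n_reps=3, seed=0)
        assert res.pfi == 1.0

    def test_corrupting_sole_predictor_degrades_rmse(self):
        rng = np.random.default_rng(2)
        fm = self._features(rng)
        est = _stub_estimator(ch=0)
        targets = fm.values[:, :, 0] + 0.1 * rng.standard_normal((20, 400))
        res = pfi(est, fm, targets, channel=0, n_reps=20, seed=3)
        assert res.pfi > 1.0

    def test_linear_toy_model_closed_form(self):
        # net output = w * x_ch, targets = 0  =>  base RMSE = |w| * rms(x_ch);
        # after substitution RMSE -> |w| * rms(z), z ~ N(0,1), so
        # E[pfi] ~ 1 / rms(x_ch) at large sample sizes
        rng = np.random.default_rng(4)
        fm = self._features(rng, n=50)
        fm.values[:, :, 3] *= 2.0  # rms(x_3) = 2
        est = _stub_estimator(ch=3, weight=1.7)
        targets = np.zeros((50, 400))
        res = pfi(est, fm, targets, channel=3, n_reps=1000, seed=5)
        expected = 1.0 / np.sqrt(np.mean(fm.values[:, :, 3] ** 2))
        assert res.pfi == pytest.approx(expected, rel=0.01)

    def test_unknown_channel_rejected(self, small_features):
        fm, tg = small_features
        std = fit_standardizer(fm)
        z = apply_standardizer(std, fm)
        est = _stub_estimator(0)
        with pytest.raises(ValueError):
            pfi(est, z, tg, channel="gyro_x")


class TestCopErrorProfile:
    def test_identical_cop_single_bin(self, contacts):
        sub = contacts[:5]
        errors = np.arange(5.0)
        prof = cop_error_profile(sub, errors, n_bins=10)
        # all contacts are from one runner at one condition: touchdown
        # positions fall in at most 2 adjacent bins
        assert len(prof) <= 2

    def test_linear_errors_monotone_bins(self):
        # synthetic profile: construct contacts-like objects via namespace
        class FakeContact:
            def __init__(self, pos):
                self.pressure = np.ones((400, 16))
                self.cop_y = np.full(400, pos * 270.0)
                self.insole_length = 270.0

        positions = np.linspace(0.1, 0.9, 50)
        fakes = [FakeContact(p) for p in positions]
        errors = 2.0 * positions + 1.0
        prof = cop_error_profile(fakes, errors, n_bins=5)
        assert prof["mean"].is_monotonic_increasing

    def test_matches_group_by_oracle(self, contacts):
        rng = np.random.default_rng(6)
        errors = rng.normal(0.0, 1.0, len(contacts))
        prof = cop_error_profile(contacts, errors, n_bins=4)
        pos = np.array([touchdown_cop_y(c) for c in contacts])
        which = np.clip((pos * 4).astype(int), 0, 3)
        for _, row in prof.iterrows():
            sel = errors[which == int(row["bin"])]
            assert row["n"] == len(sel)
            assert row["mean"] == pytest.approx(sel.mean())

    def test_too_few_bins_rejected(self, contacts):
        with pytest.raises(ValueError):
            cop_error_profile(contacts, np.zeros(len(contacts)), n_bins=1)


class TestRunLoso:
    CFG = ModelConfig(
        learning_rate=3e-3, n_epochs=3, batch_size=8, lstm_hidden=8,
        input_dropout=0.0, linear_dropout=0.0, linear2_size=4, linear3_size=4, seed=7,
    )

    def test_structural_soundness(self, small_features):
        fm, tg = small_features
        report = run_loso(fm, tg, self.CFG, dtype="float32")
        pids = sorted(set(fm.participant_ids))
        assert sorted(report.per_contact["participant_id"].unique()) == pids
        assert not report.failed_folds
        # each participant's contacts all evaluated exactly once
        counts = report.per_contact.groupby("participant_id").size()
        for pid in pids:
            assert counts[pid] == int(np.sum(fm.participant_ids == pid))

    def test_duplicated_participant_rejected(self, small_features):
        fm, tg = small_features
        with pytest.raises(ValueError):
            run_loso(fm, tg, self.CFG, participants=["P000", "P000", "P001"])

    def test_standardized_input_rejected(self, small_features):
        fm, tg = small_features
        z = apply_standardizer(fit_standardizer(fm), fm)
        with pytest.raises(ValueError):
            run_loso(z, tg, self.CFG)

    def test_fewer_than_three_participants_rejected(self, small_features):
        fm, tg = small_features
        keep = fm.participant_ids == fm.participant_ids[0]
        sub = features.FeatureMatrix(
            values=fm.values[keep],
            contact_index=[ci for ci, k in zip(fm.contact_index, keep) if k],
            standardized=False,
        )
        with pytest.raises(ValueError):
            run_loso(sub, tg[keep], self.CFG)
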