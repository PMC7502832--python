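"""Map-estimation chain: ESTATICS, dual-angle inversion, MT, receive, PD."""

import numpy as np
import pytest

from mpmtools.mapfit import (
    MPMModel,
    calibrate_pd,
    estatics_fit,
    estimate_a,
    estimate_mt,
    estimate_r1,
    receive_bias_datadriven,
    receive_sensitivity_from_ratio,
)
from mpmtools.phantom import SiteEffect, make_smooth_field, simulate_session
from mpmtools.protocols import vendor_protocols
from mpmtools.signal import SignalParams, spgr_signal_rational
from mpmtools.volumes import AcquisitionVolume


def _volume(contrast, s0, r2s, vendor="siemens", shape=(4, 4, 4)):
    proto = vendor_protocols(vendor)[contrast]
    s0 = np.broadcast_to(np.asarray(s0, float), shape)
    r2s = np.broadcast_to(np.asarray(r2s, float), shape)
    data = np.stack([s0 * np.exp(-te * r2s) for te in proto.te_s], axis=-1)
    return AcquisitionVolume(data, proto)


class TestEstatics:
    def test_noiseless_single_contrast_exact(self):
        vol = _volume("PDw", 100.0, 20.0)
        s0, r2s, residual, mask = estatics_fit([vol])
        assert np.allclose(s0["PDw"], 100.0)
        assert np.allclose(r2s, 20.0)
        assert np.allclose(residual[mask], 0.0, atol=1e-12)

    def test_zero_decay_gives_flat_echoes_and_zero_slope(self):
        s0, r2s, _, _ = estatics_fit([_volume("T1w", 50.0, 0.0)])
        assert np.allclose(r2s, 0.0, atol=1e-12)
        assert np.allclose(s0["T1w"], 50.0)

    def test_joint_fit_equals_per_contrast_fits_on_shared_r2s(self):
        # oracle: three independent 2-parameter log-linear fits
        vols = {c: _volume(c, s0, 18.0) for c, s0 in
                (("MTw", 60.0), ("PDw", 80.0), ("T1w", 40.0))}
        s0, r2s, _, mask = estatics_fit(vols)
        for c, vol in vols.items():
            te = vol.protocol.te_s
            logs = np.log(vol.data[0, 0, 0])
            slope, intercept = np.polyfit(te, logs, 1)
            assert np.exp(intercept) == pytest.approx(s0[c][0, 0, 0], rel=1e-10)
            assert -slope == pytest.approx(r2s[0, 0, 0], rel=1e-10)

    def test_nonpositive_signal_masks_voxel(self):
        vol = _volume("PDw", 100.0, 20.0)
        vol.data[0, 0, 0, 3] = 0.0
        s0, r2s, _, mask = estatics_fit([vol])
        assert not mask[0, 0, 0]
        assert np.isnan(r2s[0, 0, 0])
        assert mask.sum() == mask.size - 1

    def test_single_echo_rejected(self):
        from mpmtools.protocols import with_deviation

        proto = with_deviation(vendor_protocols("siemens")["PDw"], te_ms=(2.46,))
        vol = AcquisitionVolume(np.ones((2, 2, 2, 1)), proto)
        with pytest.raises(ValueError, match="fewer than 2 echoes"):
            estatics_fit([vol])


class TestDualAngleInversion:
    # signals generated by the rational model itself: inversion is algebraic
    A_TRUE, R1_TRUE = 1000.0, 1.0
    A_PD, A_T1 = np.deg2rad(4.0), np.deg2rad(25.0)
    TR = 0.018

    def _signals(self):
        s_pd = spgr_signal_rational(
            SignalParams(self.A_TRUE, self.A_PD, self.TR, self.R1_TRUE))
        s_t1 = spgr_signal_rational(
            SignalParams(self.A_TRUE, self.A_T1, self.TR, self.R1_TRUE))
        return np.full((3, 3, 3), s_pd), np.full((3, 3, 3), s_t1)

    def test_round_trip_machine_precision(self):
        s_pd, s_t1 = self._signals()
        r1 = estimate_r1(s_pd, s_t1, self.A_PD, self.A_T1, self.TR, self.TR)
        a = estimate_a(s_pd, s_t1, self.A_PD, self.A_T1, self.TR, self.TR)
        assert np.allclose(r1, self.R1_TRUE, rtol=1e-12)
        assert np.allclose(a, self.A_TRUE, rtol=1e-12)

    def test_amplitude_is_degree_one_in_signals(self):
        s_pd, s_t1 = self._signals()
        a1 = estimate_a(s_pd, s_t1, self.A_PD, self.A_T1, self.TR, self.TR)
        a2 = estimate_a(2 * s_pd, 2 * s_t1, self.A_PD, self.A_T1, self.TR, self.TR)
        assert np.allclose(a2, 2 * a1, rtol=1e-12)

    def test_contrast_collapse_is_masked(self):
        s = np.full((2, 2, 2), 50.0)
        r1 = estimate_r1(s, s, self.A_PD, self.A_PD, self.TR, self.TR)
        assert np.all(np.isnan(r1))

    def test_exact_model_inputs_bias_below_5pct(self):
        # model-mismatch oracle over the plausible R1 range at protocol angles
        from mpmtools.signal import spgr_signal_exact

        for r1_true in np.linspace(0.5, 1.5, 11):
            s_pd = spgr_signal_exact(
                SignalParams(self.A_TRUE, self.A_PD, self.TR, r1_true))
            s_t1 = spgr_signal_exact(
                SignalParams(self.A_TRUE, self.A_T1, self.TR, r1_true))
            r1 = estimate_r1(np.atleast_1d(s_pd), np.atleast_1d(s_t1),
                             self.A_PD, self.A_T1, self.TR, self.TR)[0]
            a = estimate_a(np.atleast_1d(s_pd), np.atleast_1d(s_t1),
                           self.A_PD, self.A_T1, self.TR, self.TR)[0]
            assert abs(r1 - r1_true) / r1_true < 0.05
            assert r1 < r1_true  # approximation bias is consistently low
            assert abs(a - self.A_TRUE) / self.A_TRUE < 0.05


class TestEstimateMT:
    @pytest.mark.parametrize("tr_mt", [0.037, 0.048])
    def test_round_trip_recovers_2pu(self, tr_mt):
        alpha = np.deg2rad(6.0)
        s_mt = spgr_signal_rational(
            SignalParams(1000.0, alpha, tr_mt, 1.0, mt_delta=0.02))
        mt = estimate_mt(np.float64(1000.0), np.float64(1.0),
                         np.atleast_1d(s_mt), alpha, tr_mt)
        assert mt[0] == pytest.approx(2.0, abs=1e-10)

    def test_unsaturated_signal_gives_zero(self):
        alpha = np.deg2rad(6.0)
        s0 = spgr_signal_rational(SignalParams(1000.0, alpha, 0.037, 1.0))
        mt = estimate_mt(1000.0, 1.0, np.atleast_1d(s0), alpha, 0.037)
        assert mt[0] == pytest.approx(0.0, abs=1e-10)

    def test_threshold_and_nonpositive_signal_masked(self):
        alpha = np.deg2rad(6.0)
        mt = estimate_mt(1000.0, 1.0, np.array([-5.0, 1e-12]), alpha, 0.037)
        assert np.isnan(mt[0])       # non-positive signal
        assert np.isnan(mt[1])       # implausibly large saturation


class TestReceiveSensitivity:
    def test_identical_pair_gives_unity(self):
        head = np.full((12, 12, 12), 7.0)
        s = receive_sensitivity_from_ratio(head, head.copy())
        assert np.allclose(s, 1.0)

    def test_known_field_recovered_within_3pct_rms(self):
        truth = make_smooth_field((24, 24, 24), 0.15, 6.0, seed=8)
        body = np.full((24, 24, 24), 10.0)
        head = body * truth
        s = receive_sensitivity_from_ratio(head, body, smooth_vox=1.0)
        rms = np.sqrt(np.mean((s - truth / truth.mean()) ** 2))
        assert rms < 0.03

    def test_zero_body_signal_masked(self):
        body = np.full((8, 8, 8), 5.0)
        body[0, 0, 0] = 0.0
        s = receive_sensitivity_from_ratio(body * 1.2, body, smooth_vox=0.0)
        assert np.isnan(s[0, 0, 0])


class TestDataDrivenBias:
    def _mask(self, shape):
        return _ellipsoid_mask(shape)

    def test_unbiased_input_gives_unity(self):
        mask = self._mask((20, 20, 20))
        a = np.where(mask, 500.0, np.nan)
        bias = receive_bias_datadriven(a, mask, order=2)
        assert np.allclose(bias[mask], 1.0, atol=1e-9)

    def test_order2_field_recovered_within_2pct(self):
        shape = (20, 20, 20)
        mask = self._mask(shape)
        axes = [np.linspace(-1, 1, n) for n in shape]
        x, y, z = np.meshgrid(*axes, indexing="ij")
        truth = np.exp(0.2 * x - 0.15 * y**2 + 0.1 * x * z)
        a = 500.0 * truth
        bias = receive_bias_datadriven(a, mask, order=2)
        ratio = bias[mask] / (truth[mask] / truth[mask].mean())
        rms = np.sqrt(np.mean((ratio - 1.0) ** 2))
        assert rms < 0.02

    def test_order0_is_constant_one(self):
        mask = self._mask((16, 16, 16))
        a = np.abs(np.random.default_rng(0).normal(100, 5, (16, 16, 16)))
        bias = receive_bias_datadriven(a, mask, order=0)
        assert np.allclose(bias, 1.0)

    def test_tiny_mask_rejected(self):
        mask = np.zeros((16, 16, 16), bool)
        mask[0, 0, :3] = True
        with pytest.raises(ValueError, match="mask too small"):
            receive_bias_datadriven(np.ones((16, 16, 16)), mask, order=2)


def _ellipsoid_mask(shape):
    axes = [np.linspace(-1, 1, n) for n in shape]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    return x**2 + y**2 + z**2 < 0.8


class TestCalibratePD:
    def test_wm_mean_is_exactly_69(self):
        rng = np.random.default_rng(1)
        a = np.abs(rng.normal(1234.0, 100.0, (10, 10, 10)))
        wm = np.zeros((10, 10, 10))
        wm[3:7, 3:7, 3:7] = 1.0
        pd = calibrate_pd(a, np.ones_like(a), wm)
        assert pd[wm > 0.95].mean() == pytest.approx(69.0, rel=1e-12)

    def test_idempotent(self):
        a = np.full((6, 6, 6), 432.1)
        wm = np.ones((6, 6, 6))
        once = calibrate_pd(a, np.ones_like(a), wm)
        twice = calibrate_pd(once, np.ones_like(a), wm)
        assert np.allclose(once, twice, rtol=1e-12)

    def test_closed_form_scale(self):
        a = np.full((6, 6, 6), 1234.0)
        pd = calibrate_pd(a, np.ones_like(a), np.ones((6, 6, 6)))
        assert np.allclose(pd, 1234.0 * (69.0 / 1234.0))

    def test_empty_wm_mask_rejected(self):
        with pytest.raises(ValueError, match="white-matter"):
            calibrate_pd(np.ones((4, 4, 4)), np.ones((4, 4, 4)),
                         np.zeros((4, 4, 4)))


class TestFitMPM:
    def test_noiseless_rational_round_trip(self, ground_truth, clean_site):
        sess = simulate_session(ground_truth, clean_site, seed=1,
                                forward="rational")
        res = MPMModel.from_session(
            sess, wm_probability=ground_truth.probabilities["WM"],
            brain_mask=ground_truth.head_mask).fit()
        m = res.maps.mask & (ground_truth.labels >= 2)
        for est, true in ((res.maps.mt, 100 * ground_truth.mt_delta),
                          (res.maps.r1, ground_truth.r1),
                          (res.maps.r2s, ground_truth.r2s),
                          (res.maps.amplitude, ground_truth.pd)):
            rel = np.abs(est[m] - true[m]) / np.abs(true[m])
            assert np.nanmax(rel) < 1e-10

    def test_supplied_transmit_field_cancels_simulated_one(self, ground_truth):
        site = SiteEffect("ZH", noise_sigma=0.0, ft_amplitude=0.1,
                          s_amplitude=0.0)
        sess = simulate_session(ground_truth, site, seed=2, forward="rational")
        res = MPMModel.from_session(
            sess, wm_probability=ground_truth.probabilities["WM"],
            brain_mask=ground_truth.head_mask).fit()
        m = res.maps.mask & (ground_truth.labels >= 2)
        rel = np.abs(res.maps.r1[m] - ground_truth.r1[m]) / ground_truth.r1[m]
        assert np.nanmax(rel) < 1e-9

    def test_unsupplied_transmit_error_is_quadratic_in_r1(self, ground_truth):
        # a uniform +10% transmit deviation not handed to the estimator
        # biases R1 by ~ f_T^2, i.e. about twice the transmit error
        from mpmtools.volumes import FieldMaps

        eps = 0.10
        site = SiteEffect("ZH", noise_sigma=0.0, ft_amplitude=0.0,
                          s_amplitude=0.0)
        shape = ground_truth.shape
        true_fields = FieldMaps(np.full(shape, 1.0 + eps), np.ones(shape))
        sess = simulate_session(ground_truth, site, seed=3, forward="rational",
                                field_maps=true_fields)
        res = MPMModel(  # transmit field deliberately not supplied
            sess.volumes,
            wm_probability=ground_truth.probabilities["WM"],
            brain_mask=ground_truth.head_mask).fit()
        m = res.maps.mask & ground_truth.tissue_mask("WM")
        rel_bias = np.nanmedian(res.maps.r1[m] / ground_truth.r1[m]) - 1.0
        # under-reading the flip angle by f biases R1 by 1/f^2, i.e. about
        # twice the transmit error (and in the opposite direction)
        assert rel_bias == pytest.approx(1.0 / (1.0 + eps) ** 2 - 1.0, abs=0.01)
        assert 1.5 * eps < abs(rel_bias) < 3.0 * eps

    def test_masking_counts_are_conserved(self, ground_truth, clean_site):
        sess = simulate_session(ground_truth, clean_site, seed=1)
        res = MPMModel.from_session(
            sess, wm_probability=ground_truth.probabilities["WM"],
            brain_mask=ground_truth.head_mask).fit()
        for step in res.masking_log:
            assert step["n_in"] == step["n_valid"] + step["n_masked"]
        chain = res.masking_log
        for prev, nxt in zip(chain, chain[1:]):
            assert nxt["n_in"] == prev["n_valid"]

    def test_missing_contrast_rejected(self, ground_truth, clean_site):
        sess = simulate_session(ground_truth, clean_site, seed=1)
        volumes = dict(sess.volumes)
        del volumes["MTw"]
        with pytest.raises(ValueError, match="MTw"):
            MPMModel(volumes)

    def test_summary_table_reports_tissue_means(self, ground_truth, clean_site):
        sess = simulate_session(ground_truth, clean_site, seed=1,
                                forward="rational")
        res = MPMModel.from_session(
            sess, wm_probability=ground_truth.probabilities["WM"],
            brain_mask=ground_truth.head_mask).fit()
        table = res.summary({"WM": ground_truth.tissue_mask("WM")})
        row = table[(table.region == "WM") & (table["map"] == "R1")].iloc[0]
        assert row["mean"] == pytest.approx(
            ground_truth.r1[ground_truth.tissue_mask("WM")].mean(), rel=1e-6)


class TestMonteCarloNoise:
    def test_estimator_sd_shrinks_with_averaging_and_mean_is_unbiased(self):
        # N=400 synthetic repetitions at SNR ~50: the dual-angle R1
        # estimator's SD falls as 1/sqrt(averages) and its mean stays
        # within 2 SE of the noiseless value
        rng = np.random.default_rng(42)
        n, a_true, r1_true, tr = 400, 1000.0, 1.0, 0.018
        a_pd, a_t1 = np.deg2rad(4.0), np.deg2rad(25.0)
        s_pd = spgr_signal_rational(SignalParams(a_true, a_pd, tr, r1_true))
        s_t1 = spgr_signal_rational(SignalParams(a_true, a_t1, tr, r1_true))
        sigma = s_pd / 50.0

        def estimate(n_avg):
            noisy_pd = s_pd + sigma * rng.standard_normal((n, n_avg)).mean(1)
            noisy_t1 = s_t1 + sigma * rng.standard_normal((n, n_avg)).mean(1)
            return estimate_r1(noisy_pd, noisy_t1, a_pd, a_t1, tr, tr)

        r1_1 = estimate(1)
        r1_16 = estimate(16)
        sd1, sd16 = np.nanstd(r1_1), np.nanstd(r1_16)
        assert sd1 / sd16 == pytest.approx(4.0, rel=0.35)
        se = sd1 / np.sqrt(n)
        assert abs(np.nanmean(r1_1) - r1_true) < 2.5 * se + 0.02 * sd1**2
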