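"""Difference images, concentration curves and the twofold normalization."""

import numpy as np
import pytest

import dtpa
from dtpa.normalization import region_difference_auc


def _uniform_series(value=400.0, n_time=8, shape=(1, 8, 8)):
    return dtpa.DSCESeries(
        signal=np.full((n_time,) + shape, value), te_ms=47.0, tr_ms=1440.0
    )


def _full_toi(shape=(8, 8)):
    return dtpa.TOI(label="ref", tissue_class="NAWM", mask=np.ones(shape, bool), slice_index=0)


class TestCoilLoadNormalization:
    def test_fixed_point_region_mean_equals_c_ideal(self):
        series = _uniform_series(400.0)
        normalized, state = dtpa.coil_load_normalize(series, _full_toi(), c_ideal=100.0)
        assert state.coil_factor == pytest.approx(4.0)
        assert normalized.signal[0].mean() == pytest.approx(100.0, rel=1e-12)

    def test_identity_when_mean_already_ideal(self):
        series = _uniform_series(100.0)
        normalized, state = dtpa.coil_load_normalize(series, _full_toi(), c_ideal=100.0)
        assert state.coil_factor == pytest.approx(1.0)
        np.testing.assert_array_equal(normalized.signal, series.signal)

    def test_removes_simulated_coil_load_difference(self, small_series):
        series, truth = small_series
        ref = truth.reference_toi
        out = []
        for scale in (0.7, 1.3):
            scaled = dtpa.DSCESeries(
                signal=series.signal * scale, te_ms=series.te_ms, tr_ms=series.tr_ms
            )
            normalized, _ = dtpa.coil_load_normalize(scaled, ref)
            out.append(normalized.signal)
        np.testing.assert_allclose(out[0], out[1], rtol=1e-12)

    def test_degenerate_region_rejected(self):
        series = _uniform_series(0.0)
        with pytest.raises(ValueError, match="degenerate reference region"):
            dtpa.coil_load_normalize(series, _full_toi())


class TestDifferenceSeries:
    def test_constant_series_gives_zero_difference(self):
        diff = dtpa.compute_difference_series(_uniform_series())
        assert np.all(diff.diff == 0)

    def test_uniform_drop_gives_uniform_difference(self):
        series = _uniform_series(400.0)
        series.signal[1:] -= 5.0
        diff = dtpa.compute_difference_series(series)
        assert np.all(diff.diff[1:] == 5.0)
        assert np.all(diff.diff[0] == 0.0)

    def test_baseline_frame_identically_zero(self, small_series):
        series, _ = small_series
        diff = dtpa.compute_difference_series(series, baseline_index=0)
        assert np.all(diff.diff[0] == 0.0)

    def test_leakage_flips_sign_late_in_enhancing_lesion(self, small_series):
        series, truth = small_series
        diff = dtpa.compute_difference_series(series)
        el = truth.leakage_sign.astype(bool)
        assert el.any()
        # late in reperfusion the leakage term dominates: DIFF < 0 inside EL
        assert diff.diff[-1][el].mean() < 0
        nawm = ~el
        assert diff.diff[-1][nawm].mean() >= 0


class TestConcentrationCurve:
    def test_constant_signal_gives_zero_curve(self):
        curve = dtpa.concentration_curve(_uniform_series(), _full_toi())
        np.testing.assert_array_equal(curve.values, 0.0)

    def test_inverts_exponential_model_exactly(self):
        c_true = np.array([0.0, 0.001, 0.004, 0.002, 0.0005, 0.0, 0.0, 0.0])
        series = _uniform_series(400.0)
        series.signal *= np.exp(-47.0 * c_true)[:, None, None, None]
        curve = dtpa.concentration_curve(series, _full_toi())
        np.testing.assert_allclose(curve.values, c_true, atol=1e-15)

    def test_recovers_phantom_ground_truth(self):
        cfg = dtpa.null_phantom_config(seed=0)
        series, truth = dtpa.simulate_phantom(cfg)
        curve = dtpa.concentration_curve(series, truth.reference_toi)
        true_c = truth.concentration["NAWM"]
        rms = np.sqrt(np.mean((curve.values - true_c) ** 2))
        assert rms < 0.05 * true_c.max()

    def test_noise_free_recovery_is_near_exact(self):
        from dataclasses import replace

        cfg = replace(dtpa.null_phantom_config(seed=0), noise_sigma=0.0)
        cfg.tissues = {k: replace(v, texture_sd=0.0) for k, v in cfg.tissues.items()}
        series, truth = dtpa.simulate_phantom(cfg)
        curve = dtpa.concentration_curve(series, truth.reference_toi)
        np.testing.assert_allclose(curve.values, truth.concentration["NAWM"], atol=1e-8)

    def test_non_positive_region_mean_is_error(self):
        series = _uniform_series(1.0)
        series.signal[3] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            dtpa.concentration_curve(series, _full_toi())


class TestCardiacOutputNormalization:
    @staticmethod
    def _bolus_series():
        series = _uniform_series(400.0, n_time=12)
        drop = np.array([0, 0, 0, 10, 40, 60, 40, 20, 10, 5, 2, 1], dtype=float)
        series.signal -= drop[:, None, None, None]
        return series

    def test_auc_fixed_point(self):
        series = self._bolus_series()
        ref = _full_toi()
        diff = dtpa.compute_difference_series(series)
        phases = dtpa.detect_phases(dtpa.concentration_curve(series, ref), smooth_width=1)
        normalized, state = dtpa.cardiac_output_normalize(diff, ref, phases, auc_ref=200.0)
        members = np.concatenate(
            [phases.interval_members("IFP"), phases.interval_members("OFP")]
        )
        auc = region_difference_auc(normalized, ref, members)
        assert auc == pytest.approx(200.0, rel=1e-12)

    def test_identity_when_auc_equals_reference(self):
        series = self._bolus_series()
        ref = _full_toi()
        diff = dtpa.compute_difference_series(series)
        phases = dtpa.detect_phases(dtpa.concentration_curve(series, ref), smooth_width=1)
        members = np.concatenate(
            [phases.interval_members("IFP"), phases.interval_members("OFP")]
        )
        auc = region_difference_auc(diff, ref, members)
        normalized, state = dtpa.cardiac_output_normalize(diff, ref, phases, auc_ref=auc)
        assert state.auc_factor == pytest.approx(1.0)
        np.testing.assert_array_equal(normalized.diff, diff.diff)

    def test_flat_difference_rejected(self):
        series = _uniform_series(400.0, n_time=12)
        bolus = self._bolus_series()
        ref = _full_toi()
        phases = dtpa.detect_phases(dtpa.concentration_curve(bolus, ref), smooth_width=1)
        diff = dtpa.compute_difference_series(series)
        with pytest.raises(ValueError, match="no detectable bolus"):
            dtpa.cardiac_output_normalize(diff, ref, phases)

    def test_cardiac_scaled_pair_agrees_after_normalization(self):
        """Bolus amplitude x1.5 (cardiac-output surrogate): after AUC
        normalization the NAWM TPM-DIFF interval averages of the calibrated
        intervals agree within 1%."""
        lo_cfg, hi_cfg = dtpa.cardiac_pair_configs(seed=0)
        means = {}
        for name, cfg in (("lo", lo_cfg), ("hi", hi_cfg)):
            series, truth = dtpa.simulate_phantom(cfg)
            res = dtpa.run_workflow(
                dtpa.RunConfig(), series=series, tois=truth.tois + [truth.reference_toi]
            )
            rec = res.records
            sel = rec[
                (rec.tissue_class == "NAWM")
                & (rec.tpm_type == "DIFF")
                & (rec.statistic == "mean")
            ]
            means[name] = {
                iv: sel[sel.interval == iv]["value"].mean() for iv in ("IFP", "OFP")
            }
        for iv in ("IFP", "OFP"):
            rel = abs(means["lo"][iv] - means["hi"][iv]) / abs(means["lo"][iv])
            assert rel < 0.01, (iv, rel)


class TestTwofoldProperties:
    def test_normalize_then_diff_commutes_with_diff_then_scale(self, small_series):
        series, truth = small_series
        ref = truth.reference_toi
        normalized, state = dtpa.coil_load_normalize(series, ref)
        a = dtpa.compute_difference_series(normalized).diff
        b = dtpa.compute_difference_series(series).diff / state.coil_factor
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_both_fixed_points_hold_simultaneously(self, effect_run):
        series, truth, res = effect_run
        header = res.report.header
        ref = truth.reference_toi
        normalized, _ = dtpa.coil_load_normalize(series, ref, c_ideal=header["c_ideal"])
        mask = ref.mask3d(series.spatial_shape)
        assert normalized.signal[0][mask].mean() == pytest.approx(
            header["c_ideal"], rel=1e-12
        )
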