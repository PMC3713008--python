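"""TOI statistics grid, interval averaging, direct mode and Δ-markers."""

import numpy as np
import pandas as pd
import pytest

import dtpa
from dtpa.normalization import DifferenceSeries
from dtpa.phases import BolusPhases
from dtpa.texture import TPMSeries


def _toi(mask, cls="EL", label="t"):
    return dtpa.TOI(label=label, tissue_class=cls, mask=mask, slice_index=0)


class TestRegionStatistics:
    def test_degenerate_set_of_zeros(self):
        out = dtpa.region_statistics(np.zeros(4))
        assert out["mean"] == 0 and out["var"] == 0 and out["vava"] == 0
        assert np.isnan(out["skew"]) and np.isnan(out["kurt"])

    def test_one_to_five_hand_oracle(self):
        out = dtpa.region_statistics(np.array([1.0, 2, 3, 4, 5]))
        assert out["mean"] == pytest.approx(3.0)
        assert out["var"] == pytest.approx(2.0)
        assert out["vava"] == pytest.approx(2.8)  # m4 = 6.8
        assert out["stdev"] == pytest.approx(np.sqrt(2.0))

    def test_translation_invariance(self, rng):
        vals = rng.random(40)
        a = dtpa.region_statistics(vals)
        b = dtpa.region_statistics(vals + 17.3)
        assert b["mean"] == pytest.approx(a["mean"] + 17.3)
        for key in ("stdev", "var", "vava", "skew", "kurt"):
            assert b[key] == pytest.approx(a[key], rel=1e-9), key

    def test_empty_set_fully_undetermined(self):
        out = dtpa.region_statistics(np.array([]))
        assert all(np.isnan(v) for v in out.values())


class TestTOITimeCourse:
    @staticmethod
    def _tpm(values, valid=None):
        valid = np.ones(values.shape, bool) if valid is None else valid
        return TPMSeries("DIFF", values, 3, valid)

    def test_matches_region_statistics_frame_by_frame(self, rng):
        values = rng.normal(size=(6, 1, 10, 10))
        valid = rng.random(values.shape) > 0.2
        mask = rng.random((10, 10)) > 0.5
        tpm = self._tpm(values, valid)
        course = dtpa.toi_time_course(tpm, _toi(mask))
        for k in range(6):
            sel = mask & valid[k, 0]
            ref = dtpa.region_statistics(values[k, 0][sel])
            for stat in dtpa.STATISTICS:
                got, want = course.loc[k, stat], ref[stat]
                if np.isnan(want):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want, rel=1e-9, abs=1e-12), (k, stat)

    def test_single_voxel_toi(self):
        values = np.arange(8.0).reshape(8, 1, 1, 1).repeat(4, 2).repeat(4, 3)
        mask = np.zeros((4, 4), bool)
        mask[2, 2] = True
        course = dtpa.toi_time_course(self._tpm(values), _toi(mask))
        np.testing.assert_allclose(course["mean"], np.arange(8.0))
        np.testing.assert_allclose(course["var"], 0.0)

    def test_spatially_constant_tpm_has_zero_dispersion(self):
        values = np.full((5, 1, 6, 6), 2.5)
        course = dtpa.toi_time_course(self._tpm(values), _toi(np.ones((6, 6), bool)))
        np.testing.assert_allclose(course["stdev"], 0.0)

    def test_empty_intersection_is_undetermined(self):
        values = np.zeros((4, 1, 4, 4))
        valid = np.zeros(values.shape, bool)
        course = dtpa.toi_time_course(self._tpm(values, valid), _toi(np.ones((4, 4), bool)))
        assert course["mean"].isna().all()


class TestIntervalAverage:
    PHASES = BolusPhases(toa=3, t_peak=5, t_min=7, n_time=10)

    def _course(self, mean_vals):
        df = pd.DataFrame({s: np.full(10, 1.0) for s in dtpa.STATISTICS})
        df["mean"] = mean_vals
        df["n_voxels"] = 9
        return df

    def test_constant_course_is_identity(self):
        rec = dtpa.interval_average(self._course(np.full(10, 4.2)), self.PHASES,
                                    _toi(np.ones((2, 2), bool)), "DIFF")
        sel = rec[rec.statistic == "mean"]
        assert (sel["value"] == pytest.approx(4.2, rel=1e-12)) is not False
        np.testing.assert_allclose(sel["value"], 4.2)

    def test_baseline_average_of_1_2_3(self):
        vals = np.array([1.0, 2, 3, 9, 9, 9, 9, 9, 9, 9])
        rec = dtpa.interval_average(self._course(vals), self.PHASES,
                                    _toi(np.ones((2, 2), bool)), "DIFF")
        blp = rec[(rec.statistic == "mean") & (rec.interval == "BLP")]["value"].iloc[0]
        assert blp == pytest.approx(2.0)

    def test_nan_frames_dropped_from_average(self):
        vals = np.array([1.0, np.nan, 3, 9, 9, 9, 9, 9, 9, 9])
        rec = dtpa.interval_average(self._course(vals), self.PHASES,
                                    _toi(np.ones((2, 2), bool)), "DIFF")
        row = rec[(rec.statistic == "mean") & (rec.interval == "BLP")].iloc[0]
        assert row["value"] == pytest.approx(2.0)
        assert row["n_timepoints"] == 2 and not row["undetermined"]

    def test_record_grid_arithmetic(self, effect_run):
        _, _, res = effect_run
        rec = res.records
        per_tpm = rec.groupby("tpm_type").apply(
            lambda g: g.groupby(["tissue_class", "statistic", "interval"]).ngroups,
            include_groups=False,
        )
        assert (per_tpm == 72).all()
        assert per_tpm.size == 8
        total_cells = rec.groupby(
            ["tpm_type", "tissue_class", "statistic", "interval"]
        ).ngroups
        assert total_cells == 576


class TestDirectTOITexture:
    def test_single_voxel(self):
        diff = DifferenceSeries(np.arange(8.0).reshape(8, 1, 1, 1) * np.ones((8, 1, 3, 3)),
                                0, 47, 1440)
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        course = dtpa.direct_toi_texture(diff, _toi(mask))
        np.testing.assert_allclose(course["var"], 0.0)
        assert course["skew"].isna().all()

    def test_constant_region_zero_dispersion(self):
        diff = DifferenceSeries(np.full((6, 1, 5, 5), 3.0), 0, 47, 1440)
        course = dtpa.direct_toi_texture(diff, _toi(np.ones((5, 5), bool)))
        np.testing.assert_allclose(course[["stdev", "var", "vava"]], 0.0)

    def test_direct_mean_close_to_kernel_aver_on_smooth_data(self, rng):
        # smooth field: moving average ~ identity, so direct mean ~ AVER mean
        base = rng.normal(size=(28, 28))
        smooth = base.copy()
        from scipy.ndimage import gaussian_filter

        smooth = gaussian_filter(base, sigma=4) + 10.0
        frames = np.repeat(smooth[None, None], 4, axis=0)
        diff = DifferenceSeries(frames, 0, 47, 1440)
        mask = np.zeros((28, 28), bool)
        mask[8:20, 8:20] = True
        toi = _toi(mask)
        direct = dtpa.direct_toi_texture(diff, toi)["mean"].iloc[0]
        aver = dtpa.compute_tpm(diff, "AVER", kernel=3)
        kernel_mean = dtpa.toi_time_course(aver, toi)["mean"].iloc[0]
        assert kernel_mean == pytest.approx(direct, rel=0.02)


class TestDeltaMarkers:
    @staticmethod
    def _records(ifp, rpp):
        rows = []
        for interval, value in (("IFP", ifp), ("RPP", rpp)):
            rows.append({
                "toi_label": "el1", "tissue_class": "EL", "tpm_type": "DIFF",
                "statistic": "mean", "interval": interval, "value": value,
                "n_voxels": 9, "n_timepoints": 3, "undetermined": False,
            })
        return pd.DataFrame(rows)

    def test_rpp_minus_ifp(self):
        dm = dtpa.delta_markers(self._records(10.0, 4.0))
        val = dm[dm.marker == "dTPM_DIFF"]["value"].iloc[0]
        assert val == pytest.approx(-6.0)

    def test_equal_intervals_give_zero(self):
        dm = dtpa.delta_markers(self._records(5.0, 5.0))
        assert dm[dm.marker == "dTPM_DIFF"]["value"].iloc[0] == pytest.approx(0.0)

    def test_missing_interval_is_undetermined(self):
        rec = self._records(5.0, 5.0)
        rec = rec[rec.interval == "IFP"]
        dm = dtpa.delta_markers(rec)
        assert np.isnan(dm[dm.marker == "dTPM_DIFF"]["value"].iloc[0])

    def test_leakage_grading_is_monotone(self):
        """Larger leakage pulls the reperfusion difference signal further
        below the inflow level: ΔTPM-DIFF decreases with the leakage
        coefficient in the enhancing lesion."""
        deltas = []
        for leak in (200.0, 600.0, 1000.0):
            series, truth = dtpa.simulate_phantom(
                dtpa.effect_phantom_config(seed=5, el_leakage=leak)
            )
            res = dtpa.run_workflow(
                dtpa.RunConfig(), series=series, tois=truth.tois + [truth.reference_toi]
            )
            dm = res.report.delta_markers
            deltas.append(
                dm[(dm.tissue_class == "EL") & (dm.marker == "dTPM_DIFF")]["value"].mean()
            )
        assert deltas[0] > deltas[1] > deltas[2]

    def test_el_diff_mean_negative_during_reperfusion(self, effect_run):
        _, _, res = effect_run
        rec = res.records
        el_rpp = rec[
            (rec.tissue_class == "EL") & (rec.tpm_type == "DIFF")
            & (rec.statistic == "mean") & (rec.interval == "RPP")
        ]["value"]
        assert el_rpp.mean() < 0
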