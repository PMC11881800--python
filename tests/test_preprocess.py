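"""Preprocessing chain: optical density, motion correction, Beer-Lambert
inversion, detrending, systemic removal, ROI pooling."""

import numpy as np
import pytest

from nirsconn.preprocess import (
    ROI_CHANNEL_COUNTS,
    ROI_LABELS,
    HemoglobinSeries,
    OpticalDensitySeries,
    RawIntensityRecording,
    correct_motion,
    default_roi_map,
    detrend_center,
    dpf,
    extinction_matrix,
    intensity_to_od,
    od_to_hemoglobin,
    pool_rois,
    remove_systemic,
)


def _recording(intensities, fs=7.8125):
    n = intensities.shape[0] // 2
    return RawIntensityRecording(
        intensities=intensities,
        wavelength=np.tile([760.0, 850.0], n),
        source=np.repeat(np.arange(1, n + 1), 2),
        detector=np.repeat(np.arange(1, n + 1), 2),
        fs=fs,
    )


class TestIntensityToOd:
    def test_constant_intensity_gives_zero(self):
        rec = _recording(np.full((2, 100), 3.7))
        od = intensity_to_od(rec)
        np.testing.assert_allclose(od.delta_od, 0.0, atol=1e-15)

    def test_ln_e_case(self):
        phi = np.full((2, 10), 2.0)
        phi[:, 1:] = 2.0 / np.e
        rec = _recording(phi)
        od = intensity_to_od(rec, reference="first")
        np.testing.assert_allclose(od.delta_od[:, 1:], 1.0, atol=1e-14)
        np.testing.assert_allclose(od.delta_od[:, 0], 0.0, atol=1e-14)

    def test_matches_log_ratio_oracle(self):
        rng = np.random.default_rng(0)
        phi = np.exp(rng.normal(0, 0.1, size=(4, 200)))
        rec = _recording(phi)
        od = intensity_to_od(rec, reference="mean")
        expected = np.log(phi.mean(axis=1, keepdims=True) / phi)
        np.testing.assert_allclose(od.delta_od, expected, atol=1e-14)

    def test_nonpositive_intensity_rejected_with_location(self):
        phi = np.ones((2, 50))
        phi[1, 7] = 0.0
        with pytest.raises(ValueError, match="measurement 1, sample 7"):
            _recording(phi)

    def test_missing_wavelength_partner_rejected(self):
        with pytest.raises(ValueError, match="wavelength"):
            RawIntensityRecording(
                intensities=np.ones((2, 10)),
                wavelength=np.array([760.0, 760.0]),
                source=np.array([1, 2]),
                detector=np.array([1, 2]),
                fs=10.0,
            )


class TestCorrectMotion:
    def _od(self, x, fs=7.8125):
        n = x.shape[0]
        return OpticalDensitySeries(
            delta_od=x,
            wavelength=np.tile([760.0], n),
            source=np.arange(n),
            detector=np.arange(n),
            fs=fs,
        )

    def test_clean_sinusoid_passes_through(self):
        t = np.arange(2000) / 7.8125
        x = 0.05 * np.sin(2 * np.pi * 0.05 * t)[None, :]
        out = correct_motion(self._od(x))
        rms_in = np.sqrt(np.mean(x**2))
        rms_change = np.sqrt(np.mean((out.delta_od - x) ** 2))
        assert rms_change < 0.05 * rms_in

    def test_spike_suppressed_below_detection_threshold(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.01, size=(1, 2000))
        x[0, 1000:1003] += 20 * 0.01  # 20x SD spike
        out = correct_motion(self._od(x))
        d = np.abs(np.diff(out.delta_od[0]))
        scale = 1.4826 * np.median(np.abs(d - np.median(d)))
        assert np.all(d[995:1010] < 5 * scale)

    def test_step_shift_removed(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.01, size=(1, 2000))
        shift = 10 * 0.01
        x[0, 1000:] += shift
        out = correct_motion(self._od(x))
        gap = out.delta_od[0, 1010:].mean() - out.delta_od[0, :990].mean()
        assert abs(gap) < 0.1 * shift

    def test_window_longer_than_recording_rejected(self):
        x = np.zeros((1, 10))
        with pytest.raises(ValueError, match="window"):
            correct_motion(self._od(x), window_s=100.0)

    def test_shape_preserved(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(3, 500))
        out = correct_motion(self._od(x))
        assert out.delta_od.shape == x.shape


class TestOdToHemoglobin:
    @pytest.mark.parametrize("age,expected", [(0.0, 4.99), (1.0, 5.057)])
    def test_dpf_printed_values(self, age, expected):
        assert dpf(age) == pytest.approx(expected, abs=1e-12)

    def test_forward_inverse_roundtrip_machine_precision(self):
        rng = np.random.default_rng(4)
        hbo = rng.normal(0, 0.5, size=200)
        hbr = rng.normal(0, 0.2, size=200)
        E = extinction_matrix((760.0, 850.0))
        pathlen = 3.0 * dpf(10.0)
        od_vals = (E @ np.vstack([hbo, hbr])) * pathlen
        od = OpticalDensitySeries(
            delta_od=od_vals,
            wavelength=np.array([760.0, 850.0]),
            source=np.array([1, 1]),
            detector=np.array([1, 1]),
            fs=7.8125,
            subject_age=10.0,
        )
        hb = od_to_hemoglobin(od)
        np.testing.assert_allclose(hb.hbo[0], hbo, atol=1e-12)
        np.testing.assert_allclose(hb.hbr[0], hbr, atol=1e-12)

    def test_singular_extinction_table_rejected(self):
        od = OpticalDensitySeries(
            delta_od=np.zeros((2, 10)),
            wavelength=np.array([760.0, 850.0]),
            source=np.array([1, 1]),
            detector=np.array([1, 1]),
            fs=10.0,
        )
        degenerate = {760.0: (1.0, 1.0), 850.0: (1.0, 1.0)}
        with pytest.raises(np.linalg.LinAlgError):
            od_to_hemoglobin(od, extinction_table=degenerate)


def _hb(hbo, fs=7.8125):
    n = hbo.shape[0]
    return HemoglobinSeries(
        hbo=hbo,
        hbr=-0.3 * hbo,
        source=np.arange(1, n + 1),
        detector=np.arange(1, n + 1),
        fs=fs,
    )


class TestDetrendCenter:
    def test_pure_line_maps_to_zero(self):
        t = np.arange(500, dtype=float)
        x = (2.0 + 0.03 * t)[None, :]
        out = detrend_center(_hb(x))
        np.testing.assert_allclose(out.hbo, 0.0, atol=1e-9)

    def test_line_plus_sinusoid_matches_least_squares_oracle(self):
        t = np.arange(2000, dtype=float)
        sin = np.sin(2 * np.pi * t / 100.0)
        x = (1.5 - 0.01 * t + sin)[None, :]
        out = detrend_center(_hb(x))
        # independent oracle: polyfit line removal
        expected = x[0] - np.polyval(np.polyfit(t, x[0], 1), t)
        assert np.sqrt(np.mean((out.hbo[0] - expected) ** 2)) < 1e-8
        # and the result is the sinusoid up to the line it projects onto
        resid = out.hbo[0] - (sin - sin.mean())
        assert np.sqrt(np.mean(resid**2)) < 0.05

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(2, 300))
        once = detrend_center(_hb(x))
        twice = detrend_center(once)
        np.testing.assert_allclose(once.hbo, twice.hbo, atol=1e-12)

    def test_mean_below_tolerance(self):
        rng = np.random.default_rng(6)
        out = detrend_center(_hb(rng.normal(size=(3, 400))))
        assert np.all(np.abs(out.hbo.mean(axis=1)) < 1e-10)

    def test_constant_channel_zeroed_with_warning(self):
        x = np.vstack([np.full(100, 2.0), np.random.default_rng(0).normal(size=100)])
        with pytest.warns(UserWarning, match="constant"):
            out = detrend_center(_hb(x))
        np.testing.assert_allclose(out.hbo[0], 0.0)
        assert any("constant" in w for w in out.warnings_log)


class TestRemoveSystemic:
    def test_identical_channels_become_zero(self):
        g = np.sin(np.linspace(0, 20, 500))
        x = np.tile(g, (5, 1))
        out = remove_systemic(_hb(x))
        np.testing.assert_allclose(out.hbo, 0.0, atol=1e-10)

    def test_residual_orthogonal_to_global_component(self):
        rng = np.random.default_rng(7)
        g = rng.normal(size=2000)
        x = g[None, :] + 0.3 * rng.normal(size=(40, 2000))
        out = remove_systemic(_hb(x))
        for ch in range(40):
            r = np.corrcoef(out.hbo[ch], g)[0, 1]
            assert abs(r) < 0.05

    def test_residual_inner_product_with_regressor(self):
        """Each channel's residual is exactly orthogonal to its own regressor."""
        rng = np.random.default_rng(8)
        x = rng.normal(size=(5, 400))
        out = remove_systemic(_hb(x))
        total = x.sum(axis=0)
        for ch in range(5):
            reg = (total - x[ch]) / 4
            reg = reg / np.linalg.norm(reg)
            resid = out.hbo[ch] / max(np.linalg.norm(out.hbo[ch]), 1e-30)
            assert abs(resid @ reg) < 1e-8

    def test_zero_input_zero_output(self):
        out = remove_systemic(_hb(np.zeros((3, 100))))
        np.testing.assert_allclose(out.hbo, 0.0)

    def test_single_channel_noop_with_warning(self):
        x = np.random.default_rng(9).normal(size=(1, 100))
        with pytest.warns(UserWarning, match="single channel"):
            out = remove_systemic(_hb(x))
        np.testing.assert_allclose(out.hbo, x)


class TestPoolRois:
    def test_default_map_retains_40_channels_with_documented_counts(self):
        roi_map = default_roi_map(("left",))
        assert len(roi_map) == 40
        counts = roi_map["roi"].value_counts().to_dict()
        assert counts == ROI_CHANNEL_COUNTS
        hbo = np.random.default_rng(10).normal(size=(40, 50))
        hb = HemoglobinSeries(
            hbo=hbo, hbr=-0.3 * hbo,
            source=roi_map["source"].to_numpy(),
            detector=roi_map["detector"].to_numpy(),
            fs=7.8125,
        )
        roi = pool_rois(hb, roi_map)
        assert roi.n_channels_retained == 40
        assert roi.series.shape[0] == 7

    def test_identical_members_equal_member_signal(self):
        roi_map = default_roi_map(("left",))
        sig = np.sin(np.linspace(0, 10, 200))
        hbo = np.tile(sig, (40, 1))
        hb = HemoglobinSeries(
            hbo=hbo, hbr=-0.3 * hbo,
            source=roi_map["source"].to_numpy(),
            detector=roi_map["detector"].to_numpy(),
            fs=7.8125,
        )
        roi = pool_rois(hb, roi_map)
        for r in range(7):
            np.testing.assert_allclose(roi.series[r], sig, atol=1e-12)

    def test_cancelling_members_give_zero(self):
        roi_map = default_roi_map(("left",)).iloc[:2].copy()
        roi_map["roi"] = "IFG"
        sig = np.cos(np.linspace(0, 5, 100))
        hbo = np.vstack([sig, -sig])
        hb = HemoglobinSeries(
            hbo=hbo, hbr=hbo,
            source=roi_map["source"].to_numpy(),
            detector=roi_map["detector"].to_numpy(),
            fs=7.8125,
        )
        import pandas as pd

        full_map = pd.concat(
            [roi_map]
            + [
                pd.DataFrame(
                    {"source": [900 + i], "detector": [900 + i], "roi": [r], "hemisphere": ["left"]}
                )
                for i, r in enumerate(ROI_LABELS[1:])
            ]
        )
        extra = np.random.default_rng(0).normal(size=(6, 100))
        hb_full = HemoglobinSeries(
            hbo=np.vstack([hbo, extra]), hbr=np.vstack([hbo, extra]),
            source=full_map["source"].to_numpy(),
            detector=full_map["detector"].to_numpy(),
            fs=7.8125,
        )
        roi = pool_rois(hb_full, full_map)
        np.testing.assert_allclose(roi.series[0], 0.0, atol=1e-12)

    def test_missing_roi_raises(self):
        roi_map = default_roi_map(("left",))
        partial = roi_map[roi_map["roi"] != "ANG"]
        hbo = np.ones((len(partial), 20))
        hb = HemoglobinSeries(
            hbo=hbo, hbr=hbo,
            source=partial["source"].to_numpy(),
            detector=partial["detector"].to_numpy(),
            fs=7.8125,
        )
        with pytest.raises(ValueError, match="ANG"):
            pool_rois(hb, roi_map)


def test_no_stage_shortens_or_reorders_time_axis(clean_recording):
    _, rec = clean_recording
    od = intensity_to_od(rec)
    od2 = correct_motion(od)
    hb = od_to_hemoglobin(od2)
    hb2 = remove_systemic(detrend_center(hb))
    assert od.n_times == od2.n_times == hb.n_times == hb2.n_times == rec.n_times
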