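"""Slanted-edge eMTF: angle estimation, ESF/LSF oracles, Fourier stage."""

import numpy as np
import pytest
from scipy.optimize import curve_fit
from scipy.special import ndtr

from effiq.exceptions import EdgeDetectionError, ValidationError
from effiq.io import FrequencySeries, GeometrySetup, RadiographImage
from effiq.mtf import (
    EdgeAnalysisConfig,
    EsfProfile,
    SlantedEdgeMTF,
    average_and_project,
    build_esf,
    esf_to_lsf,
    estimate_edge_angle,
    lsf_to_mtf,
)
from effiq.synthetic import _edge_profile, make_edge_image

NO_WINDOW = EdgeAnalysisConfig(window="none")


class TestEdgeAngle:
    @pytest.mark.parametrize("angle", [3.0, 5.0])
    def test_recovers_generator_angle(self, angle):
        img, _ = make_edge_image(angle, 0.15, 0.143, (300, 300), noise_sd=0.0, seed=2)
        assert estimate_edge_angle(img) == pytest.approx(angle, abs=0.05)

    def test_constant_image_raises(self):
        img = RadiographImage(np.full((64, 64), 7.0), 0.143, linearized=True)
        with pytest.raises(EdgeDetectionError):
            estimate_edge_angle(img)


class TestEsf:
    def test_bin_width_is_tenth_of_pitch(self, clean_edge):
        img, _ = clean_edge
        esf = build_esf(img, estimate_edge_angle(img))
        assert esf.bin_width_mm == pytest.approx(0.1 * 0.143, rel=1e-9)

    def test_sigma_zero_esf_is_step_within_one_bin(self):
        img, _ = make_edge_image(3.0, 0.0, 0.143, (300, 300), contrast=(0.0, 1.0), noise_sd=0.0)
        esf = build_esf(img, estimate_edge_angle(img))
        # outside +/- 1.5 pitch of the crossing the profile is flat at 0 or 1
        lo = esf.values[esf.positions_mm < -1.5 * 0.143]
        hi = esf.values[esf.positions_mm > 1.5 * 0.143]
        assert np.allclose(hi, 0.0, atol=1e-9)  # dark side is positive distance
        assert np.allclose(lo, 1.0, atol=1e-9)

    def test_esf_matches_closed_form_profile(self, clean_edge):
        """Measured super-sampled ESF vs the analytic blurred-aperture step."""
        img, truth = clean_edge
        esf = build_esf(img, estimate_edge_angle(img))
        th = np.deg2rad(truth.true_angle_deg)
        w1, w2 = 0.143 * np.cos(th), 0.143 * np.sin(th)
        expected_dark = _edge_profile(esf.positions_mm, truth.true_mtf_sigma_mm, w1, w2)
        expected = 1000.0 + (100.0 - 1000.0) * expected_dark
        step = 900.0
        assert np.max(np.abs(esf.values - expected)) < 0.005 * step

    def test_unlinearized_image_rejected(self):
        img = RadiographImage(np.ones((64, 64)), 0.1, linearized=False)
        with pytest.raises(ValidationError):
            build_esf(img, 3.0)


class TestLsf:
    def test_step_esf_gives_unit_area_impulse(self):
        n = 101
        values = np.r_[np.zeros(50), 0.5, np.ones(50)]
        esf = EsfProfile(np.arange(n) * 0.01, values, np.ones(n, dtype=int))
        lsf = esf_to_lsf(esf, NO_WINDOW)
        assert np.sum(lsf) * 0.01 == pytest.approx(1.0, rel=1e-9)
        assert np.sum(np.abs(lsf) > 1e-12) <= 3  # impulse support

    def test_linear_ramp_gives_constant_lsf(self):
        esf = EsfProfile(np.arange(50) * 0.01, np.arange(50) * 0.25, np.ones(50, dtype=int))
        lsf = esf_to_lsf(esf, NO_WINDOW)
        assert np.allclose(lsf, 25.0, rtol=1e-9)

    def test_erf_esf_gives_gaussian_lsf_with_right_sigma(self):
        sigma = 0.2
        x = np.arange(-3.0, 3.0, 0.0143)
        esf = EsfProfile(x - x[0], ndtr(x / sigma), np.ones(x.size, dtype=int))
        lsf = esf_to_lsf(esf, NO_WINDOW)
        gauss = lambda t, a, mu, s: a * np.exp(-((t - mu) ** 2) / (2 * s**2))  # noqa: E731
        popt, _ = curve_fit(gauss, esf.positions_mm, lsf, p0=(2.0, 3.0, 0.3))
        assert abs(popt[2]) == pytest.approx(sigma, rel=0.02)

    def test_short_profile_rejected(self):
        esf = EsfProfile(np.array([0.0, 0.01]), np.array([0.0, 1.0]), np.ones(2, dtype=int))
        with pytest.raises(ValidationError):
            esf_to_lsf(esf)


class TestMtf:
    def test_impulse_lsf_gives_flat_unity_mtf(self):
        lsf = np.zeros(512)
        lsf[256] = 1.0
        curve = lsf_to_mtf(lsf, 0.0143)
        assert np.allclose(curve.values, 1.0, atol=1e-9)
        assert curve.values[0] == 1.0

    def test_gaussian_lsf_matches_analytic_mtf(self):
        sigma = 0.2
        x = (np.arange(1024) - 512) * 0.0143
        lsf = np.exp(-(x**2) / (2 * sigma**2))
        curve = lsf_to_mtf(lsf, 0.0143)
        f = curve.frequencies[curve.frequencies <= 2.5]
        expected = np.exp(-2 * np.pi**2 * sigma**2 * f**2)
        rms = np.sqrt(np.mean((curve.interp(f) - expected) ** 2))
        assert rms < 0.02

    def test_zero_lsf_cannot_be_normalised(self):
        with pytest.raises(ValidationError):
            lsf_to_mtf(np.zeros(64), 0.0143)


class TestAverageAndProject:
    def _flat_curve(self, fmax=3.0):
        f = np.arange(0.0, fmax, 0.01)
        return FrequencySeries(f, np.exp(-f), plane="detector", quantity="eMTF")

    def test_identical_curves_average_to_themselves(self):
        c = self._flat_curve()
        out = average_and_project([c] * 5)
        assert np.allclose(out.values, c.values[: len(out)], rtol=1e-12)
        assert out.plane == "object"

    def test_unit_magnification_keeps_frequencies(self):
        c = self._flat_curve()
        geom = GeometrySetup(sid_cm=130, sdd_cm=70, object_plane_offset_cm=0)
        out = average_and_project([c], geom)
        assert np.allclose(out.frequencies, c.frequencies)

    def test_magnification_rescales_frequencies(self):
        c = self._flat_curve()
        geom = GeometrySetup(sid_cm=130, sdd_cm=70, object_plane_offset_cm=13)
        out = average_and_project([c], geom)
        m = 130 / 117
        i = int(round(1.0 / 0.01))
        assert out.frequencies[i] == pytest.approx(1.0 * m, rel=1e-9)

    def test_object_plane_curve_rejected(self):
        f = np.arange(0.0, 1.0, 0.01)
        bad = FrequencySeries(f, np.ones_like(f), plane="object")
        with pytest.raises(ValidationError):
            average_and_project([bad])


class TestFullPipeline:
    def test_emtf_normalised_to_one_at_zero(self, clean_edge):
        img, _ = clean_edge
        for window in ("none", "hann"):
            est = SlantedEdgeMTF(roi_size_mm=40, window=window).fit([img])
            assert est.mtf_.values[0] == 1.0

    def test_parameter_recovery_on_noisy_edges(self):
        """Five noisy acquisitions recover the analytic MTF within 0.03 RMS."""
        edges = []
        for i in range(5):
            img, truth = make_edge_image(
                3.0, 0.2, 0.143, (360, 360), contrast=(100.0, 1000.0),
                noise_sd=9.0, seed=40 + i, edge_shift_mm=(i - 2) * 0.29 * 0.143,
            )
            edges.append(img)
        est = SlantedEdgeMTF(roi_size_mm=40, window="hann").fit(edges)
        curve = est.mtf_
        ny = 1 / (2 * 0.143)
        f = curve.frequencies[curve.frequencies <= 0.8 * ny]
        rms = np.sqrt(np.mean((curve.interp(f) - truth.analytic_mtf(f)) ** 2))
        assert rms < 0.03

    def test_noise_free_emtf_non_increasing(self, clean_edge):
        img, _ = clean_edge
        est = SlantedEdgeMTF(roi_size_mm=40, window="none").fit([img])
        assert np.all(np.diff(est.mtf_.values) <= 0.01)
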