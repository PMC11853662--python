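"""Phase formulas, the reference LUT, ΔE matching, and the sign test."""

import numpy as np
import pytest

import polchip as pc
from polchip.colorimetry import srgb_to_lab
from polchip.retrieval import ColorLUT
from polchip.spectra import BandLimits


class TestPhaseFormulas:
    def test_full_wave_single_wavelength(self):
        assert pc.single_wavelength_phase(560.0, 560.0) == pytest.approx(
            2 * np.pi
        )

    def test_zero_opd(self):
        assert pc.single_wavelength_phase(0.0, 550.0) == 0.0
        assert pc.average_phase(0.0) == 0.0

    def test_single_wavelength_at_band_edge(self):
        assert pc.single_wavelength_phase(1134.0, 380.0) == pytest.approx(
            2 * np.pi * 1134.0 / 380.0
        )
        assert pc.single_wavelength_phase(1134.0, 380.0) / np.pi == pytest.approx(
            5.9684, abs=1e-3
        )

    def test_average_phase_of_first_order_mica_color(self):
        # OPD 1071 nm carries the 3.85*pi band-averaged phase that pairs with
        # dn = 0.0051 at d = 210 um
        assert pc.average_phase(1071.0) / np.pi == pytest.approx(3.851, abs=2e-3)

    def test_closed_form_agrees_with_quadrature(self):
        from scipy.integrate import quad

        band = BandLimits()
        for opd in (137.0, 560.0, 1134.0, 2890.0):
            numeric = (
                2
                * np.pi
                * opd
                / (band.lambda_f - band.lambda_i)
                * quad(lambda lam: 1.0 / lam, band.lambda_i, band.lambda_f)[0]
            )
            assert pc.average_phase(opd, band) == pytest.approx(
                numeric, rel=1e-3
            )

    def test_monotone_in_opd(self):
        opd = np.linspace(0, 3000, 500)
        assert np.all(np.diff(pc.average_phase(opd)) > 0)


class TestBirefringenceInversion:
    def test_mica_published_value(self):
        est = pc.birefringence_from_phase(3.85 * np.pi, 210.0)
        assert round(est.delta_n, 4) == 0.0051

    def test_zero_phase_gives_zero(self):
        assert pc.birefringence_from_phase(0.0, 210.0).delta_n == 0.0

    def test_lower_order_color(self):
        est = pc.birefringence_from_phase(1.89 * np.pi, 210.0)
        assert round(est.delta_n, 4) == 0.0025

    def test_exact_inverse_roundtrip(self):
        for dn in (0.0008, 0.0051, 0.0054, 0.02):
            opd = dn * 210.0 * 1e3
            phi = pc.average_phase(opd)
            back = pc.birefringence_from_phase(phi, 210.0).delta_n
            assert back == pytest.approx(dn, rel=1e-12)

    def test_monotone_in_phase(self):
        dns = [
            pc.birefringence_from_phase(p, 210.0).delta_n
            for p in np.linspace(0.1, 20.0, 50)
        ]
        assert np.all(np.diff(dns) > 0)

    def test_nonpositive_thickness_rejected(self):
        with pytest.raises(ValueError):
            pc.birefringence_from_phase(1.0, 0.0)


class TestColorLut:
    def test_zero_opd_entry_is_black(self, default_lut):
        assert default_lut.lab[0, 0] == 0.0
        np.testing.assert_array_equal(default_lut.rgb[0], 0.0)

    def test_first_order_max_chroma_between_500_and_600(self, default_lut):
        chroma = np.hypot(default_lut.lab[:, 1], default_lut.lab[:, 2])
        first_order = default_lut.opd_grid_nm <= 800.0
        peak = default_lut.opd_grid_nm[first_order][chroma[first_order].argmax()]
        assert 500.0 <= peak <= 600.0

    def test_avg_phase_strictly_increasing_and_proportional(self, default_lut):
        phi = default_lut.avg_phase_rad
        opd = default_lut.opd_grid_nm
        assert np.all(np.diff(phi) > 0)
        np.testing.assert_allclose(
            phi[1:], phi[1] / opd[1] * opd[1:], rtol=1e-12
        )

    def test_csv_roundtrip_and_byte_determinism(self, tmp_path, led, crossed_train):
        lut = pc.build_color_lut(led, crossed_train, 0, 200, 10.0)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        lut.to_csv(p1)
        pc.build_color_lut(led, crossed_train, 0, 200, 10.0).to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()
        again = ColorLUT.from_csv(p1)
        np.testing.assert_array_equal(again.opd_grid_nm, lut.opd_grid_nm)
        np.testing.assert_array_equal(again.lab, lut.lab)
        assert again.metadata["spectrum_sha256"] == lut.metadata["spectrum_sha256"]

    def test_invalid_grid_rejected(self, led, crossed_train):
        with pytest.raises(ValueError):
            pc.build_color_lut(led, crossed_train, 100, 50, 1.0)
        with pytest.raises(ValueError):
            pc.build_color_lut(led, crossed_train, 0, 100, -1.0)


class TestRetrievePhase:
    def test_lut_color_roundtrip_is_exact(self, default_lut):
        target = default_lut.opd_grid_nm == 1134.0
        image = np.tile(default_lut.rgb[target][0], (4, 4, 1))
        pm = pc.retrieve_phase(image, default_lut)
        np.testing.assert_array_equal(pm.opd_nm, 1134.0)
        assert pm.delta_e.max() < 1e-6

    def test_every_grid_point_roundtrips(self, led, crossed_train):
        lut = pc.build_color_lut(led, crossed_train, 0, 2000, 25.0)
        # Lab-domain roundtrip: the inverse-crime identity at every entry
        pm = pc.retrieve_phase_from_lab(lut.lab.reshape(1, -1, 3), lut)
        np.testing.assert_array_equal(pm.opd_nm.ravel(), lut.opd_grid_nm)
        # display-RGB roundtrip: exact wherever the color is inside the sRGB
        # gamut (saturated second-order colors clip and may alias)
        decoded = srgb_to_lab(lut.rgb, lut.white_xyz)
        in_gamut = pc.ciede2000(decoded, lut.lab) < 1e-6
        assert in_gamut.mean() > 0.5
        pm_rgb = pc.retrieve_phase(lut.rgb.reshape(1, -1, 3), lut)
        np.testing.assert_array_equal(
            pm_rgb.opd_nm.ravel()[in_gamut], lut.opd_grid_nm[in_gamut]
        )

    def test_black_image_ties_break_to_smallest_opd(self, default_lut):
        pm = pc.retrieve_phase(np.zeros((3, 3, 3)), default_lut)
        np.testing.assert_array_equal(pm.opd_nm, 0.0)

    def test_out_of_range_pixels_rejected(self, default_lut):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            pc.retrieve_phase(np.full((2, 2, 3), 1.5), default_lut)

    def test_noise_monte_carlo_matches_within_two_grid_steps(
        self, led, crossed_train
    ):
        # Gaussian Lab noise sigma=1 on 1e4 samples of LUT colors; >= 95% of
        # unambiguous pixels must land within 2 grid steps of the truth
        lut = pc.build_color_lut(led, crossed_train, 0, 2000, 20.0)
        rng = np.random.default_rng(7)
        idx = rng.integers(0, lut.opd_grid_nm.size, 10_000)
        lab = lut.lab[idx] + rng.normal(0.0, 1.0, (10_000, 3))
        pm = pc.retrieve_phase_from_lab(lab, lut)
        matched = np.searchsorted(lut.opd_grid_nm, pm.opd_nm.ravel())
        unambiguous = ~pm.ambiguous.ravel()
        within = np.abs(matched - idx) <= 2
        assert unambiguous.mean() > 0.5
        assert within[unambiguous].mean() >= 0.95

    def test_luminance_invariant_mode_ignores_exposure(self, led, crossed_train):
        lut = pc.build_color_lut(led, crossed_train, 0, 1500, 10.0)
        target = lut.opd_grid_nm == 700.0
        lab = lut.lab[target][0].copy()
        lab[0] *= 0.7  # exposure mismatch in L* only
        pm = pc.retrieve_phase_from_lab(
            lab.reshape(1, 1, 3), lut, luminance_invariant=True
        )
        assert pm.opd_nm[0, 0] == 700.0


class TestSignFromFwpPair:
    @staticmethod
    def _retrieved_pair(led, sign):
        train_plus = pc.OpticalTrainConfig(fwp_present=True, fwp_angle_deg=45.0)
        train_minus = pc.OpticalTrainConfig(fwp_present=True, fwp_angle_deg=-45.0)
        lut = pc.build_color_lut(led, pc.OpticalTrainConfig(), 0, 1500, 2.0)
        needle = pc.make_needle(30.0, 4.0, 45.0, 150.0, sign, (24, 24))
        img_p, _ = pc.render_scene(needle, led, train_plus)
        img_m, _ = pc.render_scene(needle, led, train_minus)
        return (
            pc.retrieve_phase(img_p, lut),
            pc.retrieve_phase(img_m, lut),
            needle,
        )

    def test_negative_birefringence_needle_classified_negative(self, led):
        pm_p, pm_m, needle = self._retrieved_pair(led, -1)
        signs = pc.sign_from_fwp_pair(pm_p, pm_m, object_axis_deg=45.0)
        on = needle.opd_nm > 0
        assert np.all(signs[on] == -1)

    def test_positive_birefringence_needle_classified_positive(self, led):
        pm_p, pm_m, needle = self._retrieved_pair(led, 1)
        signs = pc.sign_from_fwp_pair(pm_p, pm_m, object_axis_deg=45.0)
        on = needle.opd_nm > 0
        assert np.all(signs[on] == 1)

    def test_zero_opd_background_is_undetermined(self, led):
        pm_p, pm_m, needle = self._retrieved_pair(led, -1)
        signs = pc.sign_from_fwp_pair(pm_p, pm_m, object_axis_deg=45.0)
        off = needle.opd_nm == 0
        assert np.all(signs[off] == 0)

    def test_mismatched_shapes_rejected(self, led):
        pm_p, pm_m, _ = self._retrieved_pair(led, -1)
        import dataclasses

        smaller = dataclasses.replace(
            pm_m,
            opd_nm=pm_m.opd_nm[:10],
            avg_phase_rad=pm_m.avg_phase_rad[:10],
            delta_e=pm_m.delta_e[:10],
            ambiguous=pm_m.ambiguous[:10],
        )
        with pytest.raises(ValueError, match="shapes differ"):
            pc.sign_from_fwp_pair(pm_p, smaller, 45.0)
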