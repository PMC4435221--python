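"""Flight geometry, the image container and empirical-line calibration."""

import numpy as np
import pytest

from rowweed import (
    BoundsError,
    CalibrationError,
    CameraSpec,
    FieldImage,
    InvalidArgumentError,
    MULTISPECTRAL_CAMERA,
    PanelReference,
    VISIBLE_CAMERA,
    covered_area_ha,
    empirical_line_calibrate,
    gsd_at_altitude,
)
from rowweed.geometry import DOMAIN_DN


class TestFlightGeometry:
    @pytest.mark.parametrize(
        "camera, altitude, expected_cm",
        [
            (VISIBLE_CAMERA, 40.0, 1.52),  # identity at reference altitude
            (VISIBLE_CAMERA, 60.0, 2.28),
            (VISIBLE_CAMERA, 80.0, 3.04),
        ],
    )
    def test_gsd_examples(self, camera, altitude, expected_cm):
        assert gsd_at_altitude(camera, altitude) == pytest.approx(expected_cm, abs=0.005)

    @pytest.mark.parametrize(
        "camera, altitude, expected_ha",
        [
            (VISIBLE_CAMERA, 40.0, 0.28),
            (VISIBLE_CAMERA, 80.0, 1.13),
            (MULTISPECTRAL_CAMERA, 40.0, 0.06),
            (MULTISPECTRAL_CAMERA, 100.0, 0.38),
        ],
    )
    def test_covered_area_examples(self, camera, altitude, expected_ha):
        assert round(covered_area_ha(camera, altitude), 2) == expected_ha

    def test_gsd_linear_and_area_quadratic_in_altitude(self):
        alts = np.array([20.0, 40.0, 55.0, 90.0, 120.0])
        gsds = np.array([gsd_at_altitude(VISIBLE_CAMERA, a) for a in alts])
        areas = np.array([covered_area_ha(VISIBLE_CAMERA, a) for a in alts])
        np.testing.assert_allclose(gsds / alts, gsds[0] / alts[0], rtol=1e-12)
        np.testing.assert_allclose(areas / alts**2, areas[0] / alts[0] ** 2, rtol=1e-12)
        assert covered_area_ha(VISIBLE_CAMERA, 80.0) == pytest.approx(
            4.0 * covered_area_ha(VISIBLE_CAMERA, 40.0)
        )

    def test_footprint_ratio_constant_and_about_4_6(self):
        ratios = [
            covered_area_ha(VISIBLE_CAMERA, a) / covered_area_ha(MULTISPECTRAL_CAMERA, a)
            for a in (40.0, 60.0, 100.0)
        ]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-12)
        assert ratios[0] == pytest.approx(4.6, abs=0.05)

    def test_nonpositive_altitude_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gsd_at_altitude(VISIBLE_CAMERA, 0.0)
        with pytest.raises(InvalidArgumentError):
            covered_area_ha(VISIBLE_CAMERA, -10.0)

    def test_invalid_camera_spec_rejected(self):
        with pytest.raises(InvalidArgumentError):
            CameraSpec("bad", 0, 100, 40.0, 1.5, ("R",))
        with pytest.raises(InvalidArgumentError):
            CameraSpec("bad", 100, 100, 40.0, 1.5, ("R", "R"))


def _dn_image(values, bands=("b0",)):
    return FieldImage(values=values, bands=bands, gsd_m=0.02, domain=DOMAIN_DN)


class TestEmpiricalLine:
    def test_gain_only_hand_example(self):
        # panel mean DN 200 at reflectance 0.99 -> pixel DN 100 maps to 0.495
        img = _dn_image(np.array([[200.0, 100.0], [200.0, 50.0]]))
        panel = PanelReference(region=(0, 0, 2, 1), reflectance_per_band=(0.99,))
        cal = empirical_line_calibrate(img, panel)
        assert cal.values[0, 1, 0] == pytest.approx(0.495)
        assert cal.domain == "reflectance"

    def test_two_point_line_with_dark_reference(self):
        # dark mean 10 at rho 0, bright mean 200 at 0.99: DN 100 -> 0.99*90/190
        v = np.array([[200.0, 10.0, 100.0]])
        img = _dn_image(v)
        panel = PanelReference(
            region=(0, 0, 1, 1),
            reflectance_per_band=(0.99,),
            dark_region=(0, 1, 1, 2),
            dark_reflectance_per_band=(0.0,),
        )
        cal = empirical_line_calibrate(img, panel)
        assert cal.values[0, 2, 0] == pytest.approx(0.99 * 90.0 / 190.0)

    def test_calibrated_panel_mean_equals_panel_reflectance(self, rng):
        dn = rng.uniform(180, 220, size=(10, 10, 2))  # near-homogeneous panel
        img = _dn_image(dn, bands=("b0", "b1"))
        panel = PanelReference(region=(2, 2, 6, 6), reflectance_per_band=(0.9, 0.8))
        cal = empirical_line_calibrate(img, panel)
        means = cal.values[2:6, 2:6].reshape(-1, 2).mean(axis=0)
        np.testing.assert_allclose(means, [0.9, 0.8], rtol=1e-12)

    def test_round_trip_on_linear_sensor_is_exact(self, rng):
        # DN generated as reflectance/gain recovers reflectance to 1e-10
        rho = rng.uniform(0.02, 0.9, size=(12, 12, 3))
        rho[3:5, 3:5] = [0.95, 0.9, 0.85]
        gains = np.array([0.004, 0.005, 0.0036])
        img = FieldImage(rho / gains, bands=("a", "b", "c"), gsd_m=0.02, domain=DOMAIN_DN)
        panel = PanelReference(region=(3, 3, 5, 5), reflectance_per_band=(0.95, 0.9, 0.85))
        cal = empirical_line_calibrate(img, panel)
        np.testing.assert_allclose(cal.values, rho, rtol=1e-10)

    def test_panel_errors(self):
        img = _dn_image(np.zeros((4, 4)))
        panel = PanelReference(region=(0, 0, 2, 2), reflectance_per_band=(0.9,))
        with pytest.raises(CalibrationError):
            empirical_line_calibrate(img, panel)  # zero-mean panel
        img2 = _dn_image(np.ones((4, 4)))
        outside = PanelReference(region=(0, 0, 9, 9), reflectance_per_band=(0.9,))
        with pytest.raises(BoundsError):
            empirical_line_calibrate(img2, outside)
        with pytest.raises(CalibrationError):
            empirical_line_calibrate(
                empirical_line_calibrate(img2, PanelReference((0, 0, 2, 2), (0.9,))),
                PanelReference((0, 0, 2, 2), (0.9,)),
            )  # already reflectance

    def test_nodata_ignored_in_panel_statistics(self):
        v = np.full((4, 4), 200.0)
        v[0, 0] = np.nan
        img = _dn_image(v)
        panel = PanelReference(region=(0, 0, 2, 2), reflectance_per_band=(0.99,))
        cal = empirical_line_calibrate(img, panel)
        assert cal.values[3, 3, 0] == pytest.approx(0.99)
        assert np.isnan(cal.values[0, 0, 0])


class TestFieldImageIO:
    def test_save_load_round_trip(self, tmp_path, rng):
        img = FieldImage(
            rng.uniform(0, 1, (6, 5, 3)).astype(np.float32),
            bands=("R", "G", "B"),
            gsd_m=0.0152,
            origin=(10.0, 20.0),
        )
        img.save(tmp_path / "x.tif")
        back = FieldImage.load(tmp_path / "x.tif")
        np.testing.assert_allclose(back.values, img.values, rtol=1e-6)
        assert back.bands == ("R", "G", "B")
        assert back.gsd_m == pytest.approx(0.0152)
        assert back.origin == (10.0, 20.0)
        override = FieldImage.load(tmp_path / "x.tif", gsd_cm=3.0)
        assert override.gsd_m == pytest.approx(0.03)
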