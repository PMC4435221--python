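"""Synthetic scene generator: determinism, geometry, degradation, panel."""

import numpy as np
import pytest

from rowweed import (
    FieldSpec,
    InvalidArgumentError,
    degrade_to_altitude,
    degrade_to_gsd,
    embed_calibration_panel,
    empirical_line_calibrate,
    generate_field,
    to_digital_numbers,
)
from rowweed.classify import CROP, NODATA, SOIL, WEED
from rowweed.geometry import VISIBLE_CAMERA
from rowweed.rows import _normal_projection


class TestGenerateField:
    def test_same_seed_bit_identical(self):
        spec = FieldSpec(row_angle_deg=55.0, random_seed=42)
        a = generate_field(spec, gsd_m=0.02)
        b = generate_field(spec, gsd_m=0.02)
        np.testing.assert_array_equal(a.image.values, b.image.values)
        np.testing.assert_array_equal(a.truth, b.truth)
        np.testing.assert_array_equal(a.row_offsets_m, b.row_offsets_m)

    def test_zero_weed_density_empty_weed_mask(self):
        scene = generate_field(FieldSpec(weed_density_per_m2=0.0, random_seed=1), gsd_m=0.02)
        assert not (scene.truth == WEED).any()
        assert scene.n_weed_plants == 0

    def test_seven_rows_in_5m_perpendicular_span(self):
        spec = FieldSpec(field_size_m=(5.0, 5.0), row_angle_deg=0.0, random_seed=1)
        scene = generate_field(spec, gsd_m=0.025)
        assert len(scene.row_offsets_m) == 7  # first row at 0.35 m, then every 0.7 m
        np.testing.assert_allclose(np.diff(np.sort(scene.row_offsets_m)), 0.7)

    def test_weeds_never_touch_row_centreline_plants(self):
        spec = FieldSpec(weed_density_per_m2=6.0, random_seed=3)
        scene = generate_field(spec, gsd_m=0.015)
        weed_rc = np.argwhere(scene.truth == WEED)
        x = (weed_rc[:, 1] + 0.5) * scene.gsd_m
        y = spec.field_size_m[1] - (weed_rc[:, 0] + 0.5) * scene.gsd_m
        proj = _normal_projection(x, y, scene.row_angle_deg)
        d = np.min(np.abs(proj[:, None] - scene.row_offsets_m[None, :]), axis=1)
        # no weed pixel within the maximal plant radius of a row centreline
        assert (scene.truth == WEED).sum() == 0 or d.min() > spec.plant_radius_m[1]

    def test_weed_count_matches_density_within_poisson_error(self):
        spec = FieldSpec(weed_density_per_m2=2.0, random_seed=8, field_size_m=(6.0, 6.0))
        scene = generate_field(spec, gsd_m=0.03)
        # inter-row exclusion keeps roughly half of the sampled points
        expected_max = 2.0 * 36
        assert 0 < scene.n_weed_plants <= expected_max + 4 * np.sqrt(expected_max)

    def test_camera_altitude_resolution(self):
        spec = FieldSpec(field_size_m=(3.0, 3.0), random_seed=1)
        scene = generate_field(spec, camera=VISIBLE_CAMERA, altitude_m=40.0)
        assert scene.gsd_m == pytest.approx(0.0152)
        assert scene.truth.shape == (int(round(3 / 0.0152)),) * 2

    def test_frames_are_1m_and_inside(self, scene37):
        assert len(scene37.frames) == scene37.spec.n_frames
        side_px = int(round(1.0 / scene37.gsd_m))
        for fr in scene37.frames:
            r0, c0, r1, c1 = fr.window
            assert (r1 - r0, c1 - c0) == (side_px, side_px)
            assert 0 <= r0 and r1 <= scene37.truth.shape[0]
            np.testing.assert_array_equal(fr.observed, scene37.truth[r0:r1, c0:c1])


class TestDegrade:
    def test_integer_factor_shapes_and_mean_preserved(self, scene37):
        coarse = degrade_to_gsd(scene37, 0.030)
        h, w = scene37.truth.shape
        assert coarse.truth.shape == (h // 2, w // 2)
        np.testing.assert_allclose(
            coarse.image.values.mean(axis=(0, 1)),
            scene37.image.values[: h // 2 * 2, : w // 2 * 2].mean(axis=(0, 1)),
            rtol=1e-12,
        )

    def test_non_integer_factor_area_weighted(self, scene37):
        coarse = degrade_to_gsd(scene37, 0.0152 * 1.5)
        assert coarse.gsd_m == pytest.approx(0.0228)
        # total radiance is conserved up to the cropped margin
        assert abs(
            coarse.image.values[:, :, 0].mean() - scene37.image.values[:, :, 0].mean()
        ) < 0.01

    def test_majority_label_ground_truth(self):
        scene = generate_field(FieldSpec(random_seed=2), gsd_m=0.015)
        coarse = degrade_to_gsd(scene, 0.045)
        # a coarse pixel is weed only if weed was the plurality label
        fine = scene.truth[: coarse.truth.shape[0] * 3, : coarse.truth.shape[1] * 3]
        blocks = fine.reshape(coarse.truth.shape[0], 3, coarse.truth.shape[1], 3)
        weed_counts = (blocks == WEED).sum(axis=(1, 3))
        assert ((coarse.truth == WEED) <= (weed_counts > 0)).all()

    def test_upsampling_rejected(self, scene37):
        with pytest.raises(InvalidArgumentError):
            degrade_to_gsd(scene37, 0.01)

    def test_altitude_wrapper(self):
        spec = FieldSpec(field_size_m=(3.0, 3.0), random_seed=1)
        scene = generate_field(spec, camera=VISIBLE_CAMERA, altitude_m=40.0)
        coarse = degrade_to_altitude(scene, 80.0)
        assert coarse.gsd_m == pytest.approx(0.0304)
        with pytest.raises(InvalidArgumentError):
            degrade_to_altitude(scene, 30.0)


class TestPanel:
    def test_panel_region_size_and_nodata(self):
        scene = generate_field(FieldSpec(random_seed=4), gsd_m=0.015)
        with_panel = embed_calibration_panel(scene)
        r0, c0, r1, c1 = with_panel.panel.region
        assert (r1 - r0, c1 - c0) == (30, 30)  # 0.45 m at 1.5 cm
        assert (with_panel.truth[r0:r1, c0:c1] == NODATA).all()
        assert (scene.truth != NODATA).all()  # original untouched

    def test_panel_placed_on_bare_soil(self):
        scene = generate_field(FieldSpec(random_seed=4), gsd_m=0.015)
        with_panel = embed_calibration_panel(scene)
        r0, c0, r1, c1 = with_panel.panel.region
        assert (scene.truth[r0:r1, c0:c1] == SOIL).all()

    def test_calibration_round_trip_recovers_reflectance(self):
        spec = FieldSpec(noise_sd=0.0, illumination_gradient=0.0, random_seed=9)
        scene = embed_calibration_panel(generate_field(spec, gsd_m=0.015), noise_sd=0.0)
        dn = to_digital_numbers(scene.image, 1 / 255.0)
        cal = empirical_line_calibrate(dn, scene.panel)
        np.testing.assert_allclose(cal.values, scene.image.values, rtol=1e-10)

    def test_noisy_round_trip_recovers_crop_reflectance_within_2sd(self):
        spec = FieldSpec(random_seed=11, illumination_gradient=0.0)
        scene = embed_calibration_panel(generate_field(spec, gsd_m=0.015))
        dn = to_digital_numbers(scene.image, 1 / 255.0)
        cal = empirical_line_calibrate(dn, scene.panel)
        crop_mean = cal.values[scene.truth == CROP].mean(axis=0)
        from rowweed.synth import DEFAULT_REFLECTANCE

        for bi, band in enumerate(scene.image.bands):
            mean, sd = DEFAULT_REFLECTANCE["crop"][band]
            assert abs(crop_mean[bi] - mean) < 2 * sd + 0.05  # falloff dims the mean
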