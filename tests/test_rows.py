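"""Crop-row orientation, stripe level construction and row classification."""

import numpy as np
import pandas as pd
import pytest

from rowweed import (
    FieldImage,
    FieldSpec,
    InvalidArgumentError,
    ObjectMap,
    build_stripe_level,
    classify_buffer_and_noncrop,
    classify_crop_rows,
    estimate_row_orientation,
    generate_field,
)
from rowweed.classify import run_row_detection
from rowweed.errors import NoRowsError, NoVegetationError
from rowweed.rows import BUFFER, CROP_ROW, MASKED, NON_CROP, StripeLevel, UNCLASSIFIED
from rowweed.synth import score_row_detection


def _objects_image(centres_rc, sizes, window_px=100, gsd=0.05):
    """A minimal ObjectMap stand-in: single-pixel labels at given centroids."""
    labels = np.full((window_px, window_px), -1, dtype=np.int64)
    values = np.zeros((window_px, window_px, 1))
    for i, (r, c) in enumerate(centres_rc):
        labels[r, c] = i
    om = ObjectMap.from_labels(values, labels)
    rc = om.centroid_rc  # keep centroids fixed while faking pixel counts
    om.size = np.asarray(sizes, dtype=np.int64)
    om.centroid_sum = rc * om.size[:, None]
    img = FieldImage(values, bands=("x",), gsd_m=gsd)
    return om, img


def _synthetic_level(fractions, width=0.175, spacing=0.7):
    """Hand-built StripeLevel with prescribed vegetation fractions."""
    n = len(fractions)
    df = pd.DataFrame(
        {
            "index": np.arange(n),
            "area_px": np.full(n, 1000.0),
            "veg_area_px": np.asarray(fractions) * 1000.0,
            "veg_fraction": np.asarray(fractions, dtype=float),
            "klass": UNCLASSIFIED,
        }
    )
    level = StripeLevel(
        angle_deg=0.0, stripe_width_m=width, phase_m=0.0, origin_offset_m=0.0,
        stripes=df, object_stripe=np.zeros(0, dtype=int), row_spacing_m=spacing,
    )
    df["centre_offset_m"] = level.stripe_centre_offset(df["index"].to_numpy())
    return level


class TestStripeLevelConstruction:
    def test_stripe_count_for_5m_window(self):
        scene = generate_field(FieldSpec(field_size_m=(5.0, 5.0), random_seed=1), gsd_m=0.025)
        from rowweed.classify import prepare_vegetation_objects, PipelineConfig

        diag = {"stages": []}
        _, _, _, _, objects, _, veg = prepare_vegetation_objects(
            scene.image, PipelineConfig(), diag
        )
        level = build_stripe_level(
            objects, veg, scene.image, 0.0, stripe_width_m=0.35, phase=0.0
        )
        assert len(level.stripes) == int(np.ceil(5.0 / 0.35))  # 15 stripes

    def test_all_soil_window_has_zero_fractions(self):
        om, img = _objects_image([(10, 10), (50, 50)], [100, 100])
        veg = np.array([False, False])
        level = build_stripe_level(om, veg, img, 0.0, stripe_width_m=0.35, phase=0.0)
        assert (level.stripes["veg_fraction"] == 0).all()

    def test_point_on_boundary_goes_to_lower_index_stripe(self):
        from rowweed.rows import _stripe_index

        # stripes of width 0.5 from origin 0: boundary at 1.0 belongs to
        # stripe 1 (the lower-index side), interior points use plain floor
        idx = _stripe_index(np.array([1.0, 0.999, 1.001, 0.0]), 0.0, 0.5)
        assert idx.tolist() == [1, 1, 2, 0]

    def test_stripe_width_below_pixel_rejected(self):
        om, img = _objects_image([(10, 10)], [1])
        with pytest.raises(InvalidArgumentError):
            build_stripe_level(om, np.array([True]), img, 0.0, stripe_width_m=0.01)

    def test_membership_is_a_partition_of_objects(self, scene37, classmap37):
        level = classmap37.diagnostics["stripe_levels"][0]
        assert level.object_stripe.min() >= 0
        assert level.object_stripe.max() < len(level.stripes)


class TestOrientation:
    @pytest.mark.parametrize("angle", [0.0, 37.0])
    def test_recovers_generated_orientation(self, angle):
        scene = generate_field(FieldSpec(row_angle_deg=angle, random_seed=7), gsd_m=0.03)
        level, diag = run_row_detection(scene.image)
        est = diag["row_angle_deg"]
        delta = min(abs(est - angle), 180.0 - abs(est - angle))
        assert delta <= 1.0

    def test_rotation_equivariance(self):
        # generating the same field rotated by delta shifts the estimate by delta
        base, delta = 23.0, 48.0
        ests = []
        for angle in (base, base + delta):
            scene = generate_field(
                FieldSpec(row_angle_deg=angle, weed_density_per_m2=0.0, random_seed=13),
                gsd_m=0.03,
            )
            _, diag = run_row_detection(scene.image)
            ests.append(diag["row_angle_deg"])
        shift = (ests[1] - ests[0]) % 180.0
        assert min(shift, 180.0 - shift) == pytest.approx(delta, abs=1.0)

    def test_rowless_field_scores_much_lower_than_rowed_field(self):
        rng = np.random.default_rng(5)
        # uniform random vegetation: many small objects, no line structure
        flat = rng.choice(96 * 96, size=600, replace=False)
        centres = [(2 + f // 96, 2 + f % 96) for f in flat]
        om, img = _objects_image(centres, [8] * len(centres))
        veg = np.ones(len(centres), dtype=bool)
        _, score_random = estimate_row_orientation(om, veg, img, stripe_width_m=0.35)

        scene = generate_field(FieldSpec(row_angle_deg=0.0, random_seed=7), gsd_m=0.03)
        _, diag = run_row_detection(scene.image)
        assert score_random < 0.2 * diag["row_angle_score"]

    def test_no_vegetation_raises(self):
        om, img = _objects_image([(10, 10)], [1])
        with pytest.raises(NoVegetationError):
            estimate_row_orientation(om, np.array([False]), img)


class TestRowClassification:
    def test_synthetic_rows_detected_at_true_centrelines(self, scene37):
        level, _ = run_row_detection(scene37.image)
        score = score_row_detection(scene37, level)
        assert score["passed"]
        assert score["n_detected"] == len(scene37.row_offsets_m)
        assert score["max_distance_m"] <= 0.35

    def test_strong_neighbour_within_spacing_is_masked(self):
        # fractions 0.9 and 0.85 at 0.35 m separation (mask radius
        # 0.7 - 0.175 = 0.525): the 0.85 stripe is masked, one row only
        level = _synthetic_level([0.9, 0.85, 0.05, 0.05, 0.05], width=0.35)
        classify_crop_rows(level)
        klass = level.stripes["klass"].tolist()
        assert klass[0] == CROP_ROW
        assert klass[1] == MASKED
        assert CROP_ROW not in klass[1:]

    def test_weed_stripe_near_stronger_row_is_masked_not_row(self):
        # high-vegetation weed patch one stripe (0.35 m < mask radius) from a
        # stronger row stripe: masked, never a crop row
        level = _synthetic_level([0.9, 0.6, 0.05, 0.05, 0.9], width=0.35)
        classify_crop_rows(level)
        klass = level.stripes["klass"].tolist()
        assert klass[0] == CROP_ROW and klass[4] == CROP_ROW
        assert klass[1] == MASKED

    def test_row_spacing_constraint_on_output(self, scene37):
        level, _ = run_row_detection(scene37.image)
        offs = np.sort(level.crop_row_offsets())
        assert np.all(np.diff(offs) >= level.row_spacing_m - 1e-9)

    def test_no_rows_error_on_bare_level(self):
        level = _synthetic_level([0.0, 0.01, 0.0])
        with pytest.raises(NoRowsError):
            classify_crop_rows(level)


class TestBufferAndNonCrop:
    def test_adjacency_rule(self):
        level = _synthetic_level([0.0] * 12)
        level.stripes.loc[[3, 10], "klass"] = CROP_ROW
        klass = level.stripes["klass"].copy()
        level.stripes["klass"] = [
            CROP_ROW if i in (3, 10) else UNCLASSIFIED for i in range(12)
        ]
        classify_buffer_and_noncrop(level)
        out = level.stripes["klass"].tolist()
        assert [i for i, k in enumerate(out) if k == BUFFER] == [2, 4, 9, 11]
        assert all(k == NON_CROP for i, k in enumerate(out) if i not in (2, 3, 4, 9, 10, 11))

    def test_edge_row_gets_single_sided_buffer(self):
        level = _synthetic_level([0.0] * 5)
        level.stripes["klass"] = [CROP_ROW] + [UNCLASSIFIED] * 4
        classify_buffer_and_noncrop(level)
        assert level.stripes["klass"].tolist() == [CROP_ROW, BUFFER, NON_CROP, NON_CROP, NON_CROP]

    def test_masked_stripes_become_buffer_when_adjacent(self):
        level = _synthetic_level([0.0] * 4)
        level.stripes["klass"] = [CROP_ROW, MASKED, MASKED, UNCLASSIFIED]
        classify_buffer_and_noncrop(level)
        assert level.stripes["klass"].tolist() == [CROP_ROW, BUFFER, NON_CROP, NON_CROP]
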