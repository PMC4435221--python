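"""Crop/weed discrimination and the end-to-end weed-mapping pipeline.

The central agronomic assumption: in a row crop, plants growing *between*
the rows are weeds.  Vegetation objects are therefore classified by where
they sit in the upper stripe level —

* under a crop-row stripe  -> crop,
* under a non-crop stripe  -> weed,
* under a buffer stripe    -> unresolved, settled afterwards by minimum
  spectral distance to the surrounding already-classified crop and weed
  objects (nearest class in per-band mean space; exact tie -> weed, the
  conservative choice for treatment decisions).

``run_weed_mapping`` chains every stage: optional calibration, vegetation
index, sub-plot grid, multiresolution segmentation, per-sub-plot Otsu
threshold, vegetation labelling, field-wide orientation, per-sub-plot stripe
levels, row/buffer classification, hierarchical assignment and buffer
resolution, producing a per-pixel/per-object class map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import NoVegetationError, RowweedError
from .geometry import DOMAIN_REFLECTANCE, FieldImage, PanelReference, empirical_line_calibrate
from .indices import EXG, NDVI, compute_exg, compute_ndvi, classify_vegetation_objects, object_mean_index, otsu_threshold
from .segmentation import ObjectMap, SegmentationParams, grid_subplots, segment_subplots
from .rows import (
    BUFFER,
    CROP_ROW,
    NON_CROP,
    StripeLevel,
    build_stripe_level,
    classify_buffer_and_noncrop,
    classify_crop_rows,
    default_stripe_width,
    estimate_row_orientation,
)

log = logging.getLogger("rowweed")

SOIL, CROP, WEED, NODATA = 0, 1, 2, 255
UNRESOLVED = "unresolved"

CLASS_NAMES = {SOIL: "soil", CROP: "crop", WEED: "weed", NODATA: "nodata"}


@dataclass
class ClassMap:
    """Final classification: per-pixel codes and per-object classes.

    ``labels``: uint8 raster with 0 soil, 1 crop, 2 weed, 255 nodata.
    ``object_class``: per-object code; ``assigned_by``: 'hierarchy' or
    'spectral_distance' per object ('' for soil).
    """

    labels: np.ndarray
    object_class: np.ndarray
    assigned_by: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def class_fraction(self, code: int) -> float:
        valid = self.labels != NODATA
        return float(np.mean(self.labels[valid] == code)) if valid.any() else 0.0


def hierarchical_assign(
    objects: ObjectMap,
    vegetation: np.ndarray,
    level: StripeLevel,
) -> np.ndarray:
    """Assign each object crop/weed/unresolved/soil from its stripe class.

    Returns an object-length array of strings.
    """
    classes = level.classes()
    out = np.empty(objects.n_objects, dtype=object)
    stripe_of = level.object_stripe
    for i in range(objects.n_objects):
        if not vegetation[i]:
            out[i] = "soil"
            continue
        s = int(stripe_of[i])
        if s not in classes.index:
            raise RowweedError(f"object {i} has no stripe assignment")
        k = classes.loc[s]
        if k == CROP_ROW:
            out[i] = "crop"
        elif k == NON_CROP:
            out[i] = "weed"
        elif k == BUFFER:
            out[i] = UNRESOLVED
        else:  # masked/unclassified stripes behave as non-crop area
            out[i] = "weed"
    return out


def resolve_buffer_objects(
    assignment: np.ndarray,
    objects: ObjectMap,
    use_index_values: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Settle 'unresolved' objects by minimum spectral distance.

    For each unresolved object the adjacency graph is searched outwards
    (graph radius 1, then doubled: 2, 4, ...) for already-classified crop and
    weed exemplars (classified by hierarchy, so the outcome does not depend
    on resolution order); once the search ring holds at least one of each —
    or the whole field has been reached — the object takes the class whose
    exemplar mean vector is nearest in Euclidean distance over per-band
    means.  Ties and the one-class-only degenerate cases resolve
    conservatively: tie -> weed; only crop present -> crop; only weed ->
    weed; no classified vegetation anywhere -> weed (flagged).

    ``use_index_values`` switches the feature space from per-band means to a
    per-object scalar index value.

    Returns
    -------
    (assignment, flagged): final per-object classes and a flag array marking
    objects that were defaulted with no exemplars at all.
    """
    assignment = assignment.copy()
    flagged = np.zeros(objects.n_objects, dtype=bool)
    unresolved = np.flatnonzero(assignment == UNRESOLVED)
    if unresolved.size == 0:
        return assignment, flagged

    feats = (
        np.asarray(use_index_values, dtype=np.float64)[:, None]
        if use_index_values is not None
        else objects.band_mean
    )
    is_crop = assignment == "crop"
    is_weed = assignment == "weed"
    any_crop, any_weed = bool(is_crop.any()), bool(is_weed.any())

    if not any_crop and not any_weed:
        assignment[unresolved] = "weed"
        flagged[unresolved] = True
        return assignment, flagged

    adj = objects.adjacency_sets()
    global_crop = feats[is_crop].mean(axis=0) if any_crop else None
    global_weed = feats[is_weed].mean(axis=0) if any_weed else None

    for i in unresolved:
        # expanding ring BFS: radius 1, 2, 4, ... until both classes seen
        radius = 1
        crop_mean = weed_mean = None
        while True:
            seen = {int(i)}
            frontier = {int(i)}
            for _ in range(radius):
                frontier = {nb for f in frontier for nb in adj[f]} - seen
                if not frontier:
                    break
                seen |= frontier
            ring = np.array(sorted(seen - {int(i)}), dtype=int)
            if ring.size:
                rc = ring[is_crop[ring]]
                rw = ring[is_weed[ring]]
                if rc.size:
                    crop_mean = feats[rc].mean(axis=0)
                if rw.size:
                    weed_mean = feats[rw].mean(axis=0)
            if (crop_mean is not None or not any_crop) and (
                weed_mean is not None or not any_weed
            ):
                break
            if radius >= objects.n_objects:
                crop_mean = global_crop if crop_mean is None else crop_mean
                weed_mean = global_weed if weed_mean is None else weed_mean
                break
            radius *= 2
        if crop_mean is None and weed_mean is None:
            assignment[i] = "weed"
            flagged[i] = True
        elif crop_mean is None:
            assignment[i] = "weed"
        elif weed_mean is None:
            assignment[i] = "crop"
        else:
            d_crop = float(np.linalg.norm(feats[i] - crop_mean))
            d_weed = float(np.linalg.norm(feats[i] - weed_mean))
            assignment[i] = "weed" if d_weed <= d_crop else "crop"
    return assignment, flagged


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs beyond the image itself."""

    index: str = EXG  # "ExG" or "NDVI"
    red_band: str = "R670"  # NDVI red channel (670 or 700 nm)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    subplot_size_m: float = 5.0
    stripe_width_m: float | None = None  # default: row_spacing / 4
    row_spacing_m: float = 0.7
    stop_ratio: float = 0.5
    min_row_fraction: float = 0.05
    otsu_mode: str = "subplot"  # or "global"
    spectral_distance_on_index: bool = False
    panel: PanelReference | None = None

    def resolved_stripe_width(self) -> float:
        return (
            self.stripe_width_m
            if self.stripe_width_m is not None
            else default_stripe_width(self.row_spacing_m)
        )


def prepare_vegetation_objects(image: FieldImage, config: PipelineConfig, diagnostics: dict):
    """Shared front end of the pipeline: calibrate, index, segment, threshold.

    Returns ``(image, index, grid, labels, objects, means, vegetation)``.
    """

    def stage(name):
        log.info("stage: %s", name)
        diagnostics["stages"].append(name)

    if config.panel is not None:
        stage("calibrate")
        image = empirical_line_calibrate(image, config.panel)

    stage("index")
    if config.index == NDVI:
        index = compute_ndvi(image, red_band=config.red_band)
    else:
        index = compute_exg(image)

    stage("grid")
    grid = grid_subplots(image, config.subplot_size_m)

    stage("segment")
    seg_values = image.values
    if image.domain == DOMAIN_REFLECTANCE:
        seg_values = seg_values * 255.0  # scale parameter assumes 8-bit range
    labels = segment_subplots(seg_values, grid, config.segmentation)
    objects = ObjectMap.from_labels(image.values, labels)
    if objects.n_objects == 0:
        raise NoVegetationError("image contains no valid pixels")
    log.info("%d objects over %d sub-plots", objects.n_objects, len(grid.windows))

    stage("otsu")
    means = object_mean_index(index, labels, objects.n_objects)
    if config.otsu_mode == "global":
        thr = otsu_threshold(index.values).threshold
        obj_thr = np.full(objects.n_objects, thr)
        diagnostics["thresholds"] = {"global": thr}
    else:
        obj_thr = np.full(objects.n_objects, np.nan)
        diagnostics["thresholds"] = {}
        for wi, (r0, c0, r1, c1) in enumerate(grid.windows):
            sub_labels = labels[r0:r1, c0:c1]
            ids = np.unique(sub_labels[sub_labels >= 0])
            if ids.size == 0:
                continue
            vals = index.values[r0:r1, c0:c1]
            vals = vals[np.isfinite(vals)]
            try:
                thr = otsu_threshold(vals).threshold
            except RowweedError:
                thr = np.inf  # constant sub-plot: nothing is vegetation
            obj_thr[ids] = thr
            diagnostics["thresholds"][wi] = float(thr)

    stage("vegetation")
    vegetation, flagged = classify_vegetation_objects(means, obj_thr)
    if not vegetation.any():
        raise NoVegetationError("no vegetation objects found in the image")
    diagnostics["n_flagged_vegetation"] = int(flagged.sum())
    return image, index, grid, labels, objects, means, vegetation


def run_row_detection(
    image: FieldImage, config: PipelineConfig | None = None
) -> tuple["StripeLevel", dict]:
    """Run the pipeline through crop-row classification over the whole image.

    Builds a single field-wide stripe level at the estimated orientation and
    classifies rows/buffers on it.  Returns the stripe level and the
    diagnostics dict (row angle, thresholds, ...).
    """
    config = config or PipelineConfig()
    diagnostics: dict = {"stages": []}
    image, index, grid, labels, objects, means, vegetation = prepare_vegetation_objects(
        image, config, diagnostics
    )
    angle, score = estimate_row_orientation(
        objects, vegetation, image, stripe_width_m=config.resolved_stripe_width()
    )
    diagnostics["row_angle_deg"] = angle
    diagnostics["row_angle_score"] = score
    level = build_stripe_level(
        objects,
        vegetation,
        image,
        angle,
        stripe_width_m=config.resolved_stripe_width(),
        row_spacing_m=config.row_spacing_m,
    )
    classify_crop_rows(level, stop_ratio=config.stop_ratio, min_fraction=config.min_row_fraction)
    classify_buffer_and_noncrop(level)
    return level, diagnostics


def run_weed_mapping(image: FieldImage, config: PipelineConfig | None = None) -> ClassMap:
    """Run the full pipeline on one image; returns the final :class:`ClassMap`.

    Deterministic: no stage draws random numbers.  Per-sub-plot diagnostics
    (thresholds, row angle, stripe levels) are collected on the result's
    ``diagnostics`` dict.
    """
    config = config or PipelineConfig()
    diagnostics: dict = {"stages": []}

    def stage(name):
        log.info("stage: %s", name)
        diagnostics["stages"].append(name)

    image, index, grid, labels, objects, means, vegetation = prepare_vegetation_objects(
        image, config, diagnostics
    )

    stage("orientation")
    angle, score = estimate_row_orientation(
        objects, vegetation, image, stripe_width_m=config.resolved_stripe_width()
    )
    diagnostics["row_angle_deg"] = angle
    diagnostics["row_angle_score"] = score

    stage("rows")
    assignment = np.empty(objects.n_objects, dtype=object)
    assignment[:] = "soil"
    levels = {}
    object_window = np.full(objects.n_objects, -1, dtype=np.int64)
    h, w = image.shape
    for wi, window in enumerate(grid.windows):
        r0, c0, r1, c1 = window
        in_win = np.zeros(objects.n_objects, dtype=bool)
        ids = np.unique(labels[r0:r1, c0:c1])
        ids = ids[ids >= 0]
        in_win[ids] = True
        object_window[ids] = wi
        if not (vegetation & in_win).any():
            continue  # all-soil sub-plot: everything stays soil
        level = build_stripe_level(
            objects,
            vegetation,
            image,
            angle,
            window=window,
            stripe_width_m=config.resolved_stripe_width(),
            row_spacing_m=config.row_spacing_m,
        )
        try:
            classify_crop_rows(level, stop_ratio=config.stop_ratio, min_fraction=config.min_row_fraction)
        except RowweedError:
            # no rows in this sub-plot: all vegetation counts as weed, flagged
            level.stripes["klass"] = NON_CROP
            diagnostics.setdefault("no_row_subplots", []).append(wi)
            sub_assign = np.where(vegetation, "weed", "soil")
        else:
            classify_buffer_and_noncrop(level)
            sub_assign = hierarchical_assign(objects, vegetation, level)
        assignment[in_win] = sub_assign[in_win]
        levels[wi] = level
    diagnostics["stripe_levels"] = levels
    diagnostics["object_window"] = object_window

    stage("buffer-resolution")
    feats = None
    if config.spectral_distance_on_index:
        feats = means
    was_unresolved = assignment == UNRESOLVED
    assignment, res_flagged = resolve_buffer_objects(assignment, objects, use_index_values=feats)

    stage("classmap")
    code = np.full(objects.n_objects, SOIL, dtype=np.uint8)
    code[assignment == "crop"] = CROP
    code[assignment == "weed"] = WEED
    assigned_by = np.where(was_unresolved, "spectral_distance", "hierarchy").astype(object)
    pix = np.full(image.shape, NODATA, dtype=np.uint8)
    ok = labels >= 0
    pix[ok] = code[labels[ok]]
    diagnostics["flagged_objects"] = int(
        diagnostics.get("n_flagged_vegetation", 0) + res_flagged.sum()
    )
    return ClassMap(
        labels=pix,
        object_class=code,
        assigned_by=assigned_by,
        diagnostics=diagnostics,
    )
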