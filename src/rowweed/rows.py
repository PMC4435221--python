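"""Crop-row structure: orientation estimate, stripe level, row classification.

Row crops are sown along parallel lines at a known spacing (0.7 m for
sunflower).  The field is therefore re-segmented at an *upper level* into
parallel stripes: for a candidate orientation the window is cut into bands of
constant signed distance from a line at that angle, each lower-level object
is assigned to the stripe containing its centroid, and per-stripe vegetation
fractions are computed.  At the true row orientation the fractions alternate
between vegetation-rich (rows) and vegetation-poor (inter-row) stripes, which
maximises their variance across stripes; that variance is the per-angle score
scanned over 0..180 degrees.

Row classification then greedily picks the unmasked stripe with the highest
vegetation fraction as a crop row and masks every stripe whose centreline
lies within ``row_spacing - width/2`` of it, so that a heavily weed-infested
stripe right next to a row can never itself be classified as a row.  The
remaining stripes become crop-row *buffer* (touching a row) or *non-crop*.

Angles are measured counterclockwise from the world x-axis (east), modulo
180 degrees.  The stripe normal is ``(-sin a, cos a)``; a stripe's
``centre_offset`` is the signed projection of its centreline onto that
normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, NoRowsError, NoVegetationError
from .geometry import FieldImage
from .segmentation import ObjectMap

CROP_ROW = "crop_row"
BUFFER = "buffer"
NON_CROP = "non_crop"
MASKED = "masked"
UNCLASSIFIED = "unclassified"

DEFAULT_ROW_SPACING_M = 0.7


def default_stripe_width(row_spacing_m: float = DEFAULT_ROW_SPACING_M) -> float:
    """Default stripe width: a quarter of the row spacing.

    A quarter-spacing mesh leaves at least one stripe per inter-row lane that
    touches no crop-row stripe, so the positional (non-crop) weed class is
    never empty by construction.
    """
    return row_spacing_m / 4.0


@dataclass
class StripeLevel:
    """The upper segmentation level: parallel stripes over a window.

    ``stripes`` columns: ``index`` (along the normal), ``centre_offset_m``
    (signed world offset of the stripe centreline), ``area_px`` (geometric
    pixel count), ``veg_area_px`` (pixel area of vegetation objects assigned
    by centroid), ``veg_fraction`` (clipped to [0, 1]) and ``klass``.
    ``object_stripe`` maps every lower-level object id to a stripe index.
    """

    angle_deg: float
    stripe_width_m: float
    phase_m: float
    origin_offset_m: float  # projection value at stripe index 0's lower edge
    stripes: pd.DataFrame
    object_stripe: np.ndarray
    row_spacing_m: float = DEFAULT_ROW_SPACING_M
    score: float = float("nan")

    def stripe_centre_offset(self, index: np.ndarray | int) -> np.ndarray | float:
        """World signed offset of stripe centreline(s) along the normal."""
        return self.origin_offset_m + self.phase_m + (np.asarray(index) + 0.5) * self.stripe_width_m

    def classes(self) -> pd.Series:
        return self.stripes.set_index("index")["klass"]

    def crop_row_offsets(self) -> np.ndarray:
        rows = self.stripes[self.stripes["klass"] == CROP_ROW]
        return np.asarray(self.stripe_centre_offset(rows["index"].to_numpy()), dtype=float)


def _normal_projection(x: np.ndarray, y: np.ndarray, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return -x * np.sin(a) + y * np.cos(a)


def _stripe_index(proj: np.ndarray, p0: float, width: float) -> np.ndarray:
    """Stripe index with boundary points assigned to the lower-index side."""
    q = (np.asarray(proj, dtype=np.float64) - p0) / width
    idx = np.ceil(q).astype(np.int64) - 1
    idx[np.asarray(proj) == p0] = 0
    return idx


def _window_pixel_projections(
    image: FieldImage, window: tuple[int, int, int, int], angle_deg: float
) -> np.ndarray:
    r0, c0, r1, c1 = window
    cols = np.arange(c0, c1) + 0.5
    rows = np.arange(r0, r1) + 0.5
    x = image.origin[0] + cols[None, :] * image.gsd_m
    y = image.origin[1] - rows[:, None] * image.gsd_m
    return _normal_projection(x, y, angle_deg).ravel()


def _fractions_for(
    proj_pixels: np.ndarray,
    proj_centroids: np.ndarray,
    obj_sizes: np.ndarray,
    veg: np.ndarray,
    width: float,
    phase: float,
):
    """Per-stripe geometric areas, vegetation areas and clipped fractions."""
    p0 = float(np.min(proj_pixels)) - 1e-9
    pix_idx = _stripe_index(proj_pixels, p0 + phase, width)
    obj_idx = _stripe_index(proj_centroids, p0 + phase, width)
    lo = min(int(pix_idx.min()), int(obj_idx.min()) if obj_idx.size else 0)
    pix_idx -= lo
    obj_idx -= lo
    n = int(max(pix_idx.max(), obj_idx.max() if obj_idx.size else 0)) + 1
    area = np.bincount(pix_idx, minlength=n).astype(np.float64)
    veg_area = np.bincount(obj_idx[veg], weights=obj_sizes[veg], minlength=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.clip(np.where(area > 0, veg_area / np.maximum(area, 1), 0.0), 0.0, 1.0)
    return area, veg_area, frac, p0, lo


def _score(area: np.ndarray, frac: np.ndarray) -> float:
    """Area-weighted variance of the vegetation fraction across stripes."""
    total = area.sum()
    if total == 0:
        return 0.0
    mean = float(np.sum(area * frac) / total)
    return float(np.sum(area * (frac - mean) ** 2) / total)


def estimate_row_orientation(
    objects: ObjectMap,
    vegetation: np.ndarray,
    image: FieldImage,
    window: tuple[int, int, int, int] | None = None,
    stripe_width_m: float | None = None,
    angle_step_deg: float = 1.0,
) -> tuple[float, float]:
    """Scan candidate orientations 0..180 deg and return ``(angle, score)``.

    The score of an angle is the area-weighted variance of the per-stripe
    vegetation fraction; ties go to the smallest angle.  A near-zero score
    relative to competing angles indicates no row structure (the caller may
    flag low confidence).
    """
    if window is None:
        window = (0, 0, image.shape[0], image.shape[1])
    if stripe_width_m is None:
        stripe_width_m = default_stripe_width()
    vegetation = np.asarray(vegetation, dtype=bool)
    if not vegetation.any():
        raise NoVegetationError("orientation estimate needs at least one vegetation object")

    centroids = objects.centroid_world(image.gsd_m, image.origin)
    sizes = objects.size.astype(np.float64)

    best_angle, best_score = 0.0, -1.0
    for angle in np.arange(0.0, 180.0, angle_step_deg):
        proj_pix = _window_pixel_projections(image, window, angle)
        proj_obj = _normal_projection(centroids[:, 0], centroids[:, 1], angle)
        area, _, frac, _, _ = _fractions_for(
            proj_pix, proj_obj, sizes, vegetation, stripe_width_m, 0.0
        )
        s = _score(area, frac)
        if s > best_score:
            best_angle, best_score = float(angle), s
    return best_angle, best_score


def build_stripe_level(
    objects: ObjectMap,
    vegetation: np.ndarray,
    image: FieldImage,
    angle_deg: float,
    window: tuple[int, int, int, int] | None = None,
    stripe_width_m: float | None = None,
    row_spacing_m: float = DEFAULT_ROW_SPACING_M,
    phase: str | float = "auto",
    n_phase_steps: int = 8,
) -> StripeLevel:
    """Build the upper stripe level over ``window`` at a fixed orientation.

    ``phase`` shifts the stripe mesh along the normal direction.  With
    ``"auto"`` the offset in ``[0, width)`` maximising the variance score is
    chosen, which centres rows inside stripes instead of letting a row
    straddle a stripe boundary (where its vegetation would split between two
    stripes).  Pass a float for a fixed phase.
    """
    if not 0.0 <= angle_deg < 180.0:
        raise InvalidArgumentError("angle must lie in [0, 180)")
    if window is None:
        window = (0, 0, image.shape[0], image.shape[1])
    if stripe_width_m is None:
        stripe_width_m = default_stripe_width(row_spacing_m)
    if stripe_width_m < image.gsd_m:
        raise InvalidArgumentError("stripe width is smaller than one pixel")
    vegetation = np.asarray(vegetation, dtype=bool)

    # only objects whose centroid lies inside the window feed the stripe
    # vegetation fractions (out-of-window objects still get a stripe index,
    # but contribute nothing)
    r0, c0, r1, c1 = window
    rc = objects.centroid_rc
    in_window = (
        (rc[:, 0] >= r0) & (rc[:, 0] < r1) & (rc[:, 1] >= c0) & (rc[:, 1] < c1)
    )
    vegetation = vegetation & in_window

    centroids = objects.centroid_world(image.gsd_m, image.origin)
    sizes = objects.size.astype(np.float64)
    proj_pix = _window_pixel_projections(image, window, angle_deg)
    proj_obj = _normal_projection(centroids[:, 0], centroids[:, 1], angle_deg)

    if phase == "auto":
        best_phase, best_s = 0.0, -1.0
        for ph in np.linspace(0.0, stripe_width_m, n_phase_steps, endpoint=False):
            area, _, frac, _, _ = _fractions_for(
                proj_pix, proj_obj, sizes, vegetation, stripe_width_m, ph
            )
            s = _score(area, frac)
            if s > best_s:
                best_phase, best_s = float(ph), s
        phase_m = best_phase
    else:
        phase_m = float(phase)

    area, veg_area, frac, p0, lo = _fractions_for(
        proj_pix, proj_obj, sizes, vegetation, stripe_width_m, phase_m
    )
    n = area.shape[0]
    obj_idx = _stripe_index(proj_obj, p0 + phase_m, stripe_width_m) - lo
    stripes = pd.DataFrame(
        {
            "index": np.arange(n),
            "area_px": area,
            "veg_area_px": veg_area,
            "veg_fraction": frac,
            "klass": UNCLASSIFIED,
        }
    )
    level = StripeLevel(
        angle_deg=float(angle_deg),
        stripe_width_m=float(stripe_width_m),
        phase_m=phase_m,
        origin_offset_m=p0 + lo * stripe_width_m,
        stripes=stripes,
        object_stripe=obj_idx,
        row_spacing_m=row_spacing_m,
    )
    level.stripes["centre_offset_m"] = level.stripe_centre_offset(stripes["index"].to_numpy())
    return level


def classify_crop_rows(
    level: StripeLevel,
    stop_ratio: float = 0.5,
    min_fraction: float = 0.05,
) -> StripeLevel:
    """Greedy row selection with neighbour masking (in place; also returned).

    Repeatedly the unmasked, unclassified stripe with the highest vegetation
    fraction is classified as a crop row, then every stripe whose centreline
    lies within ``row_spacing - width/2`` of the new row is masked.  The loop
    stops when the best remaining fraction drops below ``stop_ratio`` times
    the first (strongest) row's fraction, or below ``min_fraction``.

    A completion pass follows: rows recur at the known spacing, so a stripe
    sitting on the row grid of an accepted row (an integer multiple of
    ``row_spacing`` away, within half a stripe width) is accepted as a row
    whenever its fraction exceeds ``min_fraction``.  This rescues rows
    clipped at the field border, whose stripes are diluted below the
    ``stop_ratio`` cut because the stripe extends past the end of the row.
    """
    df = level.stripes
    frac = df["veg_fraction"].to_numpy().copy()
    centre = df["centre_offset_m"].to_numpy()
    state = np.array([UNCLASSIFIED] * len(df), dtype=object)
    mask_radius = level.row_spacing_m - level.stripe_width_m / 2.0

    first_fraction = None
    while True:
        open_ = state == UNCLASSIFIED
        if not open_.any():
            break
        k = int(np.flatnonzero(open_)[np.argmax(frac[open_])])
        best = frac[k]
        if best <= min_fraction:
            break
        if first_fraction is not None and best < stop_ratio * first_fraction:
            break
        if first_fraction is None:
            first_fraction = best
        state[k] = CROP_ROW
        near = (np.abs(centre - centre[k]) < mask_radius) & (state == UNCLASSIFIED)
        state[near] = MASKED

    if first_fraction is None:
        raise NoRowsError("no stripe exceeds the minimal vegetation fraction")

    # completion pass: accept on-grid stripes (see docstring)
    half_w = level.stripe_width_m / 2.0 + 1e-9
    while True:
        rows = centre[state == CROP_ROW]
        cand = np.flatnonzero((state == UNCLASSIFIED) | (state == MASKED))
        cand = cand[frac[cand] > min_fraction]
        on_grid = []
        for k in cand:
            d = np.abs(centre[k] - rows)
            m = d % level.row_spacing_m
            near = np.minimum(m, level.row_spacing_m - m) <= half_w
            if np.any(near & (d >= level.row_spacing_m - half_w)):
                on_grid.append(k)
        if not on_grid:
            break
        k = int(max(on_grid, key=lambda i: frac[i]))
        state[k] = CROP_ROW
        near = (np.abs(centre - centre[k]) < mask_radius) & (state == UNCLASSIFIED)
        state[near] = MASKED

    df["klass"] = state
    return level


def classify_buffer_and_noncrop(level: StripeLevel) -> StripeLevel:
    """Classify remaining stripes as buffer (adjacent to a row) or non-crop.

    Masked stripes are re-eligible here: masking only bars them from becoming
    rows, not from serving as buffer.
    """
    df = level.stripes
    klass = df["klass"].to_numpy(dtype=object)
    is_row = klass == CROP_ROW
    n = len(klass)
    for i in range(n):
        if is_row[i]:
            continue
        if (i > 0 and is_row[i - 1]) or (i + 1 < n and is_row[i + 1]):
            klass[i] = BUFFER
        else:
            klass[i] = NON_CROP
    df["klass"] = klass
    return level


def stripe_class_raster(level: StripeLevel, image: FieldImage,
                        window: tuple[int, int, int, int] | None = None) -> np.ndarray:
    """Per-pixel stripe class codes (0 non_crop, 1 buffer, 2 crop_row)."""
    if window is None:
        window = (0, 0, image.shape[0], image.shape[1])
    proj = _window_pixel_projections(image, window, level.angle_deg)
    idx = _stripe_index(proj, level.origin_offset_m + level.phase_m, level.stripe_width_m)
    idx = np.clip(idx, 0, len(level.stripes) - 1)
    codes = {NON_CROP: 0, MASKED: 0, UNCLASSIFIED: 0, BUFFER: 1, CROP_ROW: 2}
    lut = np.array([codes[k] for k in level.stripes["klass"]], dtype=np.uint8)
    r0, c0, r1, c1 = window
    return lut[idx].reshape(r1 - r0, c1 - c0)
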