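"""Synthetic UAV field scenes with full ground truth.

The generator emulates an early-season row-crop field seen from nadir: crop
plants as disks along parallel rows (0.7 m spacing by default), broadleaved
weed seedlings scattered between the rows by a Thomas-style clustered point
process (weeds are patchy in real fields), a textured bare-soil background,
per-class per-band reflectances drawn from normal distributions, a linear
illumination gradient and per-pixel sensor noise.  Ground truth (per-pixel
class labels, row centrelines, weed components, sampling frames) is recorded
before noise, so every pipeline stage can be scored without real imagery.

The scene is flat and in perfect nadir view; there is no perspective,
terrain, canopy radiative transfer or photorealism.  All randomness flows
from a single integer seed: identical specs and seeds give bit-identical
scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .classify import CROP, NODATA, SOIL, WEED
from .errors import InvalidArgumentError
from .geometry import (
    CameraSpec,
    DOMAIN_DN,
    DOMAIN_REFLECTANCE,
    FieldImage,
    PanelReference,
    RGB_BANDS,
    gsd_at_altitude,
)
from .assess import SampleFrame
from .rows import DEFAULT_ROW_SPACING_M, _normal_projection

PANEL_SIDE_M = 0.45

#: Per-class, per-band reflectance (mean, sd).  Soil follows a bright dry
#: soil line; crop is a healthy seedling (strong green / red-edge / NIR);
#: weed is a slightly lighter-green broadleaf, spectrally close to the crop.
DEFAULT_REFLECTANCE: dict[str, dict[str, tuple[float, float]]] = {
    "soil": {
        "R": (0.30, 0.020), "G": (0.22, 0.020), "B": (0.12, 0.020),
        "B450": (0.10, 0.015), "G530": (0.18, 0.018), "R670": (0.28, 0.020),
        "R700": (0.30, 0.020), "RE740": (0.33, 0.020), "NIR780": (0.35, 0.020),
    },
    "crop": {
        "R": (0.07, 0.012), "G": (0.12, 0.012), "B": (0.05, 0.010),
        "B450": (0.04, 0.008), "G530": (0.10, 0.012), "R670": (0.06, 0.010),
        "R700": (0.12, 0.012), "RE740": (0.30, 0.020), "NIR780": (0.45, 0.025),
    },
    "weed": {
        "R": (0.09, 0.012), "G": (0.15, 0.012), "B": (0.06, 0.010),
        "B450": (0.05, 0.008), "G530": (0.13, 0.012), "R670": (0.08, 0.010),
        "R700": (0.14, 0.012), "RE740": (0.28, 0.020), "NIR780": (0.40, 0.025),
    },
}


@dataclass(frozen=True)
class FieldSpec:
    """Study conditions of a generated field.

    Defaults describe an early-season sunflower stand: 0.7 m rows, plants
    every 0.18 m with canopy radius 8-12 cm (4-6 true leaves), and two weed
    seedlings per square metre clumped into patches between the rows.
    """

    field_size_m: tuple[float, float] = (6.0, 6.0)
    row_angle_deg: float = 0.0
    row_spacing_m: float = DEFAULT_ROW_SPACING_M
    plant_spacing_m: float = 0.18
    plant_radius_m: tuple[float, float] = (0.08, 0.12)
    weed_density_per_m2: float = 2.0
    weed_radius_m: tuple[float, float] = (0.04, 0.08)
    weed_cluster_parent_density: float | None = 0.25  # None -> uniform process
    weed_cluster_sd_m: float = 0.4
    min_row_length_m: float = 0.5
    illumination_gradient: float = 0.08
    noise_sd: float = 0.01
    shadows: bool = False
    n_frames: int = 10
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.field_size_m[0] <= 0 or self.field_size_m[1] <= 0:
            raise InvalidArgumentError("field size must be positive")
        if not 0.0 <= self.row_angle_deg < 180.0:
            raise InvalidArgumentError("row angle must lie in [0, 180)")
        if self.row_spacing_m <= 0 or self.plant_spacing_m <= 0:
            raise InvalidArgumentError("spacings must be positive")
        if self.weed_density_per_m2 < 0:
            raise InvalidArgumentError("weed density must be non-negative")
        for rng in (self.plant_radius_m, self.weed_radius_m):
            if rng[0] <= 0 or rng[1] < rng[0]:
                raise InvalidArgumentError("radius ranges must be positive and ordered")


@dataclass
class SyntheticScene:
    """A generated field image plus everything needed to score the pipeline."""

    image: FieldImage
    truth: np.ndarray  # uint8 class codes (classify module coding)
    row_angle_deg: float
    row_offsets_m: np.ndarray  # signed normal offsets of row centrelines
    n_weed_plants: int
    frames: list[SampleFrame]
    spec: FieldSpec
    altitude_m: float | None = None
    panel: PanelReference | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def gsd_m(self) -> float:
        return self.image.gsd_m


def _rect_projection_range(w_m: float, h_m: float, angle_deg: float) -> tuple[float, float]:
    corners = np.array([[0, 0], [w_m, 0], [0, h_m], [w_m, h_m]], dtype=float)
    p = _normal_projection(corners[:, 0], corners[:, 1], angle_deg)
    return float(p.min()), float(p.max())


def _clip_line_to_rect(point: np.ndarray, direction: np.ndarray, w_m: float, h_m: float):
    """Intersect an infinite line with the field rectangle; None if empty."""
    t_lo, t_hi = -np.inf, np.inf
    for dim, bound in ((0, w_m), (1, h_m)):
        d, p = direction[dim], point[dim]
        if abs(d) < 1e-12:
            if not 0.0 <= p <= bound:
                return None
        else:
            t0, t1 = (0.0 - p) / d, (bound - p) / d
            t_lo = max(t_lo, min(t0, t1))
            t_hi = min(t_hi, max(t0, t1))
    if t_hi <= t_lo:
        return None
    return t_lo, t_hi


def _paint_disks(
    values: np.ndarray,
    truth: np.ndarray,
    centres_xy: np.ndarray,
    radii: np.ndarray,
    base_reflectance: np.ndarray,
    code: int,
    gsd: float,
    h_m: float,
    falloff: float = 0.3,
) -> None:
    """Rasterise reflectance disks with a radial brightness falloff."""
    h, w = truth.shape
    for (cx, cy), r, base in zip(centres_xy, radii, base_reflectance):
        # pixel bounding box of the disk
        c0 = max(int((cx - r) / gsd), 0)
        c1 = min(int((cx + r) / gsd) + 2, w)
        r0 = max(int((h_m - cy - r) / gsd), 0)
        r1 = min(int((h_m - cy + r) / gsd) + 2, h)
        if c1 <= c0 or r1 <= r0:
            continue
        xs = (np.arange(c0, c1) + 0.5) * gsd
        ys = h_m - (np.arange(r0, r1) + 0.5) * gsd
        dx = xs[None, :] - cx
        dy = ys[:, None] - cy
        d2 = dx * dx + dy * dy
        inside = d2 <= r * r
        if not inside.any():
            continue
        f = 1.0 - falloff * (d2[inside] / (r * r))
        values[r0:r1, c0:c1][inside] = base[None, :] * f[:, None]
        truth[r0:r1, c0:c1][inside] = code


def generate_field(
    spec: FieldSpec,
    camera: CameraSpec | None = None,
    altitude_m: float | None = None,
    gsd_m: float | None = None,
    bands: tuple[str, ...] | None = None,
) -> SyntheticScene:
    """Generate a synthetic scene at the resolution implied by the flight.

    Resolution comes either from ``camera`` + ``altitude_m`` (via
    :func:`gsd_at_altitude`) or from an explicit ``gsd_m``.  ``bands``
    defaults to the camera's bands, or RGB.
    """
    if gsd_m is None:
        if camera is None or altitude_m is None:
            raise InvalidArgumentError("provide either camera+altitude or gsd_m")
        gsd_m = gsd_at_altitude(camera, altitude_m) / 100.0
    if bands is None:
        bands = camera.bands if camera is not None else RGB_BANDS
    for cls in ("soil", "crop", "weed"):
        for b in bands:
            if b not in DEFAULT_REFLECTANCE[cls]:
                raise InvalidArgumentError(f"no default reflectance for band {b!r}")

    rng = np.random.default_rng(spec.random_seed)
    w_m, h_m = spec.field_size_m
    w_px = int(round(w_m / gsd_m))
    h_px = int(round(h_m / gsd_m))
    nb = len(bands)

    # --- soil background: spatially correlated texture + fine grain
    truth = np.full((h_px, w_px), SOIL, dtype=np.uint8)
    values = np.empty((h_px, w_px, nb))
    coarse = rng.standard_normal((h_px, w_px))
    sigma_px = max(0.10 / gsd_m, 1.0)  # ~10 cm correlation length
    coarse = ndimage.gaussian_filter(coarse, sigma_px)
    sd = coarse.std()
    coarse = coarse / sd if sd > 0 else coarse
    grain = rng.standard_normal((h_px, w_px))
    for bi, b in enumerate(bands):
        mean, bsd = DEFAULT_REFLECTANCE["soil"][b]
        values[:, :, bi] = mean + bsd * (0.7 * coarse + 0.7 * grain)

    # --- crop rows
    theta = np.deg2rad(spec.row_angle_deg)
    u = np.array([np.cos(theta), np.sin(theta)])  # along-row direction
    n_vec = np.array([-np.sin(theta), np.cos(theta)])  # normal
    p_min, p_max = _rect_projection_range(w_m, h_m, spec.row_angle_deg)
    offsets = []
    candidate = p_min + spec.row_spacing_m / 2.0
    while candidate < p_max:
        offsets.append(candidate)
        candidate += spec.row_spacing_m

    row_offsets = []
    plant_centres, plant_radii = [], []
    for off in offsets:
        anchor = n_vec * off
        seg = _clip_line_to_rect(anchor, u, w_m, h_m)
        if seg is None or (seg[1] - seg[0]) < spec.min_row_length_m:
            continue
        row_offsets.append(off)
        t = seg[0] + spec.plant_spacing_m / 2.0
        while t < seg[1]:
            plant_centres.append(anchor + t * u)
            t += spec.plant_spacing_m
    plant_centres = np.array(plant_centres).reshape(-1, 2)
    plant_radii = rng.uniform(*spec.plant_radius_m, size=len(plant_centres))
    row_offsets = np.array(row_offsets, dtype=float)

    # --- weeds: clustered (Thomas) or uniform point process between rows
    area = w_m * h_m
    if spec.weed_density_per_m2 > 0:
        if spec.weed_cluster_parent_density:
            n_parents = rng.poisson(spec.weed_cluster_parent_density * area)
            parents = rng.uniform([0, 0], [w_m, h_m], size=(n_parents, 2))
            mean_offspring = spec.weed_density_per_m2 / spec.weed_cluster_parent_density
            pts = []
            for p in parents:
                k = rng.poisson(mean_offspring)
                pts.append(p[None, :] + rng.normal(0.0, spec.weed_cluster_sd_m, size=(k, 2)))
            weed_pts = np.concatenate(pts) if pts else np.empty((0, 2))
        else:
            n_weeds = rng.poisson(spec.weed_density_per_m2 * area)
            weed_pts = rng.uniform([0, 0], [w_m, h_m], size=(n_weeds, 2))
        weed_radii = rng.uniform(*spec.weed_radius_m, size=len(weed_pts))
        # keep weeds inside the field and strictly between rows: a weed disk
        # must not touch any plant disk on a row centreline
        inside = np.all((weed_pts >= 0) & (weed_pts <= [w_m, h_m]), axis=1)
        proj = _normal_projection(weed_pts[:, 0], weed_pts[:, 1], spec.row_angle_deg)
        if row_offsets.size:
            d_row = np.min(np.abs(proj[:, None] - row_offsets[None, :]), axis=1)
        else:
            d_row = np.full(len(weed_pts), np.inf)
        clear = d_row >= (weed_radii + spec.plant_radius_m[1] + 0.01)
        keep = inside & clear
        weed_pts, weed_radii = weed_pts[keep], weed_radii[keep]
    else:
        weed_pts = np.empty((0, 2))
        weed_radii = np.empty(0)

    # --- paint (weeds below crop; they never overlap by construction)
    def class_bases(cls: str, count: int) -> np.ndarray:
        means = np.array([DEFAULT_REFLECTANCE[cls][b][0] for b in bands])
        sds = np.array([DEFAULT_REFLECTANCE[cls][b][1] for b in bands])
        return means[None, :] + sds[None, :] * rng.standard_normal((count, nb))

    weed_bases = class_bases("weed", len(weed_pts))
    _paint_disks(values, truth, weed_pts, weed_radii, weed_bases, WEED, gsd_m, h_m)
    crop_bases = class_bases("crop", len(plant_centres))
    _paint_disks(values, truth, plant_centres, plant_radii, crop_bases, CROP, gsd_m, h_m)

    if spec.shadows:
        # crude cast shadows: darken soil north-west of each plant
        shadow = np.zeros_like(truth, dtype=bool)
        shift_px = max(int(0.06 / gsd_m), 1)
        plant_mask = truth == CROP
        shadow[shift_px:, :-shift_px] = plant_mask[:-shift_px, shift_px:]
        shadow &= truth == SOIL
        values[shadow] *= 0.6

    n_weed_plants = int(ndimage.label(truth == WEED, structure=np.ones((3, 3)))[1])

    # --- illumination gradient and sensor noise (truth already recorded)
    if spec.illumination_gradient:
        x = (np.arange(w_px) + 0.5) / w_px
        y = (np.arange(h_px) + 0.5) / h_px
        ramp = 1.0 + spec.illumination_gradient * ((x[None, :] + y[:, None]) - 1.0)
        values *= ramp[:, :, None]
    if spec.noise_sd:
        values += rng.normal(0.0, spec.noise_sd, size=values.shape)
    np.clip(values, 0.0, 1.2, out=values)

    image = FieldImage(
        values=values, bands=tuple(bands), gsd_m=gsd_m,
        origin=(0.0, h_m), domain=DOMAIN_REFLECTANCE,
    )

    # --- ground-truth sampling frames (non-overlapping 1 x 1 m squares)
    frames: list[SampleFrame] = []
    placed: list[tuple[float, float]] = []
    tries = 0
    while len(frames) < spec.n_frames and tries < 2000:
        tries += 1
        if w_m <= 1.0 or h_m <= 1.0:
            break
        x0 = rng.uniform(0.0, w_m - 1.0)
        y0 = rng.uniform(0.0, h_m - 1.0)
        if any(abs(x0 - px) < 1.0 and abs(y0 - py) < 1.0 for px, py in placed):
            continue
        frames.append(
            SampleFrame.from_world_square(truth, image, x0, y0, frame_id=len(frames))
        )
        placed.append((x0, y0))

    return SyntheticScene(
        image=image,
        truth=truth,
        row_angle_deg=spec.row_angle_deg,
        row_offsets_m=row_offsets,
        n_weed_plants=n_weed_plants,
        frames=frames,
        spec=spec,
        altitude_m=altitude_m,
        metadata={
            "generator": "rowweed.synth",
            "version": 1,
            "seed": spec.random_seed,
            "n_crop_plants": int(len(plant_centres)),
        },
    )


def score_row_detection(
    scene: SyntheticScene, level, tolerance_m: float = 0.35
) -> dict:
    """Score detected crop rows against the generator's centrelines.

    Detected rows are the crop-row stripe centrelines of ``level``; each is
    compared to the nearest true centreline, with the distance between the
    two lines evaluated at the point of the detected line closest to the
    field centre (the two orientations may differ by the angle-scan step).

    Returns a dict with ``n_true``, ``n_detected``, ``max_distance_m``
    (inf when counts differ and a detected row has no true partner) and
    ``passed`` (counts equal and every detected row within ``tolerance_m``).
    """
    w_m, h_m = scene.spec.field_size_m
    centre = np.array([w_m / 2.0, h_m / 2.0])
    a_d = np.deg2rad(level.angle_deg)
    n_d = np.array([-np.sin(a_d), np.cos(a_d)])
    a_t = np.deg2rad(scene.row_angle_deg)
    n_t = np.array([-np.sin(a_t), np.cos(a_t)])

    detected = np.asarray(level.crop_row_offsets(), dtype=float)
    true = np.asarray(scene.row_offsets_m, dtype=float)
    dists = []
    for c in detected:
        x = centre + (c - n_d @ centre) * n_d  # detected line point nearest centre
        if true.size:
            dists.append(float(np.min(np.abs(n_t @ x - true))))
        else:
            dists.append(np.inf)
    max_d = max(dists) if dists else (0.0 if true.size == 0 else np.inf)
    passed = len(detected) == len(true) and max_d <= tolerance_m
    return {
        "n_true": int(true.size),
        "n_detected": int(len(detected)),
        "max_distance_m": float(max_d),
        "passed": bool(passed),
    }


# ---------------------------------------------------------------------------
# Resolution degradation
# ---------------------------------------------------------------------------


def _area_weights(n_in: int, n_out: int, ratio: float) -> np.ndarray:
    """(n_out, n_in) matrix of fractional overlaps of output with input pixels."""
    wts = np.zeros((n_out, n_in))
    for i in range(n_out):
        lo, hi = i * ratio, (i + 1) * ratio
        j0, j1 = int(np.floor(lo)), min(int(np.ceil(hi)), n_in)
        for j in range(j0, j1):
            wts[i, j] = max(0.0, min(hi, j + 1) - max(lo, j))
    return wts / ratio


def degrade_to_gsd(scene: SyntheticScene, target_gsd_m: float) -> SyntheticScene:
    """Resample the scene to a coarser GSD by area-weighted averaging.

    Integer ratios reduce to exact block averaging (band means preserved).
    Ground truth is re-rasterised by majority label (ties resolve in class
    code order); frames are re-snapped to the new grid.
    """
    ratio = target_gsd_m / scene.gsd_m
    if ratio <= 1.0 + 1e-12:
        raise InvalidArgumentError("target GSD must be coarser than the source")
    h, w = scene.truth.shape
    h2, w2 = int(np.floor(h / ratio + 1e-9)), int(np.floor(w / ratio + 1e-9))

    img = scene.image.values
    if abs(ratio - round(ratio)) < 1e-9:
        f = int(round(ratio))
        img2 = img[: h2 * f, : w2 * f].reshape(h2, f, w2, f, -1).mean(axis=(1, 3))
        one_hot = [
            (scene.truth[: h2 * f, : w2 * f] == code)
            .reshape(h2, f, w2, f)
            .sum(axis=(1, 3))
            for code in (SOIL, CROP, WEED, NODATA)
        ]
    else:
        wr = _area_weights(h, h2, ratio)
        wc = _area_weights(w, w2, ratio)
        img2 = np.stack(
            [wr @ img[:, :, b] @ wc.T for b in range(img.shape[2])], axis=-1
        )
        one_hot = [
            wr @ (scene.truth == code).astype(float) @ wc.T
            for code in (SOIL, CROP, WEED, NODATA)
        ]
    codes = np.array([SOIL, CROP, WEED, NODATA], dtype=np.uint8)
    truth2 = codes[np.argmax(np.stack(one_hot), axis=0)]

    image2 = FieldImage(
        values=img2, bands=scene.image.bands, gsd_m=target_gsd_m,
        origin=scene.image.origin, domain=scene.image.domain,
    )
    frames2 = []
    for fr in scene.frames:
        r0, c0, _, _ = fr.window
        x0 = scene.image.origin[0] + c0 * scene.gsd_m
        y1 = scene.image.origin[1] - r0 * scene.gsd_m
        y0 = y1 - fr.side_m
        try:
            frames2.append(
                SampleFrame.from_world_square(
                    truth2, image2, x0, y0, side_m=fr.side_m, frame_id=fr.frame_id
                )
            )
        except Exception:
            continue  # frame fell off the (slightly cropped) coarse raster
    return replace(
        scene,
        image=image2,
        truth=truth2,
        frames=frames2,
        metadata={**scene.metadata, "degraded_from_gsd_m": scene.gsd_m},
    )


def degrade_to_altitude(scene: SyntheticScene, target_altitude_m: float) -> SyntheticScene:
    """Degrade to the GSD of a higher flight (requires a known source altitude)."""
    if scene.altitude_m is None:
        raise InvalidArgumentError("scene has no source altitude; use degrade_to_gsd")
    if target_altitude_m <= scene.altitude_m:
        raise InvalidArgumentError("target altitude must exceed the source altitude")
    target_gsd = scene.gsd_m * target_altitude_m / scene.altitude_m
    out = degrade_to_gsd(scene, target_gsd)
    out.altitude_m = target_altitude_m
    return out


# ---------------------------------------------------------------------------
# Calibration panel
# ---------------------------------------------------------------------------


def embed_calibration_panel(
    scene: SyntheticScene,
    reflectance_per_band: float | tuple[float, ...] = 0.99,
    noise_sd: float | None = None,
) -> SyntheticScene:
    """Place a reflectance panel on bare soil near the field centre.

    The panel (0.45 m side) overwrites image values with its reflectance
    (plus sensor noise) and its footprint becomes nodata in the ground truth
    so it never enters the assessment.  Returns a new scene whose ``panel``
    holds the :class:`~rowweed.geometry.PanelReference`.
    """
    nb = scene.image.n_bands
    rho = (
        tuple(float(reflectance_per_band) for _ in range(nb))
        if np.isscalar(reflectance_per_band)
        else tuple(reflectance_per_band)
    )
    side = int(round(PANEL_SIDE_M / scene.gsd_m))
    h, w = scene.truth.shape
    if side < 1 or side > min(h, w):
        raise InvalidArgumentError("panel does not fit in the image")

    # candidate top-left corners ordered by distance from the field centre
    step = max(side // 4, 1)
    r_cand = np.arange(0, h - side + 1, step)
    c_cand = np.arange(0, w - side + 1, step)
    rr, cc = np.meshgrid(r_cand, c_cand, indexing="ij")
    order = np.argsort((rr - h / 2) ** 2 + (cc - w / 2) ** 2, axis=None)
    soil = scene.truth == SOIL
    csum = np.cumsum(np.cumsum(soil.astype(np.int64), axis=0), axis=1)
    pad = np.zeros((h + 1, w + 1), dtype=np.int64)
    pad[1:, 1:] = csum

    region = None
    for k in order:
        r0, c0 = int(rr.ravel()[k]), int(cc.ravel()[k])
        r1, c1 = r0 + side, c0 + side
        count = pad[r1, c1] - pad[r0, c1] - pad[r1, c0] + pad[r0, c0]
        if count == side * side:
            region = (r0, c0, r1, c1)
            break
    if region is None:
        raise InvalidArgumentError("no bare-soil area large enough for the panel")

    rng = np.random.default_rng(scene.spec.random_seed + 7919)
    sd = scene.spec.noise_sd if noise_sd is None else noise_sd
    values = scene.image.values.copy()
    truth = scene.truth.copy()
    r0, c0, r1, c1 = region
    patch = np.broadcast_to(np.asarray(rho), (r1 - r0, c1 - c0, nb)).copy()
    if sd:
        patch = patch + rng.normal(0.0, sd, size=patch.shape)
    values[r0:r1, c0:c1] = np.clip(patch, 0.0, 1.2)
    truth[r0:r1, c0:c1] = NODATA

    panel = PanelReference(region=region, reflectance_per_band=rho)
    image = replace(scene.image, values=values)
    return replace(scene, image=image, truth=truth, panel=panel)


def to_digital_numbers(
    image: FieldImage, gain_per_band: float | tuple[float, ...] = 1.0 / 255.0
) -> FieldImage:
    """Simulate a linear sensor: ``DN = reflectance / gain`` (no quantisation).

    The inverse of a gain-only empirical line; calibrating the result against
    an embedded panel recovers the generating reflectances exactly.
    """
    if image.domain != DOMAIN_REFLECTANCE:
        raise InvalidArgumentError("expected a reflectance image")
    gains = (
        np.full(image.n_bands, float(gain_per_band))
        if np.isscalar(gain_per_band)
        else np.asarray(gain_per_band, dtype=np.float64)
    )
    if np.any(gains <= 0):
        raise InvalidArgumentError("gains must be positive")
    return replace(image, values=image.values / gains[None, None, :], domain=DOMAIN_DN)
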