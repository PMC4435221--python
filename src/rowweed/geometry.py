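"""Flight geometry and radiometric calibration.

A camera flown at altitude *h* images the ground with a ground sampling
distance (GSD) proportional to *h*; the footprint of a single image therefore
grows quadratically with altitude.  This module provides the camera model, the
georeferenced multi-band image container used throughout the pipeline, and the
empirical-line method that converts raw digital numbers (DN) to surface
reflectance using a reference panel of known reflectance placed in the field.

Conventions
-----------
World coordinates are metric, x east and y north, with the image ``origin``
at the *top-left pixel corner*.  Pixel ``(row, col)`` is 0-based; a pixel
covers ``gsd_m x gsd_m`` metres and its centre sits at
``(origin_x + (col + 0.5) * gsd_m, origin_y - (row + 0.5) * gsd_m)``.
Missing data is carried as NaN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import BoundsError, CalibrationError, ConfigurationError, InvalidArgumentError

#: Upper clip applied to reflectance values; tolerates panel over-brightness.
REFLECTANCE_CEILING = 1.2

RGB_BANDS = ("R", "G", "B")
MULTISPEC_BANDS = ("B450", "G530", "R670", "R700", "RE740", "NIR780")

#: Band label -> centre wavelength (nm).
BAND_WAVELENGTHS_NM = {
    "B": 470.0,
    "G": 550.0,
    "R": 640.0,
    "B450": 450.0,
    "G530": 530.0,
    "R670": 670.0,
    "R700": 700.0,
    "RE740": 740.0,
    "NIR780": 780.0,
}


@dataclass(frozen=True)
class CameraSpec:
    """Sensor geometry anchored at a reference altitude.

    Parameters
    ----------
    name : str
        Human-readable sensor name.
    pixels_across, pixels_down : int
        Sensor resolution (columns, rows); both >= 1.
    reference_altitude_m : float
        Altitude at which ``reference_gsd_cm`` was measured.
    reference_gsd_cm : float
        Ground sampling distance (cm/pixel) at the reference altitude.
    bands : tuple of str
        Ordered, unique band labels (see :data:`BAND_WAVELENGTHS_NM`).
    """

    name: str
    pixels_across: int
    pixels_down: int
    reference_altitude_m: float
    reference_gsd_cm: float
    bands: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pixels_across < 1 or self.pixels_down < 1:
            raise InvalidArgumentError("pixel counts must be >= 1")
        if self.reference_gsd_cm <= 0 or self.reference_altitude_m <= 0:
            raise InvalidArgumentError("reference GSD and altitude must be positive")
        if len(set(self.bands)) != len(self.bands):
            raise InvalidArgumentError("band labels must be unique")

    @staticmethod
    def from_json(path: str | Path) -> "CameraSpec":
        with open(path) as fh:
            d = json.load(fh)
        return CameraSpec(
            name=d["name"],
            pixels_across=int(d["pixels_across"]),
            pixels_down=int(d["pixels_down"]),
            reference_altitude_m=float(d["reference_altitude_m"]),
            reference_gsd_cm=float(d["reference_gsd_cm"]),
            bands=tuple(d["bands"]),
        )


#: 12-megapixel true-colour camera: 1.52 cm/pixel at 40 m.
VISIBLE_CAMERA = CameraSpec(
    name="visible-light",
    pixels_across=4032,
    pixels_down=3024,
    reference_altitude_m=40.0,
    reference_gsd_cm=1.52,
    bands=RGB_BANDS,
)

#: 1.3-megapixel six-channel multispectral camera: 2.16 cm/pixel at 40 m.
MULTISPECTRAL_CAMERA = CameraSpec(
    name="multispectral",
    pixels_across=1280,
    pixels_down=1024,
    reference_altitude_m=40.0,
    reference_gsd_cm=2.16,
    bands=MULTISPEC_BANDS,
)


def gsd_at_altitude(camera: CameraSpec, altitude_m: float) -> float:
    """Ground sampling distance (cm/pixel) at ``altitude_m``.

    GSD scales linearly with altitude for a fixed sensor/lens:
    ``gsd(h) = gsd_ref * h / h_ref``.
    """
    if altitude_m <= 0:
        raise InvalidArgumentError(f"altitude must be positive, got {altitude_m}")
    return camera.reference_gsd_cm * altitude_m / camera.reference_altitude_m


def covered_area_ha(camera: CameraSpec, altitude_m: float) -> float:
    """Ground area (hectares) covered by a single image at ``altitude_m``.

    Equals ``pixels_across * pixels_down * gsd^2`` and hence grows with the
    square of the altitude.
    """
    gsd_m = gsd_at_altitude(camera, altitude_m) / 100.0
    area_m2 = camera.pixels_across * camera.pixels_down * gsd_m * gsd_m
    return area_m2 / 10_000.0


# ---------------------------------------------------------------------------
# Image container
# ---------------------------------------------------------------------------

DOMAIN_DN = "digital_number"
DOMAIN_REFLECTANCE = "reflectance"


@dataclass
class FieldImage:
    """A georeferenced multi-band raster with square pixels.

    ``values`` is ``(rows, cols, bands)`` float64; NaN marks nodata.
    """

    values: np.ndarray
    bands: tuple[str, ...]
    gsd_m: float
    origin: tuple[float, float] = (0.0, 0.0)
    domain: str = DOMAIN_REFLECTANCE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        if self.values.ndim != 3 or self.values.shape[2] != len(self.bands):
            raise InvalidArgumentError(
                f"values shape {self.values.shape} does not match {len(self.bands)} bands"
            )
        if self.gsd_m <= 0:
            raise InvalidArgumentError("gsd_m must be positive")
        if self.domain not in (DOMAIN_DN, DOMAIN_REFLECTANCE):
            raise InvalidArgumentError(f"unknown radiometric domain {self.domain!r}")
        self.bands = tuple(self.bands)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]  # type: ignore[return-value]

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def band(self, label: str) -> np.ndarray:
        """Return one band as a 2-D view."""
        try:
            i = self.bands.index(label)
        except ValueError:
            raise ConfigurationError(f"image has no band {label!r}; bands: {self.bands}")
        return self.values[:, :, i]

    def has_band(self, label: str) -> bool:
        return label in self.bands

    def valid_mask(self) -> np.ndarray:
        """True where all bands are finite."""
        return np.all(np.isfinite(self.values), axis=2)

    def pixel_centres_world(self) -> tuple[np.ndarray, np.ndarray]:
        """World (x, y) coordinates of every pixel centre, as 2-D arrays."""
        h, w = self.shape
        cols = np.arange(w) + 0.5
        rows = np.arange(h) + 0.5
        x = self.origin[0] + cols[None, :] * self.gsd_m + np.zeros((h, 1))
        y = self.origin[1] - rows[:, None] * self.gsd_m + np.zeros((1, w))
        return x, y

    # -- I/O ----------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a TIFF (bands as last axis) plus a ``.json`` geo sidecar."""
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.values.astype(np.float32), photometric="minisblack")
        meta = {
            "bands": list(self.bands),
            "gsd_m": self.gsd_m,
            "origin": list(self.origin),
            "domain": self.domain,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @staticmethod
    def load(path: str | Path, gsd_cm: float | None = None) -> "FieldImage":
        """Read a TIFF written by :meth:`save`; ``gsd_cm`` overrides the sidecar."""
        import tifffile

        path = Path(path)
        values = np.asarray(tifffile.imread(path), dtype=np.float64)
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        else:
            meta = {}
        n_meta_bands = len(meta.get("bands", [])) or None
        if (
            values.ndim == 3
            and n_meta_bands
            and values.shape[-1] != n_meta_bands
            and values.shape[0] == n_meta_bands
        ):
            values = np.moveaxis(values, 0, -1)  # channel-first writer layout
        n_bands = 1 if values.ndim == 2 else values.shape[-1]
        bands = tuple(meta.get("bands", [f"band{i}" for i in range(n_bands)]))
        gsd_m = gsd_cm / 100.0 if gsd_cm is not None else float(meta.get("gsd_m", 0.01))
        return FieldImage(
            values=values,
            bands=bands,
            gsd_m=gsd_m,
            origin=tuple(meta.get("origin", (0.0, 0.0))),
            domain=meta.get("domain", DOMAIN_REFLECTANCE),
        )


# ---------------------------------------------------------------------------
# Empirical-line calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelReference:
    """Reference panel(s) for empirical-line calibration.

    ``region`` is a half-open pixel rectangle ``(row0, col0, row1, col1)``
    covering the bright panel interior.  A second, dark reference may be
    supplied; with a single panel the fitted line is forced through the
    origin (one calibration point determines one coefficient).
    """

    region: tuple[int, int, int, int]
    reflectance_per_band: tuple[float, ...]
    dark_region: tuple[int, int, int, int] | None = None
    dark_reflectance_per_band: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.region
        if r1 <= r0 or c1 <= c0:
            raise InvalidArgumentError("panel region is empty")
        for rho in self.reflectance_per_band:
            if not 0.0 <= rho <= 1.0:
                raise InvalidArgumentError("panel reflectance must be within [0, 1]")
        if (self.dark_region is None) != (self.dark_reflectance_per_band is None):
            raise InvalidArgumentError("dark region and dark reflectances go together")


def _region_band_means(image: FieldImage, region: tuple[int, int, int, int]) -> np.ndarray:
    r0, c0, r1, c1 = region
    h, w = image.shape
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise BoundsError(f"panel region {region} outside image of shape {(h, w)}")
    patch = image.values[r0:r1, c0:c1, :]
    if patch.size == 0:
        raise CalibrationError("panel region is empty")
    with np.errstate(invalid="ignore"):
        means = np.nanmean(patch.reshape(-1, image.n_bands), axis=0)
    if not np.all(np.isfinite(means)):
        raise CalibrationError("panel region is entirely nodata in at least one band")
    return means


def empirical_line_calibrate(image: FieldImage, panel: PanelReference) -> FieldImage:
    """Convert a DN image to reflectance with the empirical-line method.

    Per band, a line ``reflectance = gain * DN + offset`` is fitted through
    the mean DN over the panel region (offset fixed at 0 unless a dark
    reference provides a second point) and applied to every pixel.  Output is
    clipped to ``[0, 1.2]``.
    """
    if image.domain != DOMAIN_DN:
        raise CalibrationError("empirical-line calibration expects a digital-number image")
    if len(panel.reflectance_per_band) != image.n_bands:
        raise ConfigurationError("panel reflectances do not match image bands")

    bright_dn = _region_band_means(image, panel.region)
    bright_rho = np.asarray(panel.reflectance_per_band, dtype=np.float64)

    if panel.dark_region is not None:
        dark_dn = _region_band_means(image, panel.dark_region)
        dark_rho = np.asarray(panel.dark_reflectance_per_band, dtype=np.float64)
        denom = bright_dn - dark_dn
        if np.any(denom == 0):
            raise CalibrationError("bright and dark panels have identical mean DN")
        gain = (bright_rho - dark_rho) / denom
        offset = dark_rho - gain * dark_dn
    else:
        if np.any(bright_dn == 0):
            raise CalibrationError("panel mean DN is zero in at least one band")
        gain = bright_rho / bright_dn
        offset = np.zeros_like(gain)

    calibrated = image.values * gain[None, None, :] + offset[None, None, :]
    calibrated = np.clip(calibrated, 0.0, REFLECTANCE_CEILING)
    calibrated[~np.isfinite(image.values)] = np.nan
    return replace(image, values=calibrated, domain=DOMAIN_REFLECTANCE)
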