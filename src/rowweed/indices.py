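"""Vegetation indices and automatic threshold selection.

Green vegetation is separated from the bare-soil background with one of two
spectral indices:

* **ExG** (Excess Green), ``2g - r - b`` on the chromatic coordinates
  ``r = R/(R+G+B)`` etc., for true-colour imagery.  Because the chromatic
  coordinates normalise out overall brightness, ExG is invariant to uniform
  intensity scaling (e.g. an illumination gradient).
* **NDVI**, ``(NIR - R) / (NIR + R)``, for imagery with a near-infrared band.

The vegetation/soil breakpoint on the index histogram is found automatically
with Otsu's method: the threshold that maximises the between-class variance
(equivalently, minimises the pooled within-class variance) over the histogram
bin boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DegenerateInputError
from .geometry import FieldImage

EXG = "ExG"
NDVI = "NDVI"

#: Default band triplets used by :func:`compute_exg` depending on the sensor.
_EXG_BAND_SETS = (("R", "G", "B"), ("R670", "G530", "B450"))


@dataclass
class IndexRaster:
    """A single-band raster of vegetation-index values (NaN = nodata)."""

    values: np.ndarray
    index_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ConfigurationError("index raster must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ThresholdResult:
    """Otsu threshold together with the histogram that produced it."""

    threshold: float
    bin_edges: np.ndarray
    counts: np.ndarray
    between_class_variance: float


def chromatic_coordinates(
    R: np.ndarray | float, G: np.ndarray | float, B: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalised chromatic coordinates ``(r, g, b)``; black pixels -> NaN."""
    R = np.asarray(R, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    total = R + G + B
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(total > 0, R / total, np.nan)
        g = np.where(total > 0, G / total, np.nan)
        b = np.where(total > 0, B / total, np.nan)
    return r, g, b


def compute_exg(image: FieldImage, bands: tuple[str, str, str] | None = None) -> IndexRaster:
    """Excess Green index ``2g - r - b`` (range [-1, 2]).

    ``bands`` names the (red, green, blue) channels; by default the RGB
    triplet is used when present, falling back to the multispectral
    R670/G530/B450 channels.
    """
    if bands is None:
        for cand in _EXG_BAND_SETS:
            if all(image.has_band(lbl) for lbl in cand):
                bands = cand  # type: ignore[assignment]
                break
        else:
            raise ConfigurationError(f"no RGB-like band triplet among {image.bands}")
    r, g, b = chromatic_coordinates(image.band(bands[0]), image.band(bands[1]), image.band(bands[2]))
    return IndexRaster(values=2.0 * g - r - b, index_name=EXG)


def compute_ndvi(image: FieldImage, red_band: str = "R670", nir_band: str = "NIR780") -> IndexRaster:
    """NDVI ``(NIR - R)/(NIR + R)`` (range [-1, 1]); ``NIR + R == 0`` -> NaN.

    The multispectral sensor carries two red channels (670 and 700 nm); the
    670 nm channel is the default.
    """
    nir = image.band(nir_band)
    red = image.band(red_band)
    total = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(total != 0, (nir - red) / total, np.nan)
    return IndexRaster(values=values, index_name=NDVI)


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> ThresholdResult:
    """Otsu's threshold over histogram bin boundaries spanning [min, max].

    The between-class variance ``w0*w1*(mu0 - mu1)^2`` is evaluated at every
    interior bin boundary, with the class means accumulated from the actual
    values in each bin (not bin centres).  If the maximum is attained on a
    plateau of boundaries, the plateau midpoint is returned.

    Raises
    ------
    DegenerateInputError
        If fewer than two distinct finite values are supplied.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    values = values[np.isfinite(values)]
    if values.size < 2 or np.min(values) == np.max(values):
        raise DegenerateInputError("Otsu needs at least two distinct finite values")

    lo, hi = float(np.min(values)), float(np.max(values))
    edges = np.linspace(lo, hi, n_bins + 1)
    # per-bin counts and value sums (right-closed last bin, as np.histogram)
    idx = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(np.float64)
    sums = np.bincount(idx, weights=values, minlength=n_bins)

    n = values.size
    total_sum = float(np.sum(values))
    csum_n = np.cumsum(counts)  # class-0 size for boundary k = csum_n[k-1]
    csum_s = np.cumsum(sums)

    # candidate boundaries: edges[1..n_bins-1]; classes {x < t} vs {x >= t}
    n0 = csum_n[:-1]
    s0 = csum_s[:-1]
    n1 = n - n0
    s1 = total_sum - s0
    valid = (n0 > 0) & (n1 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = s0 / n0
        mu1 = s1 / n1
        sigma_b = (n0 / n) * (n1 / n) * (mu0 - mu1) ** 2
    sigma_b = np.where(valid, sigma_b, -np.inf)

    best = float(np.max(sigma_b))
    # plateau: all boundaries whose variance ties the maximum (exact fp tie)
    plateau = np.flatnonzero(sigma_b == best)
    boundary_values = edges[1:-1]
    threshold = float(np.mean(boundary_values[plateau[[0, -1]]]))
    return ThresholdResult(
        threshold=threshold,
        bin_edges=edges,
        counts=counts.astype(np.int64),
        between_class_variance=best,
    )


def object_mean_index(index: IndexRaster, labels: np.ndarray, n_objects: int) -> np.ndarray:
    """Mean index value per object (NaN pixels ignored; all-NaN object -> NaN)."""
    if labels.shape != index.shape:
        raise ConfigurationError("label raster and index raster are not congruent")
    flat_lab = labels.ravel()
    flat_val = index.values.ravel()
    ok = (flat_lab >= 0) & np.isfinite(flat_val)
    counts = np.bincount(flat_lab[ok], minlength=n_objects)
    sums = np.bincount(flat_lab[ok], weights=flat_val[ok], minlength=n_objects)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means


def classify_vegetation_objects(
    object_means: np.ndarray, threshold: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Label objects vegetation (True) iff mean index strictly exceeds threshold.

    ``threshold`` may be a scalar or a per-object array (sub-plot-wise Otsu).
    Objects whose mean is NaN (all index pixels nodata) are labelled bare soil
    and flagged.

    Returns
    -------
    (vegetation, flagged) : pair of boolean arrays, one entry per object.
    """
    object_means = np.asarray(object_means, dtype=np.float64)
    thr = np.broadcast_to(np.asarray(threshold, dtype=np.float64), object_means.shape)
    flagged = ~np.isfinite(object_means)
    with np.errstate(invalid="ignore"):
        vegetation = np.where(flagged, False, object_means > thr)
    return vegetation.astype(bool), flagged
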