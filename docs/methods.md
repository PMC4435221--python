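# Methods

This note documents the models, parameter choices and numerical conventions
behind `rowweed`, and what the synthetic benchmark does and does not show
about real imagery.

## Flight geometry and radiometry

A fixed sensor/lens images the ground with GSD proportional to flight
altitude, `gsd(h) = gsd_ref · h / h_ref`, and a footprint growing with `h²`.
The bundled camera models are a 12-megapixel RGB camera (4032 × 3024 px,
1.52 cm/px at 40 m) and a 1.3-megapixel six-band multispectral camera
(1280 × 1024 px, 2.16 cm/px at 40 m, bands at 450/530/670/700/740/780 nm).
Pixel counts follow the sensors' megapixel classes; with these values the
RGB footprint is a constant ≈ 4.6 × the multispectral footprint at any
altitude.

Empirical-line calibration fits `reflectance = gain · DN` per band through
the mean digital number over a reference-panel region. A single panel
determines a single coefficient, so the offset is zero unless a dark
reference supplies a second point. Panel statistics ignore nodata pixels;
output reflectances are clipped to [0, 1.2] to tolerate panel
over-brightness. Not modelled: lens distortion, vignetting, BRDF,
atmospheric effects, band-to-band parallax of multi-lens cameras.

World coordinates are metric, x east / y north, origin at the top-left pixel
corner; pixels are square with area `gsd²`; nodata is NaN throughout.

## Vegetation indices and thresholding

ExG is computed on chromatic coordinates (`r = R/(R+G+B)` …), which makes it
exactly invariant to uniform intensity scaling — in particular to the
multiplicative illumination gradient of the generator. For six-band imagery
ExG falls back to the 670/530/450 nm channels; NDVI uses the 670 nm red
channel by default (the 700 nm channel is selectable) because the 670 nm
band sits deeper in the chlorophyll absorption feature.

Otsu's threshold is computed over 256 equal-width bins spanning the observed
[min, max]. The between-class variance is evaluated at every interior bin
boundary using per-bin *value sums* (not bin centres), which makes the
criterion exactly the complement of the pooled within-class variance of the
raw values; a plateau of optimal boundaries returns its midpoint.
Thresholding runs per 5 × 5 m sub-plot by default (a field is spectrally
non-stationary); a global mode exists. An object is vegetation iff its mean
index strictly exceeds the threshold. Constant sub-plots raise a
degenerate-input error (treated as all-soil by the driver).

## Multiresolution segmentation

Segmentation is bottom-up region merging under a heterogeneity budget. The
merge cost combines a colour term (growth in `n · σ`, per band, population
σ) and a shape term (growth in `n · compactness` and `n · smoothness`, with
compactness `l/√n` and smoothness `l/b`). A merge is admissible while the
cost stays below `scale²`. Defaults (10, 0.9, 0.1, 0.5, 0.5 for scale,
colour, shape, smoothness, compactness) assume an 8-bit dynamic range;
the pipeline driver therefore multiplies reflectance-domain values by 255
before segmenting. Band weights default to 1.

The merge order is *synchronous mutual best fitting*: each object points at
its admissible minimum-cost neighbour (cost ties break towards the neighbour
containing the smallest row-major pixel index), and pairs that point at each
other merge simultaneously; rounds repeat to a fixed point. This rule is
deterministic, order-independent, and cheap to vectorise over the region
adjacency graph (per-object aggregates — pixel count, per-band sum and sum
of squares, perimeter in exposed pixel edges, bounding box, shared-border
lengths — combine exactly under merging). The commercial algorithm that
popularised this criterion does not publish its exact merge order; mutual
best fitting is this package's documented stand-in, and object boundaries
may differ from other implementations at the margin. Objects are
4-connected and never straddle sub-plot borders.

## Crop-row structure

Row orientation is estimated once per image: for each candidate angle
(0–180°, 1° steps) the window is cut into stripes along that angle and
scored by the **area-weighted variance of per-stripe vegetation fraction**.
Aligned stripes alternate vegetation-rich and vegetation-poor, maximising
the variance; across rows the fractions blur towards the mean. The spec of
the underlying idea — rows show "a higher percentage of vegetation" at the
right angle — admits several scores; variance is the default and a
max-fraction mode is trivially derived from the same stripe table.

Stripe geometry: a stripe's *vegetation area* is the pixel area of
vegetation objects whose centroid falls inside it (objects outside the
window contribute nothing), while its *total area* is its geometric pixel
count in the window; the fraction is clipped to [0, 1] (a plant chain wider
than a stripe can concentrate more vegetation into a stripe than the
stripe's own area). Objects exactly on a stripe boundary go to the
lower-index side.

Two parameters the stripe mesh needs but the underlying description leaves
open:

* **Stripe width** defaults to a quarter of the row spacing (0.175 m at
  0.7 m spacing). At half the spacing, every stripe would touch a crop-row
  stripe, the buffer class would swallow the whole inter-row lane and the
  positional weed class would be empty by construction; a quarter keeps at
  least one non-contact stripe per lane.
* **Mesh phase.** The offset of the mesh along the normal is chosen from 8
  candidates in [0, width) to maximise the same variance score. Without
  this, a row falling on a stripe boundary splits its vegetation between two
  stripes and can defeat the greedy selection.

Row classification is greedy: take the unmasked stripe with the highest
vegetation fraction as a crop row, mask every stripe whose centreline lies
within `row_spacing − width/2` of it (so a heavily infested neighbouring
stripe can never become a row), and stop when the best remaining fraction
falls below `stop_ratio` (default 0.5) of the first row's fraction or below
`min_fraction` (default 0.05). A completion pass follows: because rows recur
at the known spacing, any stripe on the row grid of an accepted row (integer
multiple of the spacing, within half a stripe width) whose fraction exceeds
`min_fraction` is also accepted. This rescues rows clipped at the field
border, whose stripes extend past the end of the row segment and are diluted
below the `stop_ratio` cut. Remaining stripes become *buffer* (sharing a
border with a row stripe; masked stripes are re-eligible here) or
*non-crop*.

## Crop/weed discrimination

The upper→lower hierarchy assigns vegetation objects under row stripes to
crop, under non-crop stripes to weed, and leaves buffer objects unresolved.
These are settled by minimum spectral distance: the adjacency graph is
searched outwards (radius 1, 2, 4, …) for crop and weed exemplars classified
by the hierarchy (using hierarchy exemplars only keeps the outcome
independent of resolution order); the object takes the class whose exemplar
mean is nearest in Euclidean distance over calibrated per-band means (an
index-value feature space is available). Degenerate cases resolve
conservatively — exact tie → weed; no weed exemplars anywhere → crop wins
only by being the sole class; no classified vegetation at all → weed,
flagged. Over-detection is preferred to under-detection because treating a
weed-free spot costs far less than leaving an infestation unsprayed.

## Frame assessment

Ground truth comes as 1 × 1 m frames snapped to the pixel grid. An observed
weed plant (8-connected component) counts as detected when ≥ `min_overlap`
(default 0.1) of its pixels are predicted weed; spurious weed area is
predicted weed not overlapping observed weed. Categories are exclusive and
decided in this order: false-positive (spurious area > `fp_area_frac`
(default 0.05) of the frame) → false-negative (infested, nothing detected)
→ underestimated (some plants missed) → correct. The two thresholds
operationalise what is, in field practice, a visual judgement; both are
configurable and recorded in output metadata, and false-positive precedence
is a declared convention.

## Synthetic scenes

The generator emulates an early-season sunflower field: rows 0.7 m apart
(first centreline half a spacing from the field edge; rows shorter than
0.5 m in-field are dropped), plants every 0.18 m with canopy radius
8–12 cm, and weed seedlings (radius 4–8 cm, default 2 plants/m²) from a
Thomas cluster process (parent density 0.25 m⁻², cluster σ 0.4 m) — weeds
are patchy in real fields — restricted so weed disks never touch row
plants. Reflectances are drawn per class/band from normals (bright dry
soil line; crop with strong green/red-edge/NIR response; weed a slightly
lighter green, deliberately close to crop), modulated by a radial canopy
falloff, a ±8% linear illumination ramp and N(0, 0.01) pixel noise. Soil
texture mixes a ~10 cm-correlated field with white grain. Default field size
is 6 × 6 m — large enough for 9–12 rows and a 2 × 2 sub-plot grid while
keeping a full pipeline run at 1.5 cm GSD to a few seconds. Ground truth
(class raster, row centrelines, weed components, frames) is recorded before
noise; one integer seed drives all randomness, and identical specs and seeds
are bit-identical.

Altitude degradation block-averages the image to a coarser GSD (area-weighted
resampling for non-integer ratios) and re-rasterises ground truth by majority
label (ties resolve in class-code order soil < crop < weed). A 0.45 m
calibration panel can be embedded on bare soil near the field centre; its
footprint becomes nodata so it never enters assessment.

**What passing these tests shows — and does not.** The synthetic fields have
straight rows, disk-shaped plants, Gaussian class spectra and no shadows,
mosaicking seams, perspective or terrain. Perfect row detection and
weed-free-frame classification on them demonstrate the internal consistency
and the structural logic of the pipeline under its own assumptions, not
field-grade accuracy; real imagery adds spectral mixing at row edges, shadow
confusion (a crude shadow mode exists, off by default) and plant-shape
variability that degrade weed discrimination well before they affect row
finding.

## Numerical conventions

Population (÷ n) standard deviations everywhere; single pixels have σ = 0.
Perimeters count exposed pixel edges; a pixel's bounding box is itself.
Otsu plateaus return midpoints; vegetation uses strict `>`. Angles are
counterclockwise from the x-axis, modulo 180°. Stripe-boundary points go to
the lower-index stripe. Merge-cost ties break to the lower object id (the
object containing the smallest row-major pixel index). All pipeline stages
are deterministic given the image and configuration.

## Known limitations

Curved or interrupted rows, per-row plant counting and row-gap detection are
out of scope; the orientation model assumes one field-wide direction. The
mutual-best-fit merge order is a stand-in for a proprietary heuristic. The
completion pass assumes the sowing grid is strictly periodic. Segmentation
cost scaling assumes an 8-bit-like dynamic range; images calibrated to
reflectance are rescaled internally. The frame evaluation thresholds are
conventions, not fitted quantities.
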