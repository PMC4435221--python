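"""Frame-based weed-coverage assessment.

Ground truth comes as 1 x 1 m georeferenced sampling frames with per-pixel
observed labels (crop / weed / soil).  Per frame the pipeline's prediction is
scored into one of four exclusive categories:

* **correct** — every observed weed plant was detected and no appreciable
  spurious weed area was predicted (covers weed-free frames predicted clean);
* **underestimated** — some observed weed plants detected, others missed;
* **false_negative** — a weed-infested frame with no plant detected;
* **false_positive** — weeds were overestimated: predicted weed area not
  overlapping any observed weed exceeds a fraction of the frame.

A plant counts as *detected* when at least ``min_overlap`` of its pixels are
predicted weed; overestimation triggers when the spurious weed area exceeds
``fp_area_frac`` of the frame.  Both thresholds operationalise a visual
judgement and are configurable; false-positive takes precedence when over-
and under-detection co-occur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .classify import CROP, NODATA, SOIL, WEED, ClassMap
from .errors import BoundsError, InvalidArgumentError
from .geometry import FieldImage

CATEGORY_CORRECT = "correct"
CATEGORY_UNDER = "underestimated"
CATEGORY_FALSE_NEG = "false_negative"
CATEGORY_FALSE_POS = "false_positive"
CATEGORIES = (CATEGORY_CORRECT, CATEGORY_UNDER, CATEGORY_FALSE_NEG, CATEGORY_FALSE_POS)


@dataclass
class SampleFrame:
    """A 1 x 1 m ground-truth square snapped to the pixel grid.

    ``window`` is the half-open pixel rectangle; ``observed`` the ground
    truth label raster of the same shape (codes as in :mod:`rowweed.classify`).
    """

    frame_id: int
    window: tuple[int, int, int, int]
    observed: np.ndarray
    side_m: float = 1.0

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.window
        if self.observed.shape != (r1 - r0, c1 - c0):
            raise InvalidArgumentError("observed labels do not match the frame window")

    @staticmethod
    def from_world_square(
        truth: np.ndarray, image: FieldImage, x0: float, y0: float,
        side_m: float = 1.0, frame_id: int = 0,
    ) -> "SampleFrame":
        """Snap a world square (min corner ``(x0, y0)``) to the pixel grid."""
        g = image.gsd_m
        c0 = int(round((x0 - image.origin[0]) / g))
        r1 = int(round((image.origin[1] - y0) / g))
        side = int(round(side_m / g))
        r0, c1 = r1 - side, c0 + side
        h, w = truth.shape
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            raise BoundsError("frame outside the raster")
        return SampleFrame(
            frame_id=frame_id, window=(r0, c0, r1, c1),
            observed=truth[r0:r1, c0:c1].copy(), side_m=side_m,
        )


@dataclass(frozen=True)
class FrameOutcome:
    frame_id: int
    category: str
    predicted_weed_coverage_pct: float
    observed_weed_coverage_pct: float
    weed_present: bool
    n_plants: int
    n_detected: int


def _frame_slice(classmap: ClassMap, frame: SampleFrame) -> np.ndarray:
    r0, c0, r1, c1 = frame.window
    h, w = classmap.labels.shape
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise BoundsError(f"frame {frame.frame_id} outside the class map")
    return classmap.labels[r0:r1, c0:c1]


def weed_coverage(classmap: ClassMap, frame: SampleFrame) -> float:
    """Percentage of valid frame pixels classified weed."""
    pred = _frame_slice(classmap, frame)
    valid = pred != NODATA
    if not valid.any():
        raise InvalidArgumentError(f"frame {frame.frame_id} has no valid pixels")
    return 100.0 * float(np.sum(pred[valid] == WEED)) / float(valid.sum())


def _coverage(labels: np.ndarray) -> float:
    valid = labels != NODATA
    return 100.0 * float(np.sum(labels[valid] == WEED)) / max(int(valid.sum()), 1)


def assess_frame(
    predicted: ClassMap,
    frame: SampleFrame,
    min_overlap: float = 0.1,
    fp_area_frac: float = 0.05,
) -> FrameOutcome:
    """Score one ground-truth frame against the prediction.

    Observed weed plants are 8-connected components of the observed weed
    mask.  See the module docstring for the decision rule.
    """
    pred = _frame_slice(predicted, frame)
    obs = frame.observed
    if pred.size == 0:
        raise InvalidArgumentError("empty frame")

    obs_weed = obs == WEED
    pred_weed = pred == WEED
    structure = np.ones((3, 3), dtype=bool)
    plant_labels, n_plants = ndimage.label(obs_weed, structure=structure)

    n_detected = 0
    for p in range(1, n_plants + 1):
        plant = plant_labels == p
        overlap = float(np.sum(pred_weed & plant)) / float(np.sum(plant))
        if overlap >= min_overlap:
            n_detected += 1

    frame_area = float(np.sum(pred != NODATA))
    spurious = float(np.sum(pred_weed & ~obs_weed & (pred != NODATA)))

    if spurious > fp_area_frac * frame_area:
        category = CATEGORY_FALSE_POS
    elif n_plants > 0 and n_detected == 0:
        category = CATEGORY_FALSE_NEG
    elif n_plants > 0 and n_detected < n_plants:
        category = CATEGORY_UNDER
    else:
        category = CATEGORY_CORRECT

    return FrameOutcome(
        frame_id=frame.frame_id,
        category=category,
        predicted_weed_coverage_pct=_coverage(pred),
        observed_weed_coverage_pct=_coverage(obs),
        weed_present=bool(n_plants > 0),
        n_plants=int(n_plants),
        n_detected=int(n_detected),
    )


def summarize_assessment(
    outcomes: list[FrameOutcome], extra_strata: dict[int, dict] | None = None
) -> pd.DataFrame:
    """Percentages of the four categories per stratum (weed vs weed-free).

    ``extra_strata`` maps frame_id to additional grouping columns (e.g. GSD).
    Each row of the returned table sums to 100 over the category columns.
    """
    if not outcomes:
        raise InvalidArgumentError("no outcomes to summarize")
    records = []
    for o in outcomes:
        rec = {
            "weed_presence": "weed" if o.weed_present else "no_weed",
            "category": o.category,
        }
        if extra_strata and o.frame_id in extra_strata:
            rec.update(extra_strata[o.frame_id])
        records.append(rec)
    df = pd.DataFrame(records)
    keys = [c for c in df.columns if c != "category"]
    counts = df.groupby(keys, sort=True)["category"].value_counts().unstack(fill_value=0)
    for cat in CATEGORIES:
        if cat not in counts.columns:
            counts[cat] = 0
    counts = counts[list(CATEGORIES)]
    pct = 100.0 * counts.div(counts.sum(axis=1), axis=0)
    pct.columns = [f"{c}_pct" for c in pct.columns]
    pct["n_frames"] = counts.sum(axis=1)
    return pct.reset_index()
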