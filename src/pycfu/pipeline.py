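"""End-to-end counting pipeline and the two CSV output formats.

``count_image`` runs preprocess -> score-map -> segmentation -> colour
postfilter -> ROI filtering on one image; ``run_batch`` maps it over a
list of files, never aborting the batch on a single bad image, and
``write_outputs`` writes the summary (one row per image) and detailed
(one row per object) tables.  The whole pipeline is deterministic: the
same image and configuration always produce byte-identical outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .config import PipelineConfig
from .postfilter import filter_by_likelihood, fit_colour_model
from .preprocess import preprocess_image
from .roi import RoiMask, detect_dish, filter_objects, full_frame_mask
from .scoremap import build_scoremap, default_thresholds, threshold_scoremap
from .segment import regularise_mask, split_and_validate

log = logging.getLogger(__name__)

__all__ = ["ColonyRecord", "SummaryRow", "ImageResult", "count_image",
           "run_batch", "write_outputs", "SUMMARY_COLUMNS",
           "DETAILED_COLUMNS"]

SUMMARY_COLUMNS = ["image", "count", "mask_surface"]
DETAILED_COLUMNS = ["image", "mask_surface", "x", "y", "median_r",
                    "median_g", "median_b", "area", "perimeter",
                    "cluster_size", "excluded"]


@dataclass
class ColonyRecord:
    """One detected object: centre, corrected colour medians, morphology.

    ``median_*`` are medians of the background-subtracted (polarity
    corrected) channels over the object's pixels.  ``excluded`` marks
    objects flagged by the colour postfilter; they stay in the detailed
    output.  Coordinates are 0-based pixel indices, x = column, y = row.
    """

    image_name: str
    mask_surface: int
    x: float
    y: float
    median_r: float
    median_g: float
    median_b: float
    area: float
    perimeter: float
    cluster_size: int
    excluded: bool = False


@dataclass
class SummaryRow:
    image_name: str
    count: int | None  #: None if the image could not be processed
    mask_surface: int


@dataclass
class ImageResult:
    summary: SummaryRow
    records: list[ColonyRecord] = field(default_factory=list)


def _object_medians(obj, foregrounds):
    y0, x0, y1, x1 = obj.bbox
    meds = []
    for fg in foregrounds:
        meds.append(float(np.median(fg[y0:y1, x0:x1][obj.mask])))
    while len(meds) < 3:  # grey input: replicate the single channel
        meds.append(meds[0])
    return meds


def count_image(image: np.ndarray, config: PipelineConfig | None = None,
                name: str = "image", roi: RoiMask | None = None) -> ImageResult:
    """Count colonies on one image.

    Parameters
    ----------
    image : (H, W, 3) uint8 RGB (or (H, W) grey) array
    config : PipelineConfig
    name : label used in the output rows
    roi : optional pre-made mask; overrides auto-petri
    """
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    image = np.asarray(image)
    shape = image.shape[:2]
    r_max = config.filter.resolved_r_max(shape)
    # freeze the image-derived maximal radius into the filter constants so
    # every stage (screen size cap included) sees the same value
    fparams = replace(config.filter, r_max=r_max)

    if roi is None:
        if config.roi.auto_petri:
            lum = (image.mean(axis=2) if image.ndim == 3
                   else image.astype(np.float64))
            roi = detect_dish(lum, config.roi.margin, config.roi)
        else:
            roi = full_frame_mask(shape)

    grey, foregrounds = preprocess_image(
        image, r_max=r_max, params=config.preprocess, mask=roi.mask)

    thresholds = default_thresholds(grey, config.scoremap.stride, roi.mask)
    if not thresholds:
        log.info("%s: flat image inside ROI; no objects", name)
        return ImageResult(SummaryRow(name, 0, roi.surface))

    sm = build_scoremap(grey, fparams, thresholds, roi.mask)
    score_t = config.scoremap.score_threshold
    if isinstance(score_t, int) and score_t > 0:
        score_t = min(score_t, sm.n_thresholds)
    else:
        score_t = "auto"
    mask = threshold_scoremap(sm, score_t)
    mask = regularise_mask(mask, config.segment.mask_smooth_iters)

    objects = split_and_validate(mask, fparams, config.segment, r_max)
    objects = filter_objects(objects, roi)
    log.info("%s: %d objects after segmentation (%.2f s)", name,
             len(objects), time.perf_counter() - t0)

    medians = [_object_medians(o, foregrounds) for o in objects]
    excluded = np.zeros(len(objects), dtype=bool)
    if config.postfilter.enabled and objects:
        model = fit_colour_model([m for m in medians],
                                 [o.cluster_size for o in objects],
                                 config.postfilter)
        excluded = filter_by_likelihood(medians, model,
                                        config.postfilter.quantile)

    records = []
    for obj, med, exc in zip(objects, medians, excluded):
        records.append(ColonyRecord(
            image_name=name, mask_surface=roi.surface,
            x=obj.centroid[1], y=obj.centroid[0],
            median_r=med[0], median_g=med[1], median_b=med[2],
            area=obj.area, perimeter=obj.perimeter,
            cluster_size=obj.cluster_size, excluded=bool(exc)))
    count = int(sum(1 for r in records if not r.excluded))
    return ImageResult(SummaryRow(name, count, roi.surface), records)


def run_batch(images, config: PipelineConfig | None = None,
              masks=None) -> tuple[list[SummaryRow], list[ColonyRecord]]:
    """Process a list of image paths (or (name, array) pairs).

    Unreadable or failing images are logged and reported with count NA;
    the batch continues.
    """
    config = config or PipelineConfig()
    rows: list[SummaryRow] = []
    records: list[ColonyRecord] = []
    for i, item in enumerate(images):
        if isinstance(item, (tuple, list)):
            name, img = item
        else:
            name = str(item)
            try:
                img = iio.imread(item)
            except Exception:
                log.exception("cannot read %s; skipping", item)
                rows.append(SummaryRow(name, None, 0))
                continue
        if img.ndim == 3 and img.shape[2] == 4:
            img = img[:, :, :3]
        roi = None
        if masks is not None and masks[i] is not None:
            roi = RoiMask(mask=np.asarray(masks[i]) > 0, origin="manual")
        try:
            result = count_image(img, config, name=name, roi=roi)
        except Exception:
            log.exception("processing failed for %s", name)
            rows.append(SummaryRow(name, None, 0))
            continue
        rows.append(result.summary)
        records.extend(result.records)
    return rows, records


def write_outputs(rows, records, summary_path, detailed_path) -> None:
    """Write the summary and detailed CSV files with their fixed headers."""
    summary = pd.DataFrame(
        [(r.image_name, r.count if r.count is not None else "NA",
          r.mask_surface) for r in rows],
        columns=SUMMARY_COLUMNS)
    detailed = pd.DataFrame(
        [(c.image_name, c.mask_surface, c.x, c.y, c.median_r, c.median_g,
          c.median_b, c.area, c.perimeter, c.cluster_size, int(c.excluded))
         for c in records],
        columns=DETAILED_COLUMNS)
    summary.to_csv(summary_path, index=False)
    detailed.to_csv(detailed_path, index=False)
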