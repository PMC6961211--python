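"""Per-ROI morphometrics of detected mitolysosomes.

Counts, areas and intensity statistics are aggregated per cell/tissue ROI.
Intensity means and totals are taken on the raw (unsmoothed) channels, since
they are read-outs of reporter content; the median filter exists only to
stabilise detection.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .io import rasterize_roi
from .types import (
    DetectionParams,
    DetectionResult,
    Roi,
    RoiMeasurements,
    RoiSet,
    TwoChannelImage,
)

__all__ = ["measure_roi", "measure_image"]

logger = logging.getLogger(__name__)


def measure_roi(
    result: DetectionResult,
    image: TwoChannelImage,
    roi: Roi,
    params: DetectionParams,
) -> RoiMeasurements:
    """One results-table row for a single ROI.

    Areas are in um^2 (pixel count x pixel_size_um^2).  ``rg_ratio`` is the
    ratio of total red to total green intensity within the ROI.  The
    mitolysosome count is the number of accepted peaks whose pixel lies
    inside the rasterized ROI; mitolysosome areas come from the mitophagy
    mask restricted to the ROI.  Mean mitolysosome size divides mask area by
    the peak count and is reported as 0 when no peak falls in the ROI.
    """
    raster = rasterize_roi(roi, image.shape)
    n_px = int(raster.sum())
    if n_px == 0:
        raise ValueError(f"ROI {roi.label!r} rasterizes to 0 pixels")
    px_area = image.pixel_size_um**2
    cell_area = n_px * px_area

    red_total = float(image.red[raster].sum())
    green_total = float(image.green[raster].sum())
    red_mean = red_total / n_px
    green_mean = green_total / n_px
    if green_total > 0:
        rg_ratio = red_total / green_total
    else:
        logger.warning("ROI %r has zero total green intensity", roi.label)
        rg_ratio = 0.0

    n = sum(1 for x, y in result.peaks if raster[y, x])
    ml_px = int((result.mask & raster).sum())
    ml_total_area = ml_px * px_area

    nml_per_um2 = n / cell_area
    nml_over_green = n / green_mean if green_mean > 0 else 0.0
    ml_pct_area = 100.0 * ml_total_area / cell_area
    ml_mean_area = ml_total_area / n if n > 0 else 0.0
    ml_area_over_green = ml_total_area / green_mean if green_mean > 0 else 0.0

    ys, xs = np.nonzero(raster)
    return RoiMeasurements(
        image=image.name,
        cell_roi=roi.label,
        cell_area_um2=cell_area,
        green_mean=green_mean,
        red_mean=red_mean,
        green_total=green_total,
        red_total=red_total,
        rg_ratio=rg_ratio,
        n_mitolysosomes=n,
        nml_per_um2=nml_per_um2,
        nml_over_green=nml_over_green,
        ml_total_area_um2=ml_total_area,
        ml_pct_area=ml_pct_area,
        ml_mean_area_um2=ml_mean_area,
        ml_area_over_green=ml_area_over_green,
        x_tl=int(xs.min()),
        y_tl=int(ys.min()),
        ratio_thresh=params.ratio_thresh,
        red_thresh=result.red_threshold_value,
        smooth_rad=params.smooth_radius,
    )


def measure_image(
    result: DetectionResult,
    image: TwoChannelImage,
    roi_set: RoiSet,
    params: DetectionParams,
) -> list[RoiMeasurements]:
    """One row per ROI, in ROI-set order.

    Overlapping ROIs are measured independently; a peak in the overlap
    counts in every ROI containing it (a warning is logged when that
    happens).
    """
    if len(roi_set) == 0:
        raise ValueError("ROI set is empty")
    rows = []
    claimed = np.zeros(image.shape, dtype=bool)
    overlap_warned = False
    for roi in roi_set:
        raster = rasterize_roi(roi, image.shape)
        if not overlap_warned and (claimed & raster).any():
            if any(raster[y, x] and claimed[y, x] for x, y in result.peaks):
                logger.warning(
                    "overlapping ROIs: peaks in the overlap are counted in every ROI"
                )
                overlap_warned = True
        claimed |= raster
        rows.append(measure_roi(result, image, roi, params))
    return rows
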