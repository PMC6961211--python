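"""Reading and writing the external artifacts of the pipeline.

Handles multi-channel TIFF input (interleaved or ImageJ hyperstack channel
layouts, with pixel calibration from the resolution tags), ImageJ ROI
containers and label masks, polygon rasterization, the per-ROI results CSV
and the derived ratio / mask / overlay images.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image as PILImage

from . import ijroi
from .types import DetectionResult, Roi, RoiSet, RoiMeasurements, TwoChannelImage

__all__ = [
    "CSV_COLUMNS",
    "read_image",
    "read_rois",
    "rasterize_roi",
    "write_results_csv",
    "write_derived_images",
]

logger = logging.getLogger(__name__)

#: Results-table column names, in output order.
CSV_COLUMNS = [
    "Image",
    "CellROI",
    "CellArea_μm2",
    "greenMean",
    "redMean",
    "RGratio",
    "nMitolysosomes",
    "nML_per_um2",
    "nML_over_green",
    "MLtotalArea_μm2",
    "MLpctArea",
    "MLmeanArea_μm2",
    "MLarea_μm2_over_green",
    "X_tl",
    "Y_tl",
    "ratioThresh",
    "redThresh",
    "smoothRad",
]

_MICRON_UNITS = {"um", "µm", "μm", "micron", "microns", "micrometer"}


def _pixel_size_um(tif: tifffile.TiffFile) -> float | None:
    """Pixel size from TIFF resolution tags, in micrometres per pixel."""
    page = tif.pages[0]
    tags = page.tags
    xres = tags.get("XResolution")
    if xres is None:
        return None
    num, den = xres.value
    if num == 0 or den == 0:
        return None
    pixels_per_unit = num / den
    unit_um = None
    ij = tif.imagej_metadata or {}
    ij_unit = str(ij.get("unit", "")).lower()
    if ij_unit in _MICRON_UNITS:
        unit_um = 1.0
    else:
        resunit = tags.get("ResolutionUnit")
        code = getattr(resunit.value, "value", resunit.value) if resunit else 1
        if code == 2:  # inch
            unit_um = 25400.0
        elif code == 3:  # centimetre
            unit_um = 10000.0
        elif ij_unit:  # unknown ImageJ unit string
            return None
    if unit_um is None:
        return None
    return unit_um / pixels_per_unit


def read_image(
    path: str | Path, red_channel_index: int, green_channel_index: int
) -> TwoChannelImage:
    """Load a multi-channel TIFF and assign the mCherry / GFP channels.

    Channel indices are 1-based, matching the channel numbers a microscopy
    user sees.  Pixel calibration is taken from the TIFF resolution
    metadata when present, else it defaults to 1 um/pixel with a warning
    (areas would then effectively be in pixel units).
    """
    path = Path(path)
    if red_channel_index == green_channel_index:
        raise ValueError("red and green channel indices must be distinct")
    if red_channel_index < 1 or green_channel_index < 1:
        raise ValueError("channel indices are 1-based and must be >= 1")
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")

    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        pixel_size = _pixel_size_um(tif)

    if data.ndim < 3:
        raise ValueError("image has fewer than 2 channels")
    if "C" in axes:
        caxis = axes.index("C")
    elif "S" in axes:  # interleaved samples (e.g. RGB)
        caxis = axes.index("S")
    else:
        caxis = int(np.argmin(data.shape))
        logger.warning(
            "%s: no channel axis in metadata; assuming axis %d (size %d)",
            path.name,
            caxis,
            data.shape[caxis],
        )
    data = np.moveaxis(data, caxis, 0)
    while data.ndim > 3:  # z-stacks / time series: analyse the first plane
        logger.warning("%s: taking first plane of extra axis (shape %s)", path.name, data.shape)
        data = data[:, 0]
    n_channels = data.shape[0]
    if n_channels < 2:
        raise ValueError("image has fewer than 2 channels")
    for idx, which in ((red_channel_index, "red"), (green_channel_index, "green")):
        if idx > n_channels:
            raise ValueError(
                f"{which} channel index {idx} out of range (image has {n_channels} channels)"
            )

    if pixel_size is None:
        pixel_size = 1.0
        logger.warning(
            "%s: no pixel calibration in TIFF metadata; assuming 1 um/pixel",
            path.name,
        )
    return TwoChannelImage(
        red=data[red_channel_index - 1].astype(np.float64),
        green=data[green_channel_index - 1].astype(np.float64),
        pixel_size_um=float(pixel_size),
        name=path.stem,
    )


def _rois_from_label_mask(labels: np.ndarray) -> list[Roi]:
    values = np.unique(labels)
    values = values[values > 0]
    return [Roi(label=str(int(v)), mask=labels == v) for v in values]


def read_rois(path: str | Path, image_shape: tuple[int, int]) -> RoiSet:
    """Read an ImageJ .roi file, a .zip of .roi files, or a label mask.

    Label masks (TIFF/PNG rasters of integer labels, background 0) yield one
    mask ROI per label, labelled by the integer value.  File order / label
    order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ROI file not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".roi":
        rois = [ijroi.read_roi_file(path)]
    elif suffix == ".zip":
        rois = ijroi.read_roi_zip(path)
    elif suffix in {".tif", ".tiff"}:
        rois = _rois_from_label_mask(tifffile.imread(path))
    elif suffix == ".png":
        rois = _rois_from_label_mask(np.asarray(PILImage.open(path)))
    else:
        raise ValueError(f"unsupported ROI container: {path.name}")
    if not rois:
        raise ValueError(f"no ROIs found in {path.name}")
    # deduplicate labels while preserving order
    seen: dict[str, int] = {}
    for roi in rois:
        if roi.label in seen:
            seen[roi.label] += 1
            roi.label = f"{roi.label}-{seen[roi.label]}"
        else:
            seen[roi.label] = 1
    return RoiSet(rois=rois)


def _polygon_mask_evenodd(
    polygon: Sequence[tuple[float, float]], image_shape: tuple[int, int]
) -> np.ndarray:
    """Even-odd rasterization of a polygon, tested at pixel centers."""
    h, w = image_shape
    xs = np.array([p[0] for p in polygon])
    ys = np.array([p[1] for p in polygon])
    # restrict the test to the polygon's bounding box, clipped to the image
    x0 = max(int(np.floor(xs.min())), 0)
    x1 = min(int(np.ceil(xs.max())), w)
    y0 = max(int(np.floor(ys.min())), 0)
    y1 = min(int(np.ceil(ys.max())), h)
    out = np.zeros((h, w), dtype=bool)
    if x0 >= x1 or y0 >= y1:
        return out
    px, py = np.meshgrid(
        np.arange(x0, x1) + 0.5, np.arange(y0, y1) + 0.5, indexing="xy"
    )
    inside = np.zeros(px.shape, dtype=bool)
    n = len(polygon)
    for i in range(n):
        xa, ya = xs[i], ys[i]
        xb, yb = xs[(i + 1) % n], ys[(i + 1) % n]
        crosses = (ya <= py) != (yb <= py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xi = xa + (py - ya) * (xb - xa) / (yb - ya)
        inside ^= crosses & (px < xi)
    out[y0:y1, x0:x1] = inside
    return out


def rasterize_roi(roi: Roi, image_shape: tuple[int, int]) -> np.ndarray:
    """Binary raster of an ROI; polygon membership uses the even-odd rule.

    Raises if the ROI lies entirely outside the image; a valid but
    degenerate polygon (zero area) yields an all-false raster with a
    warning.
    """
    h, w = image_shape
    if roi.mask is not None:
        if roi.mask.shape != (h, w):
            raise ValueError(
                f"mask ROI shape {roi.mask.shape} does not match image shape {(h, w)}"
            )
        return roi.mask.copy()
    xs = [p[0] for p in roi.polygon]
    ys = [p[1] for p in roi.polygon]
    if min(xs) >= w or max(xs) <= 0 or min(ys) >= h or max(ys) <= 0:
        raise ValueError("ROI outside image bounds")
    raster = _polygon_mask_evenodd(roi.polygon, image_shape)
    if not raster.any():
        logger.warning("ROI %r rasterizes to 0 pixels (degenerate polygon)", roi.label)
    return raster


def write_results_csv(rows: Sequence[RoiMeasurements], path: str | Path) -> None:
    """Write the per-ROI results table; an empty run gives a header-only CSV."""
    records = [
        {
            "Image": m.image,
            "CellROI": m.cell_roi,
            "CellArea_μm2": m.cell_area_um2,
            "greenMean": m.green_mean,
            "redMean": m.red_mean,
            "RGratio": m.rg_ratio,
            "nMitolysosomes": m.n_mitolysosomes,
            "nML_per_um2": m.nml_per_um2,
            "nML_over_green": m.nml_over_green,
            "MLtotalArea_μm2": m.ml_total_area_um2,
            "MLpctArea": m.ml_pct_area,
            "MLmeanArea_μm2": m.ml_mean_area_um2,
            "MLarea_μm2_over_green": m.ml_area_over_green,
            "X_tl": m.x_tl,
            "Y_tl": m.y_tl,
            "ratioThresh": m.ratio_thresh,
            "redThresh": m.red_thresh,
            "smoothRad": m.smooth_rad,
        }
        for m in rows
    ]
    df = pd.DataFrame.from_records(records, columns=CSV_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")


def _normalize_u8(raster: np.ndarray) -> np.ndarray:
    lo, hi = float(raster.min()), float(raster.max())
    if hi <= lo:
        return np.zeros(raster.shape, dtype=np.uint8)
    return ((raster - lo) * (255.0 / (hi - lo))).astype(np.uint8)


def write_derived_images(
    result: DetectionResult,
    roi_set: RoiSet,
    out_dir: str | Path,
    image: TwoChannelImage,
) -> dict[str, Path]:
    """Write the three derived images for one input image.

    ``<name>_ratio.tif`` (32-bit float ratio), ``<name>_mask.tif`` (8-bit,
    0/255 mitophagy mask) and ``<name>_overlay.png`` (red channel grayscale
    with ROI outlines in yellow and detected peaks marked in cyan).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = image.name
    paths = {
        "ratio": out_dir / f"{name}_ratio.tif",
        "mask": out_dir / f"{name}_mask.tif",
        "overlay": out_dir / f"{name}_overlay.png",
    }
    tifffile.imwrite(paths["ratio"], result.ratio.astype(np.float32))
    tifffile.imwrite(paths["mask"], np.where(result.mask, 255, 0).astype(np.uint8))

    gray = _normalize_u8(image.red)
    rgb = np.stack([gray, gray, gray], axis=-1)
    from scipy import ndimage  # local import to keep module import light

    for roi in roi_set:
        m = rasterize_roi(roi, image.shape)
        outline = m & ~ndimage.binary_erosion(m)
        rgb[outline] = (255, 255, 0)
    h, w = image.shape
    for x, y in result.peaks:
        for dx, dy in ((0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)):
            xx, yy = x + dx, y + dy
            if 0 <= xx < w and 0 <= yy < h:
                rgb[yy, xx] = (0, 255, 255)
    PILImage.fromarray(rgb).save(paths["overlay"])
    return paths
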