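"""Core domain types shared across the package.

The unit of analysis is a two-channel fluorescence image carrying an
mCherry (red) and a GFP (green) raster of a tandem mCherry-GFP mitophagy
reporter.  Outside lysosomes both fluorophores emit, so red/green is close
to 1; inside mitolysosomes GFP is quenched by the acidic pH and the ratio
rises, which is what detection exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

__all__ = [
    "TwoChannelImage",
    "Roi",
    "RoiSet",
    "DetectionParams",
    "DetectionResult",
    "RoiMeasurements",
]


@dataclass
class TwoChannelImage:
    """An mCherry/GFP image pair with pixel calibration.

    Parameters
    ----------
    red, green : ndarray
        2-D non-negative intensity rasters of identical shape (arbitrary
        units).  ``red`` is the mCherry channel, ``green`` the GFP channel.
    pixel_size_um : float
        Physical size of one pixel side in micrometres.
    name : str
        Image identifier used in result tables.
    """

    red: np.ndarray
    green: np.ndarray
    pixel_size_um: float = 1.0
    name: str = "image"

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red, dtype=np.float64)
        self.green = np.asarray(self.green, dtype=np.float64)
        if self.red.ndim != 2 or self.green.ndim != 2:
            raise ValueError("channels must be 2-D rasters")
        if self.red.shape != self.green.shape:
            raise ValueError(
                f"channel shapes differ: red {self.red.shape} vs green {self.green.shape}"
            )
        if not (np.all(np.isfinite(self.red)) and np.all(np.isfinite(self.green))):
            raise ValueError("channel intensities must be finite")
        if (self.red < 0).any() or (self.green < 0).any():
            raise ValueError("channel intensities must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape


@dataclass
class Roi:
    """One region of interest: a polygon (vertex list) or a binary mask.

    Polygon vertices are ``(x, y)`` pairs in pixel units with the origin at
    the top-left corner of pixel ``(0, 0)``; membership is decided at pixel
    centers ``(x + 0.5, y + 0.5)`` with the even-odd rule.
    """

    label: str
    polygon: Union[Sequence[tuple[float, float]], None] = None
    mask: Union[np.ndarray, None] = None

    def __post_init__(self) -> None:
        if (self.polygon is None) == (self.mask is None):
            raise ValueError("Roi needs exactly one of polygon or mask")
        if self.polygon is not None:
            self.polygon = [(float(x), float(y)) for x, y in self.polygon]
            if len(self.polygon) < 3:
                raise ValueError("polygon ROI needs at least 3 vertices")
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.ndim != 2:
                raise ValueError("mask ROI must be 2-D")
            if not self.mask.any():
                raise ValueError("mask ROI has no true pixels")


@dataclass
class RoiSet:
    """Ordered collection of uniquely labelled ROIs within one image."""

    rois: list[Roi] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rois]
        if len(set(labels)) != len(labels):
            raise ValueError("ROI labels must be unique within a set")

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)


@dataclass
class DetectionParams:
    """User-facing thresholds of the counting method.

    smooth_radius : pixels; radius of the circular median-filter kernel
        applied to both channels before the ratio is formed.  0 disables
        filtering.
    ratio_thresh : prominence ("noise tolerance") used when detecting peaks
        in the ratio image.  A local maximum counts only if it stands more
        than this value above the highest saddle connecting it to higher
        ground.
    red_stddev_offset : the red intensity threshold is
        mean(red) + red_stddev_offset * std(red), computed over the whole
        smoothed red channel; may be negative.
    red_channel_index / green_channel_index : 1-based channel numbers in the
        source image.
    """

    smooth_radius: float = 1.0
    ratio_thresh: float = 0.5
    red_stddev_offset: float = 0.0
    red_channel_index: int = 1
    green_channel_index: int = 2

    def __post_init__(self) -> None:
        if self.smooth_radius < 0:
            raise ValueError("smooth_radius must be >= 0")
        if not self.ratio_thresh > 0:
            raise ValueError("ratio_thresh must be > 0")


@dataclass
class DetectionResult:
    """Everything the detector derives from one image.

    ratio : the mCherry/GFP ratio raster (finite everywhere).
    peaks : accepted maxima as (x, y) pixel coordinates, one representative
        pixel per equal-valued plateau.
    mask : binary mitophagy mask attributing pixels to mitolysosomes.
    red_threshold_value : realized red intensity cut-off,
        mean(red) + k * std(red) on the smoothed red channel.
    smoothed_red : the median-filtered red channel the threshold and the
        peak filtering were evaluated on.
    """

    ratio: np.ndarray
    peaks: list[tuple[int, int]]
    mask: np.ndarray
    red_threshold_value: float
    smoothed_red: np.ndarray | None = None


@dataclass
class RoiMeasurements:
    """One row of the per-ROI results table."""

    image: str
    cell_roi: str
    cell_area_um2: float
    green_mean: float
    red_mean: float
    green_total: float
    red_total: float
    rg_ratio: float
    n_mitolysosomes: int
    nml_per_um2: float
    nml_over_green: float
    ml_total_area_um2: float
    ml_pct_area: float
    ml_mean_area_um2: float
    ml_area_over_green: float
    x_tl: int
    y_tl: int
    ratio_thresh: float
    red_thresh: float
    smooth_rad: float
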