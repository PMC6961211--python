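"""Synthetic two-channel reporter scenes with exact ground truth.

Emulates the optics of a tandem mCherry-GFP mitophagy reporter: inside a
cell both channels carry the same reporter signal (ratio ~ 1); a
mitolysosome is a punctum of reporter-dense material whose GFP is quenched
by lysosomal pH, so the punctum gains red amplitude while its green is
scaled by ``1 - quench_fraction``:

    red   = base + amplitude * profile
    green = (1 - quench) * (base + amplitude * profile)   within the footprint

With ``quench_fraction = 0`` (the "bafilomycin" condition: lysosomal
de-acidification de-quenches GFP) the two channels are identical and no
red-only punctum exists, which is the method's specificity control.

Puncta are hard disks by default so footprints, mask areas and ratios are
exactly computable; a Gaussian radial profile is available for softer
scenes.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import tifffile

from . import detection
from .types import DetectionParams, Roi, RoiSet, TwoChannelImage

__all__ = [
    "Punctum",
    "SceneSpec",
    "PunctumTruth",
    "render_scene",
    "make_benchmark_suite",
]

logger = logging.getLogger(__name__)


@dataclass
class Punctum:
    """One mitolysosome to render: center (x, y) px, radius px, red
    amplitude (a.u.) and GFP quench fraction in [0, 1]."""

    center: tuple[float, float]
    radius: float
    red_amplitude: float
    green_quench_fraction: float = 0.9


@dataclass
class SceneSpec:
    """Declarative description of one synthetic image."""

    image_shape: tuple[int, int] = (256, 256)
    cells: list[tuple[Sequence[tuple[float, float]], float]] = field(default_factory=list)
    puncta: list[Punctum] = field(default_factory=list)
    background_level: float = 20.0
    noise_sd: float = 0.0
    seed: int = 0
    pixel_size_um: float = 0.1
    profile: Literal["disk", "gaussian"] = "disk"
    name: str = "scene"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PunctumTruth:
    """Ground-truth record for one rendered punctum."""

    punctum_id: int
    center: tuple[float, float]
    radius: float
    red_amplitude: float
    quench_fraction: float
    footprint: frozenset[tuple[int, int]]
    peak_red: float
    contrast: float  # punctum ratio minus the baseline ratio of 1
    detectable: bool | None = None


def _point_in_polygon(x: float, y: float, poly: Sequence[tuple[float, float]]) -> bool:
    inside = False
    n = len(poly)
    for i in range(n):
        xa, ya = poly[i]
        xb, yb = poly[(i + 1) % n]
        if (ya <= y) != (yb <= y):
            xi = xa + (y - ya) * (xb - xa) / (yb - ya)
            if x < xi:
                inside = not inside
    return inside


def _disk_footprint(
    center: tuple[float, float], radius: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Integer pixel indices (ys, xs) with (x-cx)^2 + (y-cy)^2 <= r^2."""
    h, w = shape
    cx, cy = center
    x0, x1 = max(int(np.floor(cx - radius)), 0), min(int(np.ceil(cx + radius)) + 1, w)
    y0, y1 = max(int(np.floor(cy - radius)), 0), min(int(np.ceil(cy + radius)) + 1, h)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    return yy[inside], xx[inside]


def render_scene(
    spec: SceneSpec,
    prominence: float | None = None,
    red_threshold: float | None = None,
) -> tuple[TwoChannelImage, list[PunctumTruth], RoiSet]:
    """Render a scene and return the image, ground truth and cell ROIs.

    When ``prominence`` and ``red_threshold`` are given, each truth record
    gets a ``detectable`` flag: contrast above the prominence AND punctum
    red intensity at or above the threshold.
    """
    h, w = spec.image_shape
    red = np.full((h, w), float(spec.background_level))
    green = red.copy()

    cell_rois = []
    from .io import rasterize_roi  # deferred: io imports types only

    for i, (polygon, base) in enumerate(spec.cells):
        roi = Roi(label=f"cell_{i + 1}", polygon=polygon)
        m = rasterize_roi(roi, (h, w))
        red[m] = base
        green[m] = base
        cell_rois.append(roi)

    truth = []
    for j, p in enumerate(spec.puncta):
        cx, cy = p.center
        host = next(
            (poly for poly, _ in spec.cells if _point_in_polygon(cx, cy, poly)), None
        )
        if host is None:
            raise ValueError(f"punctum {j} at {p.center} lies outside every cell")
        ys, xs = _disk_footprint(p.center, p.radius, (h, w))
        if spec.profile == "gaussian":
            d2 = (xs - cx) ** 2 + (ys - cy) ** 2
            prof = np.exp(-0.5 * d2 / max(p.radius / 2.0, 0.5) ** 2)
        else:
            prof = np.ones(len(xs))
        red[ys, xs] += p.red_amplitude * prof
        green[ys, xs] = (1.0 - p.green_quench_fraction) * red[ys, xs]
        q = p.green_quench_fraction
        contrast = (1.0 / (1.0 - q) - 1.0) if q < 1 else np.inf
        truth.append(
            PunctumTruth(
                punctum_id=j,
                center=p.center,
                radius=p.radius,
                red_amplitude=p.red_amplitude,
                quench_fraction=q,
                footprint=frozenset(zip(xs.tolist(), ys.tolist())),
                peak_red=float(red[ys, xs].max()),
                contrast=float(contrast),
            )
        )

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        red = np.clip(red + rng.normal(0.0, spec.noise_sd, (h, w)), 0.0, None)
        green = np.clip(green + rng.normal(0.0, spec.noise_sd, (h, w)), 0.0, None)

    if prominence is not None and red_threshold is not None:
        for t in truth:
            t.detectable = bool(t.contrast > prominence and t.peak_red >= red_threshold)

    image = TwoChannelImage(
        red=red, green=green, pixel_size_um=spec.pixel_size_um, name=spec.name
    )
    return image, truth, RoiSet(rois=cell_rois)


def _octagon(cx: float, cy: float, r: float, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Slightly irregular octagon approximating a cell outline."""
    pts = []
    for k in range(8):
        ang = 2 * np.pi * k / 8
        rr = r * (0.85 + 0.3 * rng.random())
        pts.append((cx + rr * np.cos(ang), cy + rr * np.sin(ang)))
    return pts


def _place_puncta(
    rng: np.random.Generator,
    cells: list[tuple[list[tuple[float, float]], float]],
    n: int,
    radius_range: tuple[float, float],
    amplitude: float,
    quench: float,
    min_sep_factor: float = 4.0,
) -> list[Punctum]:
    """Rejection-sample punctum centers inside cells with pairwise separation
    of at least ``min_sep_factor`` times the larger radius."""
    puncta: list[Punctum] = []
    attempts = 0
    while len(puncta) < n and attempts < 200 * n:
        attempts += 1
        poly, _ = cells[rng.integers(len(cells))]
        xs = [p[0] for p in poly]
        ys = [p[1] for p in poly]
        x = rng.uniform(min(xs), max(xs))
        y = rng.uniform(min(ys), max(ys))
        r = float(rng.uniform(*radius_range))
        # keep the whole footprint inside the cell (margin of r + 2 px)
        if not all(
            _point_in_polygon(x + dx, y + dy, poly)
            for dx, dy in ((r + 2, 0), (-r - 2, 0), (0, r + 2), (0, -r - 2))
        ):
            continue
        ok = True
        for q in puncta:
            sep = min_sep_factor * max(r, q.radius)
            if (x - q.center[0]) ** 2 + (y - q.center[1]) ** 2 < sep**2:
                ok = False
                break
        if ok:
            puncta.append(
                Punctum(center=(float(x), float(y)), radius=r,
                        red_amplitude=amplitude, green_quench_fraction=quench)
            )
    return puncta


def random_scene(
    seed: int,
    n_puncta: int,
    image_shape: tuple[int, int] = (256, 256),
    noise_sd: float = 0.0,
    quench: float = 0.9,
    base_intensity: float = 120.0,
    background_level: float = 20.0,
    amplitude: float = 500.0,
    radius_range: tuple[float, float] = (2.0, 3.0),
    pixel_size_um: float = 0.1,
    name: str = "scene",
) -> SceneSpec:
    """A reproducible scene: 4 cells on a 2x2 grid with ``n_puncta`` disks.

    Defaults mimic a 16-bit widefield acquisition at high magnification:
    dim extracellular background, uniform reporter signal inside cells, and
    bright mCherry puncta whose GFP is 90% quenched.
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    cells = []
    for gy in (0.25, 0.75):
        for gx in (0.25, 0.75):
            r = 0.17 * min(h, w)
            cells.append((_octagon(gx * w, gy * h, r, rng), base_intensity))
    puncta = _place_puncta(rng, cells, n_puncta, radius_range, amplitude, quench)
    if len(puncta) < n_puncta:
        logger.warning("placed %d of %d requested puncta", len(puncta), n_puncta)
    return SceneSpec(
        image_shape=image_shape,
        cells=cells,
        puncta=puncta,
        background_level=background_level,
        noise_sd=noise_sd,
        seed=int(rng.integers(2**31 - 1)),
        pixel_size_um=pixel_size_um,
        name=name,
    )


def make_benchmark_suite(
    out_dir: str | Path,
    n_images: int = 10,
    seed: int = 0,
    params: DetectionParams | None = None,
    noise_sd: float = 0.0,
    quench: float = 0.9,
    condition_cycle: Sequence[str] = ("dfp", "control"),
) -> pd.DataFrame:
    """Write a batch-compatible benchmark folder and return the truth table.

    Alternates a mitophagy-induced condition (5-50 puncta per image, the
    iron-chelator regime) with a control condition (no puncta).  Per image:
    a calibrated 2-channel TIFF (red = channel 1, green = channel 2), an
    ImageJ ROI zip of the cell outlines, and one combined ground-truth CSV
    for the folder (``ground_truth.csv``).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = params or DetectionParams()
    from . import ijroi

    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_images):
        condition = condition_cycle[i % len(condition_cycle)]
        n_puncta = int(rng.integers(5, 51)) if condition == "dfp" else 0
        name = f"img{i:03d}_{condition}"
        spec = random_scene(
            seed=int(rng.integers(2**31 - 1)),
            n_puncta=n_puncta,
            noise_sd=noise_sd,
            quench=quench,
            name=name,
        )
        image, truth, roi_set = render_scene(spec)
        smoothed_red = detection.median_smooth(image.red, params.smooth_radius)
        red_thr = detection.compute_red_threshold(smoothed_red, params.red_stddev_offset)
        for t in truth:
            t.detectable = bool(
                t.contrast > params.ratio_thresh and t.peak_red >= red_thr
            )

        stack = np.clip(np.round(np.stack([image.red, image.green])), 0, 65535)
        tifffile.imwrite(
            out_dir / f"{name}.tif",
            stack.astype(np.uint16),
            imagej=True,
            resolution=(1.0 / spec.pixel_size_um, 1.0 / spec.pixel_size_um),
            metadata={"unit": "um", "axes": "CYX"},
        )
        ijroi.write_roi_zip(roi_set, out_dir / f"{name}.zip")
        for t in truth:
            records.append(
                {
                    "punctum_id": t.punctum_id,
                    "image": name,
                    "condition": condition,
                    "x": t.center[0],
                    "y": t.center[1],
                    "radius_px": t.radius,
                    "red_amplitude": t.red_amplitude,
                    "quench_fraction": t.quench_fraction,
                    "footprint_px": len(t.footprint),
                    "detectable_flag": t.detectable,
                }
            )
    columns = [
        "punctum_id", "image", "condition", "x", "y", "radius_px",
        "red_amplitude", "quench_fraction", "footprint_px", "detectable_flag",
    ]
    df = pd.DataFrame.from_records(records, columns=columns)
    df.to_csv(out_dir / "ground_truth.csv", index=False)
    return df
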