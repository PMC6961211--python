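"""Minimal ImageJ ``.roi`` codec (read + write).

Implements the subset of the ImageJ ROI binary format (big-endian, magic
``Iout``, version >= 218) needed for cell outlines: polygon, freehand,
traced, rectangle and oval ROIs.  Line, point and other annotation types
are rejected with an error naming the type.  Rectangles and ovals are
converted to polygons on read (ovals as a fine 128-gon) so downstream code
deals with one representation.

Byte layout of the 64-byte header, the packed relative coordinates and the
64-byte second header (holding the name) follows ImageJ's RoiDecoder /
RoiEncoder.
"""

from __future__ import annotations

import math
import struct
import zipfile
from pathlib import Path
from typing import Iterable

from .types import Roi

__all__ = [
    "decode_roi",
    "encode_roi",
    "read_roi_file",
    "read_roi_zip",
    "write_roi_file",
    "write_roi_zip",
]

_MAGIC = b"Iout"
_VERSION = 228

# ROI type byte -> name
_TYPE_NAMES = {
    0: "polygon",
    1: "rectangle",
    2: "oval",
    3: "line",
    4: "freeline",
    5: "polyline",
    6: "no-roi",
    7: "freehand",
    8: "traced",
    9: "angle",
    10: "point",
}
_SUPPORTED = {0, 1, 2, 7, 8}
_OPT_SUBPIXEL = 128


def decode_roi(data: bytes, default_label: str = "roi") -> Roi:
    """Decode one .roi byte blob into a polygon :class:`Roi`."""
    if len(data) < 64 or data[:4] != _MAGIC:
        raise ValueError("not an ImageJ ROI file (bad magic)")
    roi_type = data[6]
    name = _TYPE_NAMES.get(roi_type, f"type {roi_type}")
    if roi_type not in _SUPPORTED:
        raise ValueError(f"unsupported ROI type: {name}")
    top, left, bottom, right = struct.unpack(">4h", data[8:16])
    n = struct.unpack(">h", data[16:18])[0]
    options = struct.unpack(">h", data[50:52])[0]
    hdr2 = struct.unpack(">i", data[60:64])[0]

    label = default_label
    if 0 < hdr2 <= len(data) - 24:
        name_off, name_len = struct.unpack(">2i", data[hdr2 + 16 : hdr2 + 24])
        if name_off > 0 and name_len > 0 and name_off + 2 * name_len <= len(data):
            label = data[name_off : name_off + 2 * name_len].decode("utf-16-be")

    if roi_type == 1:  # rectangle
        poly = [(left, top), (right, top), (right, bottom), (left, bottom)]
        return Roi(label=label, polygon=poly)
    if roi_type == 2:  # oval inscribed in the bounding box
        cx, cy = (left + right) / 2.0, (top + bottom) / 2.0
        rx, ry = (right - left) / 2.0, (bottom - top) / 2.0
        poly = [
            (cx + rx * math.cos(t), cy + ry * math.sin(t))
            for t in (2 * math.pi * i / 128 for i in range(128))
        ]
        return Roi(label=label, polygon=poly)

    if n < 3:
        raise ValueError("polygon ROI with fewer than 3 vertices")
    base = 64
    xs = struct.unpack(f">{n}h", data[base : base + 2 * n])
    ys = struct.unpack(f">{n}h", data[base + 2 * n : base + 4 * n])
    if options & _OPT_SUBPIXEL and len(data) >= base + 4 * n + 8 * n:
        # best-effort: absolute float coordinates follow the integer ones
        fbase = base + 4 * n
        fx = struct.unpack(f">{n}f", data[fbase : fbase + 4 * n])
        fy = struct.unpack(f">{n}f", data[fbase + 4 * n : fbase + 8 * n])
        poly = list(zip(fx, fy))
    else:
        poly = [(x + left, y + top) for x, y in zip(xs, ys)]
    return Roi(label=label, polygon=poly)


def encode_roi(roi: Roi, name: str | None = None) -> bytes:
    """Encode a polygon :class:`Roi` as ImageJ .roi bytes (type polygon)."""
    if roi.polygon is None:
        raise ValueError("only polygon ROIs can be encoded")
    name = roi.label if name is None else name
    xs = [int(round(x)) for x, _ in roi.polygon]
    ys = [int(round(y)) for _, y in roi.polygon]
    left, top = min(xs), min(ys)
    right, bottom = max(xs), max(ys)
    n = len(xs)

    header = bytearray(64)
    header[0:4] = _MAGIC
    struct.pack_into(">h", header, 4, _VERSION)
    header[6] = 0  # polygon
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    coords = struct.pack(f">{n}h", *(x - left for x in xs)) + struct.pack(
        f">{n}h", *(y - top for y in ys)
    )
    hdr2_offset = 64 + len(coords)
    struct.pack_into(">i", header, 60, hdr2_offset)

    name_bytes = name.encode("utf-16-be")
    header2 = bytearray(64)
    struct.pack_into(">2i", header2, 16, hdr2_offset + 64, len(name))
    return bytes(header) + coords + bytes(header2) + name_bytes


def read_roi_file(path: str | Path) -> Roi:
    path = Path(path)
    return decode_roi(path.read_bytes(), default_label=path.stem)


def read_roi_zip(path: str | Path) -> list[Roi]:
    """All .roi entries of a zip, in archive order."""
    rois = []
    with zipfile.ZipFile(path) as zf:
        for info in zf.infolist():
            if not info.filename.lower().endswith(".roi"):
                continue
            stem = Path(info.filename).stem
            rois.append(decode_roi(zf.read(info), default_label=stem))
    return rois


def write_roi_file(roi: Roi, path: str | Path) -> None:
    Path(path).write_bytes(encode_roi(roi))


def write_roi_zip(rois: Iterable[Roi], path: str | Path) -> None:
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for roi in rois:
            zf.writestr(f"{roi.label}.roi", encode_roi(roi))
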