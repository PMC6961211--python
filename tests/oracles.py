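"""Independent brute-force reference implementations used only for testing.

These deliberately share no code with the package: maxima are found by
enumerating candidate plateaus and examining sub-level sets, the median
filter by explicit per-pixel neighbourhood sorts, and polygon membership by
a scalar even-odd crossing test.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_S8 = np.ones((3, 3), dtype=bool)


def prominence_maxima_oracle(raster, prominence):
    """Accepted maxima as a set of frozensets of (x, y) plateau pixels.

    A candidate is an 8-connected component of equal value with no strictly
    greater neighbour.  A candidate of value v is accepted iff the connected
    component of {raster >= v - prominence} containing it (a) holds no pixel
    above v and (b) holds no other value-v candidate whose smallest (y, x)
    pixel is lexicographically smaller.  Constant images have no maxima.
    """
    a = np.asarray(raster, dtype=float)
    if a.size == 0 or a.max() == a.min():
        return set()
    # enumerate candidate plateaus
    candidates = []  # (value, boolean component, representative (y, x))
    for v in np.unique(a):
        labels, n = ndimage.label(a == v, structure=_S8)
        for i in range(1, n + 1):
            comp = labels == i
            ring = ndimage.binary_dilation(comp, structure=_S8) & ~comp
            if not (a[ring] > v).any():
                ys, xs = np.nonzero(comp)
                rep = min(zip(ys.tolist(), xs.tolist()))
                candidates.append((float(v), comp, rep))

    accepted = set()
    for v, comp, rep in candidates:
        sub = a >= v - prominence
        labels, _ = ndimage.label(sub, structure=_S8)
        ys, xs = np.nonzero(comp)
        region = labels == labels[ys[0], xs[0]]
        if (a[region] > v).any():
            continue  # a higher summit is reachable without a deep-enough dip
        rivals = [
            r for v2, c2, r in candidates
            if v2 == v and (region & c2).any()
        ]
        if rep == min(rivals):
            accepted.add(frozenset(zip(xs.tolist(), ys.tolist())))
    return accepted


def median_filter_oracle(raster, radius):
    """Direct per-pixel sort with the dx^2+dy^2 <= r^2+1 kernel and
    edge-replicated borders."""
    a = np.asarray(raster, dtype=float)
    if radius == 0:
        return a.copy()
    r = int(np.ceil(radius))
    offsets = [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dx * dx + dy * dy <= radius * radius + 1
    ]
    h, w = a.shape
    out = np.empty_like(a)
    for y in range(h):
        for x in range(w):
            vals = [
                a[min(max(y + dy, 0), h - 1), min(max(x + dx, 0), w - 1)]
                for dy, dx in offsets
            ]
            out[y, x] = float(np.median(vals))
    return out


def point_in_polygon_evenodd(px, py, polygon):
    """Scalar even-odd crossing test (the rasterization reference)."""
    inside = False
    n = len(polygon)
    for i in range(n):
        xa, ya = polygon[i]
        xb, yb = polygon[(i + 1) % n]
        if (ya <= py) != (yb <= py):
            xi = xa + (py - ya) * (xb - xa) / (yb - ya)
            if px < xi:
                inside = not inside
    return inside
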