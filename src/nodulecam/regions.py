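"""Extraction of the red salient regions from rendered heatmaps.

The rendered heatmap is converted to HSV; pixels inside a red hue window
(wrapping around 0°) with sufficient saturation and value are kept; the
surviving mask is split into 8-connected components, small ones are
dropped, and each component's outer boundary is traced as a closed chain of
pixel centers (Moore neighbourhood tracing) — the contour convention the
shape descriptors are defined on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as _skcolor
from skimage import measure as _skmeasure


@dataclass
class RedThresholds:
    """HSV capture window: hue in [0, h_lo] ∪ [360−h_hi, 360), S ≥ s_min,
    V ≥ v_min.  Defaults select only the red band of the heatmap colormap."""

    h_lo: float = 20.0
    h_hi: float = 20.0
    s_min: float = 0.5
    v_min: float = 0.3


@dataclass
class ExtractedRegion:
    mask: np.ndarray  # binary, full image shape
    contour: np.ndarray  # (n, 2) ordered closed chain of (row, col) pixel centers
    area_pixels: int
    source: str = ""


def rgb_to_hsv(image: np.ndarray) -> np.ndarray:
    """RGB (channels in [0,1]) → HSV with H in degrees [0, 360), S,V in [0,1]."""
    img = np.asarray(image, dtype=float)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("RGB channels must lie in [0, 1]")
    hsv = _skcolor.rgb2hsv(img)
    hsv[..., 0] = (hsv[..., 0] * 360.0) % 360.0
    return hsv


def capture_red(hsv: np.ndarray, thresholds: RedThresholds = RedThresholds()) -> np.ndarray:
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    hue_ok = (h <= thresholds.h_lo) | (h >= 360.0 - thresholds.h_hi)
    return hue_ok & (s >= thresholds.s_min) & (v >= thresholds.v_min)


# Moore neighbourhood in clockwise order starting from west
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered outer-boundary pixel centers of a single connected component
    (Moore-neighbour tracing with Jacob's stopping criterion).  The returned
    polygon is closed implicitly (last vertex connects back to the first)."""
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise ValueError("empty mask has no boundary")
    # start: topmost, then leftmost foreground pixel; its west neighbour is
    # background by construction
    y0 = ys.min()
    x0 = xs[ys == y0].min()
    start = (int(y0), int(x0))
    h, w = mask.shape

    def fg(p):
        return 0 <= p[0] < h and 0 <= p[1] < w and mask[p]

    contour = [start]
    cur = start
    backtrack = (start[0], start[1] - 1)  # arrived scanning from the west
    first_move = None
    limit = 4 * mask.size + 8
    while True:
        i = _MOORE.index((backtrack[0] - cur[0], backtrack[1] - cur[1]))
        nxt = None
        for k in range(1, 9):
            off = _MOORE[(i + k) % 8]
            cand = (cur[0] + off[0], cur[1] + off[1])
            if fg(cand):
                nxt = cand
                backtrack = (cur[0] + _MOORE[(i + k - 1) % 8][0],
                             cur[1] + _MOORE[(i + k - 1) % 8][1])
                break
        if nxt is None:  # isolated pixel
            break
        if first_move is None:
            first_move = nxt
        elif cur == start and nxt == first_move:
            break  # Jacob's criterion: left the start the same way twice
        contour.append(nxt)
        cur = nxt
        if len(contour) > limit:  # cannot trigger for a valid component
            raise RuntimeError("boundary tracing failed to terminate")
    if len(contour) > 1 and contour[-1] == contour[0]:
        contour.pop()  # closure is implicit
    return np.asarray(contour, dtype=int)


def extract_regions(mask: np.ndarray, min_area: int = 50, largest_only: bool = False,
                    source: str = "") -> list[ExtractedRegion]:
    """8-connected components of ``mask`` with area ≥ ``min_area``, outer
    boundaries traced, ordered by descending area.  An empty list is a valid
    result (no red region captured)."""
    labelled = _skmeasure.label(np.asarray(mask, dtype=bool), connectivity=2)
    regions = []
    for lab in range(1, labelled.max() + 1):
        comp = labelled == lab
        area = int(comp.sum())
        if area < min_area:
            continue
        contour = trace_boundary(comp)
        regions.append(ExtractedRegion(mask=comp, contour=contour,
                                       area_pixels=area, source=source))
    regions.sort(key=lambda r: -r.area_pixels)
    if largest_only and regions:
        regions = regions[:1]
    return regions


def overlay_contours(original: np.ndarray, regions: list[ExtractedRegion],
                     rgb=(0.0, 1.0, 0.0)) -> np.ndarray:
    """Draw region contours on an RGB copy of ``original``; the input image
    is never modified."""
    img = np.asarray(original, dtype=float)
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=2)
    out = img.copy()
    for region in regions:
        rr, cc = region.contour[:, 0], region.contour[:, 1]
        out[rr, cc] = rgb
    return out
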