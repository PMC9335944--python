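"""Convexity/compactness descriptors of extracted regions.

Three dimensionless descriptors quantify boundary complexity:

* form parameter (circularity)    F  = 4*pi*S / P**2   (1 for an ideal circle)
* area convexity (solidity)       S / S_ch             (<= 1)
* perimeter convexity             P / P_ch             (>= 1)

with S the region area, P its boundary length, and S_ch / P_ch the area and
perimeter of the region's convex hull.  Smaller F and area convexity, and
larger perimeter convexity, all indicate a more complex (irregular) edge.

Digital-measurement conventions (they matter, F is quadratic in P):

* S is the pixel count; S_ch is the pixel count of the rasterized convex
  hull (the standard "solidity" denominator), which guarantees S <= S_ch.
* P is measured on the traced pixel-center boundary chain.  The default
  estimator applies the Vossepoel–Smeulders corner correction
  (0.980·N_straight + 1.406·N_diagonal − 0.091·N_corner), accurate to ~1%
  on smooth digitized shapes; the naive chain length (straight steps 1,
  diagonal steps √2) overestimates smooth perimeters by ~5% and is kept as
  ``estimator="chain"``.  P_ch uses the same estimator on the traced hull
  boundary so the ratio is estimator-consistent (a convex digital region
  gives exactly 1).
* residual digitization bias is absorbed by a documented tolerance
  DELTA_DISCRETE on the ideal bounds (F <= 1, perimeter convexity >= 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skimage.morphology import convex_hull_image

from .regions import ExtractedRegion, trace_boundary

#: digitization slack on the ideal bounds (F <= 1 + delta, P/P_ch >= 1 - delta)
DELTA_DISCRETE = 0.1


@dataclass
class ShapeFeatures:
    S: float  # region area, pixels^2
    P: float  # region boundary length, pixels
    S_ch: float  # convex hull area
    P_ch: float  # convex hull perimeter
    F: float  # form parameter 4*pi*S/P^2
    area_convexity: float  # S / S_ch
    perimeter_convexity: float  # P / P_ch


def region_area(mask: np.ndarray) -> int:
    """Region area as a pixel count."""
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty mask has no area")
    return area


def chain_lengths(contour: np.ndarray):
    """Per-step lengths (1 or sqrt(2)) of a closed pixel-center chain."""
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or len(contour) < 3:
        raise ValueError("a closed contour needs at least 3 vertices")
    d = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    return np.hypot(d[:, 0], d[:, 1]), d


def region_perimeter(contour: np.ndarray, estimator: str = "corrected") -> float:
    """Boundary length of a closed pixel-center chain.

    ``"chain"``: polygonal arc length (unit steps count 1, diagonals √2).
    ``"corrected"`` (default): Vossepoel–Smeulders corner-corrected chain,
    which removes most of the ~5% staircase overestimate on smooth shapes.
    """
    steps, d = chain_lengths(contour)
    if estimator == "chain":
        return float(steps.sum())
    if estimator == "corrected":
        diag = steps > 1.2
        n_d = int(diag.sum())
        n_s = int(len(steps) - n_d)
        dirs = [tuple(v) for v in d.astype(int)]
        n_c = sum(1 for a, b in zip(dirs, dirs[1:] + dirs[:1]) if a != b)
        return float(0.980 * n_s + 1.406 * n_d - 0.091 * n_c)
    raise ValueError(f"unknown perimeter estimator {estimator!r}")


def convex_hull(points: np.ndarray):
    """Convex hull of a point set: ordered hull vertices, shoelace area,
    Euclidean perimeter.  Raises on collinear/degenerate input."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("convex hull needs at least 3 points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError("degenerate (collinear) point set has no 2-D hull") from exc
    vertices = pts[hull.vertices]
    return vertices, float(hull.volume), float(hull.area)  # 2-D: volume=area, area=perimeter


def form_parameter(S: float, P: float) -> float:
    """F = 4*pi*S / P^2; smaller means a more complex edge."""
    if S <= 0 or P <= 0:
        raise ValueError("area and perimeter must be positive")
    return float(4.0 * np.pi * S / P**2)


def area_convexity(S: float, S_ch: float) -> float:
    if S_ch <= 0:
        raise ValueError("degenerate hull area")
    return float(S / S_ch)


def perimeter_convexity(P: float, P_ch: float) -> float:
    if P_ch <= 0:
        raise ValueError("degenerate hull perimeter")
    return float(P / P_ch)


def compute_shape_features(region: ExtractedRegion | np.ndarray,
                           estimator: str = "corrected") -> ShapeFeatures:
    """All three descriptors for one region (an ExtractedRegion or a bare
    binary mask, whose boundary is then traced here)."""
    if isinstance(region, ExtractedRegion):
        mask, contour = region.mask, region.contour
    else:
        mask = np.asarray(region, dtype=bool)
        contour = trace_boundary(mask)
    S = region_area(mask)
    P = region_perimeter(contour, estimator=estimator)
    hull_img = convex_hull_image(mask)
    S_ch = float(hull_img.sum())
    P_ch = region_perimeter(trace_boundary(hull_img), estimator=estimator)
    return ShapeFeatures(
        S=float(S), P=P, S_ch=S_ch, P_ch=P_ch,
        F=form_parameter(S, P),
        area_convexity=area_convexity(S, S_ch),
        perimeter_convexity=perimeter_convexity(P, P_ch),
    )


FEATURE_COLUMNS = ["image_id", "label", "S", "P", "S_ch", "P_ch",
                   "F", "area_convexity", "perimeter_convexity"]


def feature_table(regions, labels, image_ids=None, estimator: str = "corrected") -> pd.DataFrame:
    """One row per region (image id, label, S, P, S_ch, P_ch, F, area
    convexity, perimeter convexity).  Per-region failures are logged as a
    warning and rowed with NaN descriptors, never fatal."""
    regions = list(regions)
    labels = list(labels)
    if image_ids is None:
        image_ids = [getattr(r, "source", "") or f"region_{i}" for i, r in enumerate(regions)]
    rows = []
    for rid, region, label in zip(image_ids, regions, labels):
        row = {"image_id": rid, "label": label}
        try:
            if region is None:
                raise ValueError("no region extracted")
            feats = compute_shape_features(region, estimator=estimator)
            row.update(asdict(feats))
        except Exception as exc:
            warnings.warn(f"shape features failed for {rid}: {exc}", stacklevel=2)
            row.update({k: np.nan for k in FEATURE_COLUMNS[2:]})
        rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
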