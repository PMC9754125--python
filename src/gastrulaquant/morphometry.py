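"""Embryo-scale morphometry: outline, elliptic deformation, invagination.

The embryo outline is segmented from a 2-D view by Otsu thresholding
(largest connected component, holes filled).  The elliptic deformation is
the L/W ratio of the ellipse with the same second-order moments as the mask;
"percent deformation" is ``100 * (L/W - 1)``, so a 1.30 ratio reads as a 30 %
deformation.  The invagination depth ``d`` is the convex-hull deficiency of
the outline -- the maximal distance from the hull boundary to the mask
boundary across the dent -- normalised by the equivalent-area diameter ``D``.
An embryo is classified as gastrulating when ``d/D`` strictly exceeds the
threshold (default 0.18).

Depth is measured on a mid-plane section (a thin slab around the central z
plane) rather than on a full axial projection: the silhouette of a
crater-shaped invagination is occluded by the surrounding shell, so only a
section through the dent shows its true depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi, sqrt

import numpy as np
import shapely
from shapely.geometry import Polygon
from scipy import ndimage as ndi
from skimage.measure import find_contours, label, regionprops

from .catalog import otsu_threshold
from .io import ImageStack

__all__ = [
    "EmbryoShape",
    "InvaginationMeasurement",
    "MorphometryConfig",
    "midplane_section",
    "segment_embryo",
    "elliptic_ratio",
    "percent_deformation",
    "measure_invagination",
    "apex_area_in_zone",
]


@dataclass(frozen=True)
class MorphometryConfig:
    gastrulation_threshold: float = 0.18
    zone_side_um: float = 50.0
    smoothing_sigma_px: float = 1.0
    section_planes: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.gastrulation_threshold < 1.0):
            raise ValueError("gastrulation_threshold must lie in (0, 1)")
        if self.zone_side_um <= 0:
            raise ValueError("zone_side_um must be > 0")


@dataclass
class EmbryoShape:
    mask: np.ndarray
    centroid: tuple[float, float]            # (x, y) px
    L_um: float
    W_um: float
    D_um: float
    convex_hull: Polygon
    pixel_size_um: float

    def __post_init__(self) -> None:
        if not (self.L_um >= self.W_um > 0 and self.D_um > 0):
            raise ValueError("invalid shape: need L >= W > 0 and D > 0")


@dataclass(frozen=True)
class InvaginationMeasurement:
    d_um: float
    d_over_D: float
    gastrulating: bool
    dent_apex: tuple[float, float]           # (x, y) px


def midplane_section(stack: ImageStack, channel: str = "junction", n_planes: int = 1) -> np.ndarray:
    """Mean of the central z planes -- the section view the depth measurement
    runs on (the dent axis is assumed to lie in the imaging plane)."""
    img = stack.channel(channel)
    z0 = img.shape[0] // 2
    half = max(0, n_planes // 2)
    lo, hi = max(0, z0 - half), min(img.shape[0], z0 + half + 1)
    return img[lo:hi].mean(axis=0)


def segment_embryo(projection: np.ndarray, pixel_size_um: float = 1.0,
                   config: MorphometryConfig | None = None) -> EmbryoShape:
    """Otsu-threshold a 2-D view, keep the largest component, fill holes, and
    fit the moment-equivalent ellipse.

    ``D`` is the diameter of the circle with the mask's area (stable on dented
    shapes, equal to 2r on disks).
    """
    config = config or MorphometryConfig()
    img = np.asarray(projection, dtype=float)
    # candidate background cuts: the 2-class Otsu threshold, plus the lowest
    # 3-class cut for sections where background / shell / junction form three
    # populations and the 2-class split lands inside the tissue
    candidates = [otsu_threshold(img)]   # raises on a degenerate histogram
    try:
        from skimage.filters import threshold_multiotsu

        candidates.append(float(threshold_multiotsu(img, classes=3, nbins=256)[0]))
    except ValueError:
        pass
    best = None
    for t in candidates:
        fg = img > t
        if not fg.any():
            continue
        lab = label(fg)
        largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
        cand = ndi.binary_fill_holes(lab == largest)
        border = np.concatenate([cand[0], cand[-1], cand[:, 0], cand[:, -1]])
        # the specimen sits away from the field edge: reject cuts whose
        # largest component is background percolation along the border
        key = (border.mean() < 0.1, int(cand.sum()))
        if best is None or key > best[0]:
            best = (key, cand)
    if best is None:
        raise ValueError("no embryo: empty foreground after thresholding")
    mask = best[1]
    if config.smoothing_sigma_px > 0:
        mask = ndi.gaussian_filter(mask.astype(float), config.smoothing_sigma_px) > 0.5
        mask = ndi.binary_fill_holes(mask)
    props = regionprops(mask.astype(np.uint8))[0]
    L = props.axis_major_length * pixel_size_um
    W = props.axis_minor_length * pixel_size_um
    D = 2.0 * sqrt(mask.sum() / pi) * pixel_size_um
    cy, cx = props.centroid
    contour = _outline(mask)
    hull = shapely.MultiPoint(contour).convex_hull
    return EmbryoShape(
        mask=mask, centroid=(cx, cy), L_um=L, W_um=max(W, 1e-9), D_um=D,
        convex_hull=hull, pixel_size_um=pixel_size_um,
    )


def _outline(mask: np.ndarray) -> np.ndarray:
    """Sub-pixel outer contour of the mask as (x, y) points."""
    contours = find_contours(mask.astype(float), 0.5)
    longest = max(contours, key=len)
    return longest[:, ::-1]  # (row, col) -> (x, y)


def elliptic_ratio(shape: EmbryoShape) -> float:
    """Major/minor axis ratio L/W (>= 1)."""
    return shape.L_um / shape.W_um


def percent_deformation(shape: EmbryoShape) -> float:
    """100 * (L/W - 1): 1.05 reads as a 5 % deformation, 1.30 as 30 %."""
    return 100.0 * (elliptic_ratio(shape) - 1.0)


def measure_invagination(shape: EmbryoShape, config: MorphometryConfig | None = None) -> InvaginationMeasurement:
    """Depth of the deepest dent as convex-hull deficiency, normalised by D.

    Classification uses a strict inequality: d/D exactly at the threshold is
    not gastrulating.
    """
    config = config or MorphometryConfig()
    contour = _outline(shape.mask)
    pts = shapely.points(contour)
    dist = shapely.distance(pts, shape.convex_hull.exterior)
    i = int(np.argmax(dist))
    d_px = float(dist[i])
    d_um = d_px * shape.pixel_size_um
    d_over_D = d_um / shape.D_um
    return InvaginationMeasurement(
        d_um=d_um,
        d_over_D=d_over_D,
        gastrulating=bool(d_over_D > config.gastrulation_threshold),
        dent_apex=(float(contour[i, 0]), float(contour[i, 1])),
    )


def apex_area_in_zone(catalog, zone_center_px: tuple[float, float],
                      config: MorphometryConfig | None = None) -> float:
    """Average apical cell area in a square zone: zone area divided by the
    number of catalog cells whose centroid falls inside the zone.

    ``zone_center_px`` is (x, y) in pixels; the zone side is
    ``config.zone_side_um`` (default the 50 x 50 um^2 sampling window).
    """
    config = config or MorphometryConfig()
    side_px = config.zone_side_um / catalog.pixel_size_um
    x0, y0 = zone_center_px
    n = 0
    for rec in catalog.records:
        cx, cy = rec.centroid
        if abs(cx - x0) <= side_px / 2 and abs(cy - y0) <= side_px / 2:
            n += 1
    if n == 0:
        raise ValueError("empty zone: no cell centroids inside")
    return config.zone_side_um**2 / n
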