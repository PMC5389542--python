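"""Single-cell identification from phase-contrast masks.

Particles are 8-connected components selected by area, split by a
distance-transform watershed, filtered on shape (ellipse-fit aspect
ratio, minimum Feret width, border contact, saturation), and written
into an integer "count mask" used to harvest per-cell pixel arrays from
the fluorescence channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from skimage import measure
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

__all__ = [
    "CellROI",
    "FilterCriteria",
    "CellPixels",
    "find_particles",
    "watershed_split",
    "filter_cells",
    "build_count_mask",
    "cell_pixels",
    "rois_from_count_mask",
    "min_feret_diameter",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class CellROI:
    """One segmented cell.

    ``pixels`` is an ``(area, 2)`` array of (row, col) coordinates in
    raster order.  ``aspect_ratio`` is the major/minor axis ratio of the
    image-moment ellipse fit; ``min_feret`` the minimum caliper width of
    the pixel-square convex hull.
    """

    id: int
    pixels: np.ndarray
    aspect_ratio: float
    min_feret: float
    touches_border: bool

    @property
    def area(self) -> int:
        return len(self.pixels)


@dataclass(frozen=True)
class FilterCriteria:
    """Cell-selection criteria for :func:`filter_cells`.

    The aspect-ratio test is strict (> threshold) and the MinFeret test
    is strict (< maximum), matching the selection semantics of the
    analysis this reproduces.  ``saturation_level`` of ``None`` infers
    the bit-depth maximum from each channel image's dtype.
    """

    area_range: tuple[float, float] = (100.0, 1200.0)
    ar_threshold: float = 2.01
    max_min_feret: float = 20.0
    exclude_saturated: bool = True
    exclude_border: bool = True
    saturation_level: float | None = None

    def __post_init__(self) -> None:
        if self.area_range[0] >= self.area_range[1]:
            raise ValueError("area_range must have min < max")
        if self.ar_threshold <= 1:
            raise ValueError("ar_threshold must be > 1")


def min_feret_diameter(pixels: np.ndarray) -> float:
    """Minimum caliper (Feret) diameter of a pixel set.

    Pixels are treated as unit squares (corners at +/- 0.5); the width
    is the minimum over convex-hull edges of the maximal perpendicular
    extent (rotating calipers).
    """
    pixels = np.asarray(pixels, dtype=float)
    if len(pixels) == 0:
        raise ValueError("empty pixel set")
    corners = (
        pixels[:, None, :]
        + np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])[None, :, :]
    ).reshape(-1, 2)
    try:
        hull = ConvexHull(corners)
    except QhullError as exc:  # pragma: no cover - corners are never collinear
        raise ValueError(f"degenerate pixel set: {exc}") from exc
    pts = corners[hull.vertices]
    edges = np.roll(pts, -1, axis=0) - pts
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    normals = np.stack([-edges[:, 1], edges[:, 0]], axis=1) / lengths[:, None]
    # width per edge: max perpendicular distance of any hull point
    proj = np.abs((pts[None, :, :] - pts[:, None, :]) @ normals[:, :, None])[:, :, 0]
    return float(proj.max(axis=1).min())


def _roi_from_coords(cid: int, coords: np.ndarray, shape: tuple[int, int]) -> CellROI:
    # moments-based ellipse fit via regionprops on a local crop
    r0, c0 = coords.min(axis=0)
    r1, c1 = coords.max(axis=0) + 1
    local = np.zeros((r1 - r0, c1 - c0), dtype=np.uint8)
    local[coords[:, 0] - r0, coords[:, 1] - c0] = 1
    props = measure.regionprops(local)[0]
    minor = props.axis_minor_length
    ar = float(props.axis_major_length / minor) if minor > 0 else float("inf")
    touches = bool(
        (coords[:, 0] == 0).any()
        or (coords[:, 1] == 0).any()
        or (coords[:, 0] == shape[0] - 1).any()
        or (coords[:, 1] == shape[1] - 1).any()
    )
    return CellROI(
        id=cid,
        pixels=coords,
        aspect_ratio=ar,
        min_feret=min_feret_diameter(coords),
        touches_border=touches,
    )


def find_particles(
    mask: np.ndarray, area_range: tuple[float, float] = (1.0, np.inf)
) -> list[CellROI]:
    """8-connected components with area inside ``area_range`` (inclusive).

    Components are ordered by the raster position of their first pixel
    and given ids 1..n in that order.
    """
    mask = np.asarray(mask, dtype=bool)
    lbl, n = ndi.label(mask, structure=_STRUCT8)
    rois: list[CellROI] = []
    if n == 0:
        return rois
    lo, hi = area_range
    next_id = 1
    # ndi.label assigns labels in raster order of first pixel already
    for region in measure.regionprops(lbl):
        coords = region.coords  # raster order within the region
        if lo <= len(coords) <= hi:
            rois.append(_roi_from_coords(next_id, coords, mask.shape))
            next_id += 1
    return rois


def watershed_split(
    mask: np.ndarray,
    peak_tolerance: float = 1.0,
    merge_saddle_ratio: float = 0.8,
) -> np.ndarray:
    """Separate touching objects with a distance-transform watershed.

    Markers are the regional maxima of the (lightly smoothed) Euclidean
    distance transform after an h-maxima transform of height
    ``peak_tolerance``.  Candidate one-pixel separation lines are kept
    only where the distance at the saddle is shallow relative to the
    adjacent basin maxima (ratio below ``merge_saddle_ratio``); deep
    saddles are spurious maxima of an elongated ridge and the basins are
    merged back, so objects with a single real distance maximum come
    back unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    dist = ndi.distance_transform_edt(mask)
    smooth = ndi.gaussian_filter(dist, 1.0)
    markers, n = ndi.label(h_maxima(smooth, peak_tolerance), structure=_STRUCT8)
    if n <= 1:
        return mask.copy()
    lbl = watershed(-smooth, markers, mask=mask, watershed_line=True)
    lines = mask & (lbl == 0)
    if not lines.any():
        return mask.copy()

    n_lbl = int(lbl.max())
    basin_max = ndi.maximum(dist, lbl, index=np.arange(1, n_lbl + 1))
    parent = list(range(n_lbl + 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    h, w = mask.shape
    line_coords = np.argwhere(lines)
    saddles: dict[tuple[int, int], float] = {}
    neighborhoods = []
    for y, x in line_coords:
        neigh = set(
            lbl[max(0, y - 1) : y + 2, max(0, x - 1) : x + 2].ravel().tolist()
        ) - {0}
        neighborhoods.append(neigh)
        for a in neigh:
            for b in neigh:
                if a < b:
                    key = (a, b)
                    saddles[key] = max(saddles.get(key, 0.0), float(dist[y, x]))
    for (a, b), saddle in saddles.items():
        if saddle >= merge_saddle_ratio * min(basin_max[a - 1], basin_max[b - 1]):
            parent[find(a)] = find(b)

    out = mask.copy()
    for (y, x), neigh in zip(line_coords, neighborhoods):
        if len({find(l) for l in neigh}) >= 2:
            out[y, x] = False
    return out


def filter_cells(
    rois: list[CellROI],
    criteria: FilterCriteria = FilterCriteria(),
    channel_images: Mapping[str, np.ndarray] | None = None,
) -> list[CellROI]:
    """Apply the stringent cell selection; logs per-criterion rejections.

    A cell is kept when its area lies in ``area_range``, its aspect
    ratio strictly exceeds ``ar_threshold``, its MinFeret is strictly
    below ``max_min_feret``, it contains no saturated pixel in any
    listed channel, and (optionally) it does not touch the image border.
    """
    rejected = {"area": 0, "aspect_ratio": 0, "min_feret": 0, "saturated": 0, "border": 0}
    kept: list[CellROI] = []
    for roi in rois:
        if not (criteria.area_range[0] <= roi.area <= criteria.area_range[1]):
            rejected["area"] += 1
            continue
        if not roi.aspect_ratio > criteria.ar_threshold:
            rejected["aspect_ratio"] += 1
            continue
        if not roi.min_feret < criteria.max_min_feret:
            rejected["min_feret"] += 1
            continue
        if criteria.exclude_saturated and channel_images:
            saturated = False
            for img in channel_images.values():
                level = criteria.saturation_level
                if level is None:
                    level = (
                        np.iinfo(img.dtype).max
                        if np.issubdtype(img.dtype, np.integer)
                        else np.inf
                    )
                if (img[roi.pixels[:, 0], roi.pixels[:, 1]] >= level).any():
                    saturated = True
                    break
            if saturated:
                rejected["saturated"] += 1
                continue
        if criteria.exclude_border and roi.touches_border:
            rejected["border"] += 1
            continue
        kept.append(roi)
    logger.info(
        "filter_cells: kept %d of %d; rejected %s", len(kept), len(rois), rejected
    )
    return kept


def build_count_mask(rois: list[CellROI], shape: tuple[int, int]) -> np.ndarray:
    """Label image with each ROI's pixels set to its id (0 elsewhere)."""
    out = np.zeros(shape, dtype=np.int32)
    for roi in rois:
        rr, cc = roi.pixels[:, 0], roi.pixels[:, 1]
        if (out[rr, cc] != 0).any():
            raise ValueError(f"ROI {roi.id} overlaps a previously placed ROI")
        out[rr, cc] = roi.id
    return out


@dataclass(frozen=True)
class CellPixels:
    """Per-cell intensity values with their (row, col) coordinates."""

    values: np.ndarray
    coords: np.ndarray


def cell_pixels(count_mask: np.ndarray, image: np.ndarray) -> dict[int, CellPixels]:
    """Harvest per-cell intensity arrays, raster-ordered, coords retained."""
    count_mask = np.asarray(count_mask)
    image = np.asarray(image)
    if count_mask.shape != image.shape:
        raise ValueError(
            f"shape mismatch: count_mask {count_mask.shape} vs image {image.shape}"
        )
    out: dict[int, CellPixels] = {}
    for region in measure.regionprops(count_mask.astype(np.int32)):
        coords = region.coords
        out[region.label] = CellPixels(
            values=image[coords[:, 0], coords[:, 1]], coords=coords
        )
    return out


def rois_from_count_mask(count_mask: np.ndarray) -> list[CellROI]:
    """Rebuild CellROI objects (with shape descriptors) from a count mask."""
    count_mask = np.asarray(count_mask).astype(np.int32)
    rois = []
    for region in measure.regionprops(count_mask):
        rois.append(_roi_from_coords(region.label, region.coords, count_mask.shape))
    return rois
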