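"""Per-cell localization statistics.

The central quantity is the threshold overlap score (TOS): per cell,
the top fraction F_T of pixels by intensity is selected in the signal
channel and in the reference (DAPI) channel; the observed fractional
overlap of the two selections is rescaled against the uniform-null
expectation (which equals F_T) onto [-1, +1]:

* TOS = 0 when observed equals expected,
* TOS = observed/expected - 1 when observed < expected (minimum -1),
* TOS = (observed/expected - 1)/(1/expected - 1) when observed > expected
  (maximum +1).

The membrane variant discards the outermost pixel layer of a cell (edge
effect), terms the next layer the "membrane", and scores the overlap of
the top-F_T selection of the eroded cell with that layer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_FT",
    "ThresholdSelection",
    "OverlapResult",
    "MembraneLayers",
    "SignalRecord",
    "CellTooThinError",
    "normalize_global",
    "normalize_cellular",
    "select_top_fraction",
    "observed_overlap",
    "expected_overlap",
    "tos",
    "score_cell",
    "membrane_layers",
    "membrane_tos",
    "signal_to_background",
    "axial_profile",
]

DEFAULT_FT = 0.1

_STRUCT3 = np.ones((3, 3), dtype=bool)


class CellTooThinError(ValueError):
    """Cell has no interior left after two erosions; excluded from
    membrane analysis."""


@dataclass(frozen=True)
class ThresholdSelection:
    """The top-F_T pixels of one cell in one channel."""

    f_t: float
    selected: np.ndarray  # (n_sel, 2) coordinates
    n_cell_pixels: int

    @property
    def n_selected(self) -> int:
        return len(self.selected)


@dataclass(frozen=True)
class OverlapResult:
    cell_id: int | None
    observed: float
    expected: float
    tos: float


@dataclass(frozen=True)
class MembraneLayers:
    """Partition of a cell into outermost (discarded), membrane and
    interior pixel layers via successive 3x3 erosions."""

    discarded_edge: np.ndarray
    membrane: np.ndarray
    interior: np.ndarray


@dataclass(frozen=True)
class SignalRecord:
    cell_id: int
    sb_ratio: float
    included: bool


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def n_selected(n_pixels: int, f_t: float) -> int:
    """Number of pixels selected at fraction f_t: round half up, floor 1."""
    return max(1, _round_half_up(f_t * n_pixels))


def normalize_global(images: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Rescale all images to [0, 1] by one shared (low, high) pair."""
    if len(images) == 0:
        raise ValueError("need at least one image")
    low = min(float(np.min(im)) for im in images)
    high = max(float(np.max(im)) for im in images)
    if high == low:
        raise ValueError("global high equals global low; cannot normalize")
    return [(np.asarray(im, dtype=float) - low) / (high - low) for im in images]


def normalize_cellular(
    cells: Mapping[int, np.ndarray],
) -> tuple[dict[int, np.ndarray], set[int]]:
    """Rescale each cell's values independently to [0, 1].

    Constant cells cannot be scaled; they get 0.5 everywhere and their
    ids are returned in the flagged set (visualization only -- callers
    must exclude them from statistics).
    """
    out: dict[int, np.ndarray] = {}
    flagged: set[int] = set()
    for cid, values in cells.items():
        values = np.asarray(values, dtype=float)
        lo, hi = float(values.min()), float(values.max())
        if hi == lo:
            out[cid] = np.full_like(values, 0.5)
            flagged.add(cid)
        else:
            out[cid] = (values - lo) / (hi - lo)
    return out, flagged


def select_top_fraction(
    values: np.ndarray, coords: np.ndarray, f_t: float = DEFAULT_FT
) -> ThresholdSelection:
    """Select the max(1, round(f_t * n)) highest-intensity pixels.

    Ties at the cutoff are broken deterministically by raster order
    (smaller row, then smaller col, first).
    """
    values = np.asarray(values)
    coords = np.asarray(coords)
    if not 0 < f_t < 1:
        raise ValueError("f_t must be in (0, 1)")
    if len(values) == 0:
        raise ValueError("empty value array")
    if len(values) != len(coords):
        raise ValueError("values and coords lengths differ")
    n_sel = n_selected(len(values), f_t)
    order = np.lexsort((coords[:, 1], coords[:, 0], -values.astype(float)))
    return ThresholdSelection(
        f_t=f_t, selected=coords[order[:n_sel]], n_cell_pixels=len(values)
    )


def _coord_set(coords: np.ndarray) -> set[tuple[int, int]]:
    return {(int(r), int(c)) for r, c in coords}


def observed_overlap(
    sel_signal: ThresholdSelection, sel_ref: ThresholdSelection
) -> float:
    """|signal selection AND reference selection| / |reference selection|."""
    if sel_ref.n_selected == 0:
        raise ValueError("reference selection is empty")
    inter = _coord_set(sel_signal.selected) & _coord_set(sel_ref.selected)
    return len(inter) / sel_ref.n_selected


def expected_overlap(f_t: float = DEFAULT_FT) -> float:
    """Null expectation of the observed overlap for a uniformly
    distributed signal: exactly F_T."""
    if not 0 < f_t < 1:
        raise ValueError("f_t must be in (0, 1)")
    return f_t


def tos(observed: float, expected: float) -> float:
    """Threshold overlap score on [-1, +1]."""
    if not 0 < expected < 1:
        raise ValueError("expected overlap must be in (0, 1)")
    if not 0 <= observed <= 1:
        raise ValueError("observed overlap must be in [0, 1]")
    if observed == expected:
        return 0.0
    if observed < expected:
        return observed / expected - 1.0
    return (observed / expected - 1.0) / (1.0 / expected - 1.0)


def score_cell(
    signal_values: np.ndarray,
    ref_values: np.ndarray,
    coords: np.ndarray,
    f_t: float = DEFAULT_FT,
    cell_id: int | None = None,
) -> OverlapResult:
    """Nucleoid-style TOS of one cell: signal vs reference top fractions."""
    sel_sig = select_top_fraction(signal_values, coords, f_t)
    sel_ref = select_top_fraction(ref_values, coords, f_t)
    obs = observed_overlap(sel_sig, sel_ref)
    exp = expected_overlap(f_t)
    return OverlapResult(cell_id=cell_id, observed=obs, expected=exp, tos=tos(obs, exp))


def membrane_layers(coords: np.ndarray) -> MembraneLayers:
    """Partition a cell into edge / membrane / interior pixel layers.

    Raises :class:`CellTooThinError` when two 3x3 erosions leave no
    interior (the cell is excluded from membrane analysis).
    """
    coords = np.asarray(coords)
    if len(coords) == 0:
        raise ValueError("empty pixel set")
    r0, c0 = coords.min(axis=0)
    shape = coords.max(axis=0) - (r0, c0) + 5  # pad 2 on each side
    local = np.zeros(shape, dtype=bool)
    local[coords[:, 0] - r0 + 2, coords[:, 1] - c0 + 2] = True
    e1 = ndi.binary_erosion(local, structure=_STRUCT3)
    e2 = ndi.binary_erosion(e1, structure=_STRUCT3)
    if not e2.any():
        raise CellTooThinError(
            "no interior remains after two erosions; cell too thin for "
            "membrane analysis"
        )
    offset = np.array([r0 - 2, c0 - 2])
    return MembraneLayers(
        discarded_edge=np.argwhere(local & ~e1) + offset,
        membrane=np.argwhere(e1 & ~e2) + offset,
        interior=np.argwhere(e2) + offset,
    )


def membrane_tos(
    values: np.ndarray,
    coords: np.ndarray,
    f_t: float = DEFAULT_FT,
    rank_over: str = "eroded",
    cell_id: int | None = None,
) -> OverlapResult:
    """TOS of a cell's top-F_T pixels against its membrane layer.

    With ``rank_over="eroded"`` (default) the outermost layer is removed
    before ranking and the null expectation is the membrane share of the
    eroded cell; with ``rank_over="whole"`` ranking covers the whole
    cell and the expectation is the membrane share of the whole cell.
    """
    if rank_over not in ("eroded", "whole"):
        raise ValueError("rank_over must be 'eroded' or 'whole'")
    values = np.asarray(values)
    coords = np.asarray(coords)
    layers = membrane_layers(coords)
    membrane_set = _coord_set(layers.membrane)
    if rank_over == "eroded":
        eroded_set = membrane_set | _coord_set(layers.interior)
        keep = np.array([(int(r), int(c)) in eroded_set for r, c in coords])
        pool_values, pool_coords = values[keep], coords[keep]
    else:
        pool_values, pool_coords = values, coords
    sel = select_top_fraction(pool_values, pool_coords, f_t)
    obs = len(_coord_set(sel.selected) & membrane_set) / sel.n_selected
    exp = len(membrane_set) / len(pool_values)
    return OverlapResult(cell_id=cell_id, observed=obs, expected=exp, tos=tos(obs, exp))


def signal_to_background(
    image: np.ndarray, count_mask: np.ndarray, cutoff: float = 1.3
) -> list[SignalRecord]:
    """Per-cell signal-to-background ratio with inclusion flags.

    Background is the mean intensity over unlabeled pixels of the image;
    cells strictly below the cutoff are flagged for exclusion (equality
    is retained).
    """
    image = np.asarray(image, dtype=float)
    count_mask = np.asarray(count_mask)
    if image.shape != count_mask.shape:
        raise ValueError("image and count_mask shapes differ")
    bg_pixels = image[count_mask == 0]
    if bg_pixels.size == 0:
        raise ValueError("count mask has no unlabeled background pixels")
    background = float(bg_pixels.mean())
    if background <= 0:
        raise ValueError("background mean must be positive")
    records = []
    for cid in np.unique(count_mask):
        if cid == 0:
            continue
        ratio = float(image[count_mask == cid].mean()) / background
        records.append(
            SignalRecord(cell_id=int(cid), sb_ratio=ratio, included=ratio >= cutoff)
        )
    return records


def axial_profile(
    values: np.ndarray, coords: np.ndarray, n_bins: int = 10
) -> np.ndarray:
    """Mean intensity in equal-width bins along the cell's long axis.

    The long axis is the principal component of the pixel coordinates.
    Returns an array of ``n_bins`` bin means (NaN for empty bins); used
    to visualize the edge effect at the cell poles.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least two pixels")
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    t = centered @ vt[0]
    edges = np.linspace(t.min(), t.max() + 1e-9, n_bins + 1)
    idx = np.clip(np.digitize(t, edges) - 1, 0, n_bins - 1)
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            out[b] = values[sel].mean()
    return out
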