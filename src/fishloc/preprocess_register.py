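"""Image preparation: background subtraction, thresholding, alignment.

Coordinates are (row, col), 0-based.  A translation ``Offset(dy, dx)``
moves image content by +dy rows and +dx cols.  Alignment is restricted
to integer translations found by exhaustive search of foreground
overlap within a configurable maximum shift.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from skimage import filters
from skimage.restoration import rolling_ball

__all__ = [
    "Offset",
    "subtract_background",
    "threshold_isodata",
    "estimate_offset",
    "apply_offset",
]


class Offset(NamedTuple):
    """Integer translation in pixels: +dy rows down, +dx cols right."""

    dy: int
    dx: int

    def __neg__(self) -> "Offset":
        return Offset(-self.dy, -self.dx)


def subtract_background(image: np.ndarray, ball_radius: int = 50) -> np.ndarray:
    """Rolling-ball background subtraction, clipped at zero.

    Returns a new float array; the input image is not modified.
    """
    if ball_radius < 1:
        raise ValueError("ball_radius must be >= 1")
    if ball_radius > min(image.shape):
        raise ValueError(
            f"ball_radius {ball_radius} exceeds image extent {min(image.shape)}"
        )
    background = rolling_ball(image.astype(float), radius=ball_radius)
    return np.clip(image.astype(float) - background, 0.0, None)


def threshold_isodata(image: np.ndarray, polarity: str = "bright") -> np.ndarray:
    """Binary mask from the iterative-intermeans (ISODATA) threshold.

    polarity "bright" selects pixels strictly above the threshold
    (fluorescence); "dark" selects pixels strictly below it (cells in
    phase contrast).
    """
    image = np.asarray(image)
    if image.size == 0 or np.ptp(image) == 0:
        raise ValueError("cannot threshold a constant image")
    if polarity not in ("bright", "dark"):
        raise ValueError(f"polarity must be 'bright' or 'dark', got {polarity!r}")
    t = filters.threshold_isodata(image)
    return image > t if polarity == "bright" else image < t


def _overlap_count(ref: np.ndarray, moving: np.ndarray, dy: int, dx: int) -> int:
    """Count ref[y, x] & moving[y + dy, x + dx] over valid indices."""
    h, w = ref.shape
    ys0, ys1 = max(0, -dy), h - max(0, dy)
    xs0, xs1 = max(0, -dx), w - max(0, dx)
    if ys1 <= ys0 or xs1 <= xs0:
        return 0
    r = ref[ys0:ys1, xs0:xs1]
    m = moving[ys0 + dy : ys1 + dy, xs0 + dx : xs1 + dx]
    return int(np.count_nonzero(r & m))


def estimate_offset(
    mask_ref: np.ndarray, mask_moving: np.ndarray, max_shift: int = 10
) -> Offset:
    """Displacement of ``mask_moving``'s foreground relative to ``mask_ref``.

    Exhaustive search over all integer shifts within +/- ``max_shift``,
    maximizing the foreground overlap count.  Ties are broken by the
    smallest |dy| + |dx|, then the smallest dy, then the smallest dx.
    Correct the moving image by applying the negated offset.
    """
    mask_ref = np.asarray(mask_ref, dtype=bool)
    mask_moving = np.asarray(mask_moving, dtype=bool)
    if mask_ref.shape != mask_moving.shape:
        raise ValueError("masks must share a shape")
    if not mask_ref.any() or not mask_moving.any():
        raise ValueError("masks must be nonempty")
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")

    best_key = None
    best = Offset(0, 0)
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            ov = _overlap_count(mask_ref, mask_moving, dy, dx)
            key = (-ov, abs(dy) + abs(dx), dy, dx)
            if best_key is None or key < best_key:
                best_key = key
                best = Offset(dy, dx)
    return best


def apply_offset(image: np.ndarray, offset: Offset, fill: float = 0) -> np.ndarray:
    """Translate image content by ``offset``; vacated pixels take ``fill``."""
    dy, dx = int(offset[0]), int(offset[1])
    h, w = image.shape
    if abs(dy) >= h or abs(dx) >= w:
        raise ValueError(f"offset {offset} out of bounds for image {image.shape}")
    out = np.full_like(image, fill)
    ys0, ys1 = max(0, -dy), h - max(0, dy)
    xs0, xs1 = max(0, -dx), w - max(0, dx)
    out[ys0 + dy : ys1 + dy, xs0 + dx : xs1 + dx] = image[ys0:ys1, xs0:xs1]
    return out
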