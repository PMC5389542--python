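"""Synthetic multi-channel microscopy scenes with known ground truth.

Cells are rendered as spherocylinders (a rectangle capped by two
semicircles) on a flat background.  Each cell carries an interior
"nucleoid" region -- an axis-aligned scaled copy of the cell shape whose
area is a configurable fraction of the cell area -- plus the two polar
cap regions.  Fluorescence channels place signal density on these
regions according to a localization mode, then apply point-spread blur,
background, noise, an optional inter-channel translation, and
quantization.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
from scipy import ndimage as ndi

__all__ = [
    "LOCALIZATION_MODES",
    "CHANNELS",
    "CellTruth",
    "SceneTruth",
    "RenderParams",
    "make_geometry",
    "render_channels",
    "write_scene",
    "read_scene",
]

LOCALIZATION_MODES = (
    "uniform",
    "nucleoid_excluded",
    "nucleoid_enriched",
    "membrane",
    "polar",
)

CHANNELS = ("phase", "dapi", "rna1", "rna2", "gfp")

_STRUCT3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class CellTruth:
    """Ground truth for a single simulated cell.

    Pixel coordinate arrays are ``(n, 2)`` integer ``(row, col)`` arrays
    in raster order, in the frame of the full image.
    """

    id: int
    center: tuple[float, float]
    angle: float
    length: float
    width: float
    cell_px: np.ndarray
    nucleoid_px: np.ndarray
    pole_px: tuple[np.ndarray, np.ndarray]

    @property
    def area(self) -> int:
        return len(self.cell_px)

    @property
    def nucleoid_area(self) -> int:
        return len(self.nucleoid_px)


@dataclass(frozen=True)
class SceneTruth:
    """Geometry ground truth for one scene."""

    image_shape: tuple[int, int]
    cells: tuple[CellTruth, ...]
    nucleoid_area_fraction: float
    seed: int

    def cell_label_image(self) -> np.ndarray:
        return _label_image(self.image_shape, [(c.id, c.cell_px) for c in self.cells])

    def nucleoid_label_image(self) -> np.ndarray:
        return _label_image(
            self.image_shape, [(c.id, c.nucleoid_px) for c in self.cells]
        )


@dataclass(frozen=True)
class RenderParams:
    """Optical / camera model used by :func:`render_channels`.

    noise_model is one of ``None``/``"none"``, ``"gaussian"``,
    ``"poisson"`` or ``"poisson+gaussian"``.  Poisson noise treats pixel
    intensities as expected photon counts; Gaussian noise adds read
    noise of ``gaussian_sd``.  ``channel_offset`` is an integer
    translation applied to every fluorescence channel (never to phase),
    emulating chromatic/stage misalignment.
    """

    psf_sigma: float = 1.0
    background_level: float = 100.0
    noise_model: str | None = "poisson"
    gaussian_sd: float = 5.0
    channel_offset: tuple[int, int] = (0, 0)
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        model = self.noise_model or "none"
        if model not in ("none", "gaussian", "poisson", "poisson+gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1


def _label_image(shape, id_px_pairs) -> np.ndarray:
    out = np.zeros(shape, dtype=np.int32)
    for cid, px in id_px_pairs:
        if len(px):
            out[px[:, 0], px[:, 1]] = cid
    return out


def _mask_from_px(px: np.ndarray, shape) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    if len(px):
        m[px[:, 0], px[:, 1]] = True
    return m


def _spherocylinder_fields(window_shape, center, angle, half_seg):
    """Axial (t) and perpendicular (p) coordinates for a local window."""
    yy, xx = np.mgrid[0 : window_shape[0], 0 : window_shape[1]]
    dy = yy - center[0]
    dx = xx - center[1]
    ay, ax = np.sin(angle), np.cos(angle)
    t = dy * ay + dx * ax
    p = dy * ax - dx * ay
    tc = np.clip(t, -half_seg, half_seg)
    dist = np.hypot(t - tc, p)
    return t, dist


def make_geometry(
    n_cells: int,
    cell_length_range: tuple[float, float] = (40.0, 50.0),
    cell_width_range: tuple[float, float] = (12.0, 15.0),
    nucleoid_area_fraction: float = 0.5,
    image_shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    min_gap: int = 3,
    max_tries_per_cell: int = 500,
) -> SceneTruth:
    """Place ``n_cells`` non-overlapping spherocylinders at random.

    Cells are placed by rejection sampling: random length, width,
    orientation and center, rejected when the candidate (dilated by
    ``min_gap``) would overlap an existing cell or leave the image.
    Every cell's true length/width ratio exceeds 2.01 so the full
    population survives the downstream rod-shape filter.  The nucleoid
    is a concentric copy of the cell scaled by sqrt(nucleoid area
    fraction) in both dimensions.

    Raises
    ------
    RuntimeError
        If a cell cannot be placed within ``max_tries_per_cell``
        attempts (cell density too high for the image).
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if not (0 < nucleoid_area_fraction < 1):
        raise ValueError("nucleoid_area_fraction must be in (0, 1)")
    for lo, hi in (cell_length_range, cell_width_range):
        if lo <= 0 or hi < lo:
            raise ValueError("ranges must be positive with min <= max")

    rng = np.random.default_rng(seed)
    h_img, w_img = image_shape
    occupied = np.zeros(image_shape, dtype=bool)
    cells: list[CellTruth] = []
    s = float(np.sqrt(nucleoid_area_fraction))

    for i in range(n_cells):
        placed = False
        for _ in range(max_tries_per_cell):
            length = rng.uniform(*cell_length_range)
            width = rng.uniform(*cell_width_range)
            if length / width <= 2.01:
                continue
            angle = rng.uniform(0.0, np.pi)
            halo = length / 2 + min_gap + 2
            if 2 * halo >= min(h_img, w_img):
                raise RuntimeError(
                    f"cell of length {length:.1f} px cannot fit in image "
                    f"{image_shape} with gap {min_gap}"
                )
            cy = rng.uniform(halo, h_img - halo)
            cx = rng.uniform(halo, w_img - halo)

            r0, c0 = int(np.floor(cy - halo)), int(np.floor(cx - halo))
            r1, c1 = int(np.ceil(cy + halo)) + 1, int(np.ceil(cx + halo)) + 1
            r0, c0 = max(r0, 0), max(c0, 0)
            r1, c1 = min(r1, h_img), min(c1, w_img)
            local_center = (cy - r0, cx - c0)
            half_seg = (length - width) / 2
            radius = width / 2

            t, dist = _spherocylinder_fields((r1 - r0, c1 - c0), local_center, angle, half_seg)
            cell = dist <= radius
            dilated = dist <= radius + min_gap
            if (occupied[r0:r1, c0:c1] & dilated).any():
                continue
            occupied[r0:r1, c0:c1] |= cell

            tc = np.clip(t, -s * half_seg, s * half_seg)
            # perpendicular part recomputed against the scaled segment
            _, dist_n = _spherocylinder_fields(
                (r1 - r0, c1 - c0), local_center, angle, s * half_seg
            )
            nucleoid = dist_n <= s * radius
            pole_a = cell & (t > half_seg)
            pole_b = cell & (t < -half_seg)

            offset = np.array([r0, c0])

            def _px(mask):
                return np.argwhere(mask) + offset

            cells.append(
                CellTruth(
                    id=i + 1,
                    center=(float(cy), float(cx)),
                    angle=float(angle),
                    length=float(length),
                    width=float(width),
                    cell_px=_px(cell),
                    nucleoid_px=_px(nucleoid),
                    pole_px=(_px(pole_a), _px(pole_b)),
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"failed to place cell {i + 1} of {n_cells} after "
                f"{max_tries_per_cell} attempts; cell density too high for "
                f"image shape {image_shape}"
            )

    return SceneTruth(
        image_shape=tuple(image_shape),
        cells=tuple(cells),
        nucleoid_area_fraction=float(nucleoid_area_fraction),
        seed=int(seed),
    )


def _interior_boundary_px(cell_px: np.ndarray, shape) -> np.ndarray:
    """One-pixel-interior boundary layer: erode1(cell) minus erode2(cell)."""
    m = _mask_from_px(cell_px, shape)
    e1 = ndi.binary_erosion(m, structure=_STRUCT3)
    e2 = ndi.binary_erosion(e1, structure=_STRUCT3)
    return np.argwhere(e1 & ~e2)


def _shift_with_fill(img: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    out = np.full_like(img, fill)
    h, w = img.shape
    ys0, ys1 = max(0, -dy), h - max(0, dy)
    xs0, xs1 = max(0, -dx), w - max(0, dx)
    if ys1 > ys0 and xs1 > xs0:
        out[ys0 + dy : ys1 + dy, xs0 + dx : xs1 + dx] = img[ys0:ys1, xs0:xs1]
    return out


def render_channels(
    truth: SceneTruth,
    mode: str,
    signal_level: float = 1000.0,
    params: RenderParams = RenderParams(),
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Render phase / DAPI / RNA channels for one scene.

    The phase channel is a cartoon sufficient for segmentation: bright
    background (background + signal) with dark cells (background).  The
    DAPI channel puts signal density on the nucleoid; the RNA channel
    follows ``mode``.  Fluorescence channels (not phase) receive the
    configured inter-channel offset.
    """
    if mode not in LOCALIZATION_MODES:
        raise ValueError(f"unknown localization mode {mode!r}")
    if signal_level <= params.background_level:
        raise ValueError("signal_level must exceed background_level")

    shape = truth.image_shape
    cell_mask = truth.cell_label_image() > 0
    nuc_mask = truth.nucleoid_label_image() > 0

    rna = np.zeros(shape, dtype=float)
    if mode == "uniform":
        rna[cell_mask] = signal_level
    elif mode == "nucleoid_excluded":
        rna[cell_mask & ~nuc_mask] = signal_level
    elif mode == "nucleoid_enriched":
        rna[nuc_mask] = signal_level
    elif mode == "membrane":
        for cell in truth.cells:
            px = _interior_boundary_px(cell.cell_px, shape)
            if len(px):
                rna[px[:, 0], px[:, 1]] = signal_level
    elif mode == "polar":
        for cell in truth.cells:
            for px in cell.pole_px:
                if len(px):
                    rna[px[:, 0], px[:, 1]] = signal_level

    dapi = np.zeros(shape, dtype=float)
    dapi[nuc_mask] = signal_level

    phase = np.full(shape, params.background_level + signal_level, dtype=float)
    phase[cell_mask] = params.background_level

    bg = params.background_level
    channels = {"phase": phase, "dapi": dapi + bg, "rna1": rna + bg}

    rng = np.random.default_rng(seed)
    model = params.noise_model or "none"
    dy, dx = params.channel_offset
    out: dict[str, np.ndarray] = {}
    for name, img in channels.items():
        if params.psf_sigma > 0:
            img = ndi.gaussian_filter(img, params.psf_sigma)
        if name != "phase" and (dy or dx):
            img = _shift_with_fill(img, dy, dx, bg)
        if model in ("poisson", "poisson+gaussian"):
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if model in ("gaussian", "poisson+gaussian"):
            img = img + rng.normal(0.0, params.gaussian_sd, size=img.shape)
        img = np.clip(np.rint(img), 0, params.max_value)
        dtype = np.uint8 if params.bit_depth == 8 else np.uint16
        out[name] = img.astype(dtype)
    return out


def write_scene(
    truth: SceneTruth, images: Mapping[str, np.ndarray], directory: str | Path
) -> dict[str, Path]:
    """Write channel TIFFs plus a ground-truth sidecar.

    The sidecar is a pair of label-image TIFFs (cell and nucleoid masks,
    integer cell ids) and a JSON record of the scene parameters, which
    together allow a lossless reload via :func:`read_scene`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    try:
        for name, img in images.items():
            p = directory / f"{name}.tif"
            tifffile.imwrite(p, img)
            paths[name] = p
        p = directory / "cell_labels.tif"
        tifffile.imwrite(p, truth.cell_label_image().astype(np.uint16))
        paths["cell_labels"] = p
        p = directory / "nucleoid_labels.tif"
        tifffile.imwrite(p, truth.nucleoid_label_image().astype(np.uint16))
        paths["nucleoid_labels"] = p
        record = {
            "image_shape": list(truth.image_shape),
            "nucleoid_area_fraction": truth.nucleoid_area_fraction,
            "seed": truth.seed,
            "cells": [
                {
                    "id": c.id,
                    "center": list(c.center),
                    "angle": c.angle,
                    "length": c.length,
                    "width": c.width,
                }
                for c in truth.cells
            ],
        }
        p = directory / "scene.json"
        p.write_text(json.dumps(record, indent=1, sort_keys=True))
        paths["scene"] = p
    except OSError as exc:
        raise OSError(f"failed writing scene to {directory}: {exc}") from exc
    return paths


def read_scene(directory: str | Path) -> tuple[SceneTruth, dict[str, np.ndarray]]:
    """Reload a scene written by :func:`write_scene`."""
    directory = Path(directory)
    record = json.loads((directory / "scene.json").read_text())
    cell_lbl = tifffile.imread(directory / "cell_labels.tif").astype(np.int32)
    nuc_lbl = tifffile.imread(directory / "nucleoid_labels.tif").astype(np.int32)
    shape = tuple(record["image_shape"])

    cells = []
    for rec in record["cells"]:
        cid = rec["id"]
        cell_px = np.argwhere(cell_lbl == cid)
        nucleoid_px = np.argwhere(nuc_lbl == cid)
        # pole masks are a deterministic function of the stored geometry
        cy, cx = rec["center"]
        ay, ax = np.sin(rec["angle"]), np.cos(rec["angle"])
        half_seg = (rec["length"] - rec["width"]) / 2
        t = (cell_px[:, 0] - cy) * ay + (cell_px[:, 1] - cx) * ax
        pole_a = cell_px[t > half_seg]
        pole_b = cell_px[t < -half_seg]
        cells.append(
            CellTruth(
                id=cid,
                center=(float(cy), float(cx)),
                angle=float(rec["angle"]),
                length=float(rec["length"]),
                width=float(rec["width"]),
                cell_px=cell_px,
                nucleoid_px=nucleoid_px,
                pole_px=(pole_a, pole_b),
            )
        )
    truth = SceneTruth(
        image_shape=shape,
        cells=tuple(cells),
        nucleoid_area_fraction=float(record["nucleoid_area_fraction"]),
        seed=int(record["seed"]),
    )
    images = {}
    for p in sorted(directory.glob("*.tif")):
        if p.stem in ("cell_labels", "nucleoid_labels"):
            continue
        images[p.stem] = tifffile.imread(p)
    return truth, images
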