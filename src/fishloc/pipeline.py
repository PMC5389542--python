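"""End-to-end glue: scene images -> per-cell localization scores.

Chains thresholding, registration, watershed segmentation, the shape
filters, count-mask construction and the TOS metrics into one call,
mirroring how the stages are meant to be composed on real image sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import localization_metrics as lm
from . import preprocess_register as pr
from . import segment_cells as sc
from .scene_sim import RenderParams, SceneTruth, make_geometry, render_channels

logger = logging.getLogger(__name__)

__all__ = ["simulate_scene", "score_images", "simulate_and_score"]


def simulate_scene(
    n_cells: int,
    mode: str,
    seed: int,
    image_shape: tuple[int, int] | None = None,
    params: RenderParams = RenderParams(),
    signal_level: float = 1000.0,
    nucleoid_area_fraction: float = 0.5,
) -> tuple[SceneTruth, dict[str, np.ndarray]]:
    """Generate geometry and render channels in one step.

    When ``image_shape`` is omitted it is scaled with the cell count so
    that rejection-sampled placement stays fast.
    """
    if image_shape is None:
        side = int(max(300, np.ceil(np.sqrt(n_cells * 110 * 110 / 0.45))))
        image_shape = (side, side)
    truth = make_geometry(
        n_cells,
        nucleoid_area_fraction=nucleoid_area_fraction,
        image_shape=image_shape,
        seed=seed,
    )
    images = render_channels(
        truth, mode, signal_level=signal_level, params=params, seed=seed + 1
    )
    return truth, images


def score_images(
    images: dict[str, np.ndarray],
    signal_channel: str = "rna1",
    ref_channel: str = "dapi",
    f_t: float = lm.DEFAULT_FT,
    criteria: sc.FilterCriteria | None = None,
    register: bool = True,
    max_shift: int = 10,
    sb_cutoff: float = 1.3,
    membrane_rank_over: str = "eroded",
) -> pd.DataFrame:
    """Run the full analysis on a channel dict containing ``phase``.

    Returns one row per retained cell with columns: cell_id, area,
    sb_ratio, included, observed, expected, tos, membrane_observed,
    membrane_expected, membrane_tos (NaN when the cell is too thin for
    membrane analysis).
    """
    if criteria is None:
        criteria = sc.FilterCriteria()
    phase = images["phase"]
    phase_mask = pr.threshold_isodata(phase, polarity="dark")

    aligned: dict[str, np.ndarray] = {}
    for name, img in images.items():
        if name == "phase":
            continue
        if register:
            fluo_mask = pr.threshold_isodata(img, polarity="bright")
            offset = pr.estimate_offset(phase_mask, fluo_mask, max_shift=max_shift)
            if offset != (0, 0):
                logger.info("channel %s offset %s; correcting", name, offset)
                img = pr.apply_offset(img, -offset, fill=int(np.median(img)))
        aligned[name] = img

    split = sc.watershed_split(phase_mask)
    rois = sc.find_particles(split, criteria.area_range)
    kept = sc.filter_cells(rois, criteria, channel_images=aligned)
    count_mask = sc.build_count_mask(kept, phase.shape)

    signal_px = sc.cell_pixels(count_mask, aligned[signal_channel])
    ref_px = sc.cell_pixels(count_mask, aligned[ref_channel])
    sb = {
        r.cell_id: r
        for r in lm.signal_to_background(
            aligned[signal_channel], count_mask, cutoff=sb_cutoff
        )
    }

    rows = []
    for roi in kept:
        cid = roi.id
        res = lm.score_cell(
            signal_px[cid].values, ref_px[cid].values, signal_px[cid].coords,
            f_t=f_t, cell_id=cid,
        )
        try:
            mem = lm.membrane_tos(
                signal_px[cid].values,
                signal_px[cid].coords,
                f_t=f_t,
                rank_over=membrane_rank_over,
                cell_id=cid,
            )
            mem_obs, mem_exp, mem_tos = mem.observed, mem.expected, mem.tos
        except lm.CellTooThinError:
            logger.info("cell %d too thin for membrane analysis", cid)
            mem_obs = mem_exp = mem_tos = np.nan
        rows.append(
            {
                "cell_id": cid,
                "area": roi.area,
                "sb_ratio": sb[cid].sb_ratio,
                "included": sb[cid].included,
                "observed": res.observed,
                "expected": res.expected,
                "tos": res.tos,
                "membrane_observed": mem_obs,
                "membrane_expected": mem_exp,
                "membrane_tos": mem_tos,
            }
        )
    return pd.DataFrame(rows)


def simulate_and_score(
    n_cells: int,
    mode: str,
    seed: int,
    params: RenderParams = RenderParams(),
    signal_level: float = 1000.0,
    f_t: float = lm.DEFAULT_FT,
    **score_kwargs,
) -> pd.DataFrame:
    """Simulate a scene and push it through the whole pipeline."""
    _, images = simulate_scene(
        n_cells, mode, seed, params=params, signal_level=signal_level
    )
    return score_images(images, f_t=f_t, **score_kwargs)
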