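"""Layer assignment and per-slice normalization to reference-layer cells.

Absolute EPSP amplitudes vary strongly across slices with opsin expression
level, so within each slice every cell's amplitude (and slope) is divided by
the mean over the reference-layer excitatory cells recorded in the same
slice: L4 for VPM stimulation, L5A for POm.  Reference cells are included in
their own denominator, which pins the pooled reference-group normalized mean
to exactly 1.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    REFERENCE_LAYER,
    CellMeta,
    DatasetError,
    EPSPFeatures,
    LayerBoundaries,
    NormalizedFeatures,
)

logger = logging.getLogger(__name__)

#: Layers carrying recordings in the analyzed datasets; L1 is assignable
#: from depth but flagged as not analyzed downstream.
ANALYZED_LAYERS = ("L2", "L3", "L4", "L5A", "L5B", "L6")


def assign_layer(depth_um: float, boundaries: LayerBoundaries) -> str:
    """Layer whose half-open depth band [lo, hi) contains ``depth_um``."""
    for layer, lo, hi in boundaries.bands:
        if lo <= depth_um < hi:
            return layer
    raise DatasetError(
        f"depth {depth_um} um outside covered range "
        f"[0, {boundaries.max_depth_um}) um"
    )


def resolve_layer(
    meta: CellMeta, boundaries: Optional[LayerBoundaries] = None
) -> str:
    """Cell's layer: the explicit label when present, else depth-derived."""
    if meta.layer is not None:
        return meta.layer
    if boundaries is None:
        raise DatasetError(
            f"cell {meta.cell_id}: no layer label and no boundaries given"
        )
    return assign_layer(meta.depth_um, boundaries)


def normalize_slice(
    features: Sequence[EPSPFeatures],
    metas: Sequence[CellMeta],
    pathway: str,
    boundaries: Optional[LayerBoundaries] = None,
) -> list[NormalizedFeatures]:
    """Per-slice normalization of amplitude and slope.

    For each slice, the denominator is the mean over control-condition
    excitatory cells in the pathway's reference layer (amplitude over cells
    with a defined amplitude, slope over cells with a defined slope).
    Slices without any reference cell are excluded with a logged warning.
    """
    ref_layer = REFERENCE_LAYER[pathway]
    meta_by_id = {m.cell_id: m for m in metas}
    feats = [f for f in features if f.cell_id in meta_by_id]

    by_slice: dict[str, list[EPSPFeatures]] = {}
    for f in feats:
        by_slice.setdefault(meta_by_id[f.cell_id].slice_id, []).append(f)

    out: list[NormalizedFeatures] = []
    for slice_id in sorted(by_slice):
        rows = by_slice[slice_id]
        ref_rows = [
            f
            for f in rows
            if (m := meta_by_id[f.cell_id]).cell_type == "EXC"
            and m.condition == "control"
            and resolve_layer(m, boundaries) == ref_layer
        ]
        if not ref_rows:
            logger.warning(
                "slice %s: no reference-layer EXC cell, slice excluded",
                slice_id,
            )
            continue
        ref_amp = float(np.mean([f.peak_amp_mV for f in ref_rows]))
        ref_slopes = [
            f.slope_mV_per_ms for f in ref_rows if f.slope_mV_per_ms is not None
        ]
        ref_slope = float(np.mean(ref_slopes)) if ref_slopes else None
        if ref_amp <= 0:
            logger.warning(
                "slice %s: non-positive reference amplitude mean, slice excluded",
                slice_id,
            )
            continue
        for f in rows:
            norm_slope = None
            if f.slope_mV_per_ms is not None and ref_slope and ref_slope > 0:
                norm_slope = f.slope_mV_per_ms / ref_slope
            out.append(
                NormalizedFeatures(
                    cell_id=f.cell_id,
                    norm_amp=f.peak_amp_mV / ref_amp,
                    norm_slope=norm_slope,
                    ref_layer=ref_layer,
                    ref_amp_mean_mV=ref_amp,
                    ref_slope_mean=ref_slope,
                )
            )
    return out


def pool_groups(
    normalized: Sequence[NormalizedFeatures],
    metas: Sequence[CellMeta],
    boundaries: Optional[LayerBoundaries] = None,
) -> pd.DataFrame:
    """Pool normalized features across slices by (pathway, cell_type, layer).

    Cells with a missing slope count towards the amplitude n but not the
    slope n, so the two sample sizes may differ within a group.
    """
    meta_by_id = {m.cell_id: m for m in metas}
    recs = []
    for f in normalized:
        m = meta_by_id[f.cell_id]
        recs.append(
            {
                "pathway": m.pathway,
                "cell_type": m.cell_type,
                "layer": resolve_layer(m, boundaries),
                "norm_amp": f.norm_amp,
                "norm_slope": f.norm_slope,
            }
        )
    df = pd.DataFrame(recs)
    if df.empty:
        return pd.DataFrame(
            columns=[
                "pathway", "cell_type", "layer",
                "amp_mean", "amp_sd", "amp_median", "amp_n",
                "slope_mean", "slope_sd", "slope_median", "slope_n",
            ]
        )
    rows = []
    for (pw, ct, layer), grp in df.groupby(
        ["pathway", "cell_type", "layer"], sort=True
    ):
        amps = grp["norm_amp"].dropna()
        slopes = grp["norm_slope"].dropna()
        rows.append(
            {
                "pathway": pw,
                "cell_type": ct,
                "layer": layer,
                "amp_mean": amps.mean(),
                "amp_sd": amps.std(ddof=1) if len(amps) > 1 else np.nan,
                "amp_median": amps.median(),
                "amp_n": int(len(amps)),
                "slope_mean": slopes.mean() if len(slopes) else np.nan,
                "slope_sd": slopes.std(ddof=1) if len(slopes) > 1 else np.nan,
                "slope_median": slopes.median() if len(slopes) else np.nan,
                "slope_n": int(len(slopes)),
            }
        )
    return pd.DataFrame(rows)
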