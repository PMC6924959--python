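"""End products: summary tables, depth profiles, grand-average time courses,
and the end-to-end pipeline runner.

Tables are emitted as machine-readable CSV plus a plain-text rendering in
the "mean ± SD *median* n" cell format used for published group matrices.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .features import FeatureParams, average_trace, compute_baseline, extract_all
from .grouping import ANALYZED_LAYERS, normalize_slice, pool_groups, resolve_layer
from .io import features_to_frame, metas_to_frame, normalized_to_frame
from .stats import compare_reference_layer
from .types import CELL_TYPES, CellMeta, LayerBoundaries, SweepSet

logger = logging.getLogger(__name__)


def cell_table(
    features,
    normalized,
    metas: Sequence[CellMeta],
    boundaries: Optional[LayerBoundaries] = None,
) -> pd.DataFrame:
    """Merge metadata, absolute and normalized features into one table."""
    fdf = features_to_frame(features)
    ndf = normalized_to_frame(normalized)
    mdf = metas_to_frame(metas)
    mdf["layer"] = [
        resolve_layer(m, boundaries) if (m.layer or boundaries) else None
        for m in metas
    ]
    out = mdf.merge(fdf, on="cell_id", how="left").merge(
        ndf, on="cell_id", how="left"
    )
    return out


def _fmt_median(m) -> str:
    # two decimals for values near 1, two significant digits for small ones
    return f"{m:.2f}" if abs(m) >= 0.095 else f"{m:.2g}"


def _cell_text(mean, sd, median, n) -> str:
    if n == 0:
        return ""
    if n == 1 or pd.isna(sd):
        return f"*{_fmt_median(median)}* n = {n}"
    return f"{mean:.2f} ± {sd:.2f} *{_fmt_median(median)}* n = {n}"


def build_summary_table(
    pooled: pd.DataFrame, feature: str = "amplitude"
) -> tuple[pd.DataFrame, str]:
    """Layer x cell-type matrix of normalized-feature summaries.

    Returns (numeric long-form table, plain-text rendering).  ``feature``
    is "amplitude" or "slope".  Cells with no recordings stay blank.
    """
    prefix = {"amplitude": "amp", "slope": "slope"}[feature]
    cols = [f"{prefix}_mean", f"{prefix}_sd", f"{prefix}_median", f"{prefix}_n"]
    lines = ["\t".join([feature] + list(CELL_TYPES))]
    layers = [l for l in ANALYZED_LAYERS]
    text_rows = {}
    for layer in layers:
        cells = []
        for ct in CELL_TYPES:
            row = pooled[
                (pooled["layer"] == layer) & (pooled["cell_type"] == ct)
            ]
            if row.empty or int(row.iloc[0][f"{prefix}_n"]) == 0:
                cells.append("")
                continue
            r = row.iloc[0]
            cells.append(
                _cell_text(
                    r[f"{prefix}_mean"], r[f"{prefix}_sd"],
                    r[f"{prefix}_median"], int(r[f"{prefix}_n"]),
                )
            )
        text_rows[layer] = cells
        lines.append("\t".join([layer] + cells))
    table = pooled[["pathway", "cell_type", "layer"] + cols].copy()
    return table, "\n".join(lines)


def build_depth_profile(
    table: pd.DataFrame,
    boundaries: LayerBoundaries,
    value_col: str = "peak_amp_mV",
) -> pd.DataFrame:
    """Sorted (depth_um, value) scatter records with layer-band annotations.

    Cells without a recorded depth are omitted; the number omitted is
    logged.
    """
    df = table[["cell_id", "depth_um", value_col]].copy()
    n_missing = int(df["depth_um"].isna().sum())
    if n_missing:
        logger.info("depth profile: %d cells without depth omitted", n_missing)
    df = df.dropna(subset=["depth_um"]).sort_values("depth_um", kind="stable")
    df["layer_band"] = [
        next(
            (name for name, lo, hi in boundaries.bands if lo <= d < hi), None
        )
        for d in df["depth_um"]
    ]
    return df.reset_index(drop=True)


def build_grand_average_timecourse(
    sweepsets: Sequence[SweepSet],
    metas: Sequence[CellMeta],
    normalize_per_cell: bool = False,
    window_ms: tuple[float, float] = (-50.0, 150.0),
) -> pd.DataFrame:
    """Baseline-subtracted mean EPSP time course per cell type.

    Each cell contributes its trial-averaged, baseline-subtracted trace
    (optionally peak-normalized); traces are pooled across layers within
    cell type.  All cells must share a sampling rate.  Returns a long-form
    frame with columns ``t_ms``, ``cell_type``, ``mean_mV``, ``n_cells``.
    """
    meta_by_id = {m.cell_id: m for m in metas}
    rates = {s.sampling_rate for s in sweepsets}
    if len(rates) != 1:
        raise ValueError("grand average requires a common sampling rate")
    fs = rates.pop()
    lo, hi = window_ms
    n_lo = int(np.floor(lo / 1000.0 * fs))
    n_hi = int(np.ceil(hi / 1000.0 * fs))
    # clamp the window to the extent available in every cell's trace
    for s in sweepsets:
        onset_idx = int(round(s.stim_onset * fs))
        n_lo = max(n_lo, -onset_idx)
        n_hi = min(n_hi, s.n_samples - 1 - onset_idx)
    if n_hi <= n_lo:
        raise ValueError(f"window {window_ms} ms has no overlap with traces")
    t_grid = np.arange(n_lo, n_hi + 1) / fs * 1000.0

    per_type: dict[str, list[np.ndarray]] = {}
    for s in sweepsets:
        t_ms, mean = average_trace(s)
        base = compute_baseline(t_ms, mean)
        onset_idx = int(round(s.stim_onset * fs))
        i0, i1 = onset_idx + n_lo, onset_idx + n_hi + 1
        trace = mean[i0:i1] - base
        if normalize_per_cell:
            peak = trace.max()
            if peak > 0:
                trace = trace / peak
        per_type.setdefault(meta_by_id[s.cell_id].cell_type, []).append(trace)

    rows = []
    for ct in sorted(per_type):
        stack = np.vstack(per_type[ct])
        grand = stack.mean(axis=0)
        rows.append(
            pd.DataFrame(
                {
                    "t_ms": t_grid,
                    "cell_type": ct,
                    "mean_mV": grand,
                    "n_cells": stack.shape[0],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    out_dir: str | Path,
    sweepsets: Sequence[SweepSet],
    metas: Sequence[CellMeta],
    pathway: str,
    boundaries: Optional[LayerBoundaries] = None,
    feature_params: Optional[FeatureParams] = None,
    input_paths: Sequence[str | Path] = (),
    seed: Optional[int] = None,
    plots: bool = False,
) -> dict:
    """Run extraction -> normalization -> pooling -> tables -> statistics.

    Writes features.csv, normalized.csv, pooled.csv, table_{amplitude,
    slope}.{csv,txt}, pvalues.csv, depth_profile.csv, timecourse.csv and a
    manifest.json recording input hashes, parameters, exclusions and the
    package version.  Returns the manifest dict.
    """
    from .params import DEFAULT_BOUNDARIES

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    boundaries = boundaries or DEFAULT_BOUNDARIES
    feature_params = feature_params or FeatureParams()

    features = extract_all(sweepsets, feature_params)
    normalized = normalize_slice(features, metas, pathway, boundaries)
    kept_ids = {f.cell_id for f in normalized}
    excluded = sorted(
        {m.slice_id for m in metas if m.cell_id not in kept_ids}
    )
    pooled = pool_groups(normalized, metas, boundaries)
    table = cell_table(features, normalized, metas, boundaries)

    features_to_frame(features).to_csv(out_dir / "features.csv", index=False)
    normalized_to_frame(normalized).to_csv(
        out_dir / "normalized.csv", index=False
    )
    pooled.to_csv(out_dir / "pooled.csv", index=False)

    for feature in ("amplitude", "slope"):
        tab, text = build_summary_table(pooled, feature)
        tab.to_csv(out_dir / f"table_{feature}.csv", index=False)
        (out_dir / f"table_{feature}.txt").write_text(text + "\n")

    pvals = compare_reference_layer(table, pathway)
    pvals.to_csv(out_dir / "pvalues.csv", index=False)

    profile = build_depth_profile(table, boundaries)
    profile.to_csv(out_dir / "depth_profile.csv", index=False)

    tc = build_grand_average_timecourse(sweepsets, metas)
    tc.to_csv(out_dir / "timecourse.csv", index=False)

    if plots:
        _plot_profile(profile, boundaries, out_dir / "depth_profile.png")

    manifest = {
        "package_version": _version,
        "pathway": pathway,
        "seed": seed,
        "n_cells": len(sweepsets),
        "n_cells_normalized": len(normalized),
        "excluded_slices": excluded,
        "feature_params": {
            "baseline_window_ms": feature_params.baseline_window_ms,
            "peak_window_ms": feature_params.peak_window_ms,
        },
        "layer_boundaries": boundaries.bands,
        "input_hashes": {
            str(p): _sha256(Path(p)) for p in input_paths if Path(p).exists()
        },
        "artifacts": sorted(
            p.name for p in out_dir.iterdir() if p.name != "manifest.json"
        ),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _plot_profile(
    profile: pd.DataFrame, boundaries: LayerBoundaries, path: Path
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 6))
    ax.plot(profile.iloc[:, 2], profile["depth_um"], "k.", ms=4)
    for _, lo, hi in boundaries.bands:
        ax.axhline(hi, color="0.8", lw=0.5)
    ax.invert_yaxis()
    ax.set_xlabel(profile.columns[2])
    ax.set_ylabel("subpial depth (µm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
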