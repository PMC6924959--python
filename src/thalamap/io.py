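"""Dataset I/O: HDF5 trace container plus CSV metadata table.

Layout on disk:

* traces: HDF5, one group per cell at ``/cells/<cell_id>`` containing a
  float64 dataset ``trials`` (n_trials x n_samples, mV) with attributes
  ``sampling_rate_hz``, ``stim_onset_s``, ``stim_duration_s``;
* metadata: CSV with header
  ``cell_id,slice_id,mouse_id,pathway,cell_type,layer,depth_um,condition``,
  empty string meaning unset.

Times are stored in SI units (seconds) and converted to the reporting units
(ms, mV/ms) only in feature tables.  Membrane potentials are stored as
recorded, i.e. not corrected for the liquid junction potential.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .types import CellMeta, DatasetError, SweepSet

META_COLUMNS = [
    "cell_id",
    "slice_id",
    "mouse_id",
    "pathway",
    "cell_type",
    "layer",
    "depth_um",
    "condition",
]


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.csv")


def write_dataset(
    sweepsets: Sequence[SweepSet],
    metas: Sequence[CellMeta],
    path: str | Path,
    meta_path: Optional[str | Path] = None,
) -> None:
    """Write a dataset (HDF5 traces + CSV metadata), sorted by cell_id.

    ``meta_path`` defaults to ``<path with .meta.csv suffix>``.
    """
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else _meta_path(path)

    ids = [s.cell_id for s in sweepsets]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DatasetError(f"duplicate cell_id(s): {dupes}")
    meta_ids = {m.cell_id for m in metas}
    if meta_ids != set(ids):
        missing = sorted(set(ids) ^ meta_ids)
        raise DatasetError(f"trace/metadata cell_id mismatch: {missing}")

    order = sorted(range(len(sweepsets)), key=lambda i: sweepsets[i].cell_id)
    with h5py.File(path, "w") as f:
        root = f.create_group("cells")
        for i in order:
            s = sweepsets[i]
            g = root.create_group(s.cell_id)
            g.create_dataset("trials", data=s.trials, dtype=np.float64)
            g.attrs["sampling_rate_hz"] = float(s.sampling_rate)
            g.attrs["stim_onset_s"] = float(s.stim_onset)
            g.attrs["stim_duration_s"] = float(s.stim_duration)

    rows = []
    for m in sorted(metas, key=lambda m: m.cell_id):
        rows.append(
            {
                "cell_id": m.cell_id,
                "slice_id": m.slice_id,
                "mouse_id": m.mouse_id,
                "pathway": m.pathway,
                "cell_type": m.cell_type,
                "layer": m.layer if m.layer is not None else "",
                "depth_um": "" if m.depth_um is None else repr(float(m.depth_um)),
                "condition": m.condition,
            }
        )
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(meta_path, index=False)


def read_metadata(meta_path: str | Path) -> list[CellMeta]:
    """Read and validate a metadata CSV."""
    df = pd.read_csv(meta_path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in META_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DatasetError(f"metadata missing columns: {missing_cols}")
    metas = []
    slice_mouse: dict[str, str] = {}
    for _, row in df.iterrows():
        depth = row["depth_um"].strip()
        meta = CellMeta(
            cell_id=row["cell_id"],
            slice_id=row["slice_id"],
            mouse_id=row["mouse_id"],
            pathway=row["pathway"],
            cell_type=row["cell_type"],
            layer=row["layer"] or None,
            depth_um=float(depth) if depth else None,
            condition=row["condition"] or "control",
        )
        if meta.depth_um is not None and not math.isfinite(meta.depth_um):
            raise DatasetError(f"cell {meta.cell_id}: non-finite depth_um")
        prev = slice_mouse.setdefault(meta.slice_id, meta.mouse_id)
        if prev != meta.mouse_id:
            raise DatasetError(
                f"cell {meta.cell_id}: slice {meta.slice_id} assigned to both "
                f"mouse {prev} and mouse {meta.mouse_id}"
            )
        metas.append(meta)
    ids = [m.cell_id for m in metas]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DatasetError(f"duplicate cell_id(s) in metadata: {dupes}")
    return metas


def read_dataset(
    path: str | Path,
    meta_path: Optional[str | Path] = None,
) -> tuple[list[SweepSet], list[CellMeta]]:
    """Read a dataset written by :func:`write_dataset`.

    Every metadata row must have a matching trace group and vice versa.
    Inconsistent sampling rates across cells are reported as a warning (the
    pipeline handles them per cell) rather than an error.
    """
    import warnings

    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else _meta_path(path)
    metas = read_metadata(meta_path)

    sweepsets = []
    with h5py.File(path, "r") as f:
        cells = f["cells"] if "cells" in f else {}
        trace_ids = sorted(cells.keys())
        meta_ids = sorted(m.cell_id for m in metas)
        if trace_ids != meta_ids:
            missing = sorted(set(trace_ids) ^ set(meta_ids))
            raise DatasetError(f"trace/metadata cell_id mismatch: {missing}")
        for cid in trace_ids:
            g = cells[cid]
            sweepsets.append(
                SweepSet(
                    cell_id=cid,
                    trials=g["trials"][()],
                    sampling_rate=float(g.attrs["sampling_rate_hz"]),
                    stim_onset=float(g.attrs["stim_onset_s"]),
                    stim_duration=float(g.attrs["stim_duration_s"]),
                )
            )
    rates = {s.sampling_rate for s in sweepsets}
    if len(rates) > 1:
        warnings.warn(f"inconsistent sampling rates across cells: {sorted(rates)}")
    metas.sort(key=lambda m: m.cell_id)
    return sweepsets, metas


def features_to_frame(features) -> pd.DataFrame:
    """EPSPFeatures rows -> DataFrame with the documented CSV columns."""
    return pd.DataFrame(
        [
            {
                "cell_id": f.cell_id,
                "baseline_mV": f.baseline_mV,
                "peak_amp_mV": f.peak_amp_mV,
                "peak_latency_ms": f.peak_latency_ms,
                "t20_ms": f.t20_ms,
                "t50_ms": f.t50_ms,
                "slope_mV_per_ms": f.slope_mV_per_ms,
            }
            for f in features
        ]
    )


def normalized_to_frame(normalized) -> pd.DataFrame:
    """NormalizedFeatures rows -> DataFrame with the documented CSV columns."""
    return pd.DataFrame(
        [
            {
                "cell_id": f.cell_id,
                "norm_amp": f.norm_amp,
                "norm_slope": f.norm_slope,
                "ref_layer": f.ref_layer,
                "ref_amp_mean_mV": f.ref_amp_mean_mV,
                "ref_slope_mean": f.ref_slope_mean,
            }
            for f in normalized
        ]
    )


def metas_to_frame(metas: Sequence[CellMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": m.cell_id,
                "slice_id": m.slice_id,
                "mouse_id": m.mouse_id,
                "pathway": m.pathway,
                "cell_type": m.cell_type,
                "layer": m.layer,
                "depth_um": m.depth_um,
                "condition": m.condition,
            }
            for m in metas
        ]
    )
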