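"""Shared data types for the EPSP quantification pipeline.

The pipeline operates on whole-cell membrane-potential recordings of
light-evoked monosynaptic EPSPs in barrel-cortex slices.  A recording is a
small matrix of repeated trials (:class:`SweepSet`); each recorded cell
carries identity metadata (:class:`CellMeta`): which slice and animal it came
from, which thalamic pathway was stimulated (VPM or POm), its cell type
(excitatory or one of three GABAergic classes) and its laminar position,
given either as an explicit layer label or as subpial depth in micrometres.

Feature extraction reduces a SweepSet to an :class:`EPSPFeatures` row
(baseline, peak amplitude, rise crossings, 20-50% rise slope); per-slice
normalization to reference-layer excitatory cells produces
:class:`NormalizedFeatures`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

PATHWAYS = ("VPM", "POm")
CELL_TYPES = ("EXC", "PV", "SST", "VIP")
#: Layers in pial-to-white-matter order.  L1 may be assigned from depth but
#: holds no recordings in the analyzed datasets.
LAYERS = ("L1", "L2", "L3", "L4", "L5A", "L5B", "L6")
CONDITIONS = ("control", "CNQX_APV", "late_timepoint")

#: Reference layer whose excitatory cells define the per-slice normalization
#: denominator, by stimulated pathway (densest axonal innervation).
REFERENCE_LAYER = {"VPM": "L4", "POm": "L5A"}


class DatasetError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass
class SweepSet:
    """One cell's stimulus-aligned trials.

    Parameters
    ----------
    cell_id
        Unique cell identifier.
    trials
        (n_trials, n_samples) membrane potential in mV.
    sampling_rate
        Digitization rate in Hz (20 kHz in the emulated experiments).
    stim_onset
        Light-pulse onset in seconds from trace start.  Must leave room for
        a full pre-stimulus baseline window.
    stim_duration
        Light-pulse duration in seconds (1 ms pulses).
    """

    cell_id: str
    trials: np.ndarray
    sampling_rate: float
    stim_onset: float
    stim_duration: float = 0.001

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=np.float64)
        if self.trials.ndim != 2 or self.trials.shape[0] < 1:
            raise DatasetError(
                f"cell {self.cell_id}: trials must be a (n_trials, n_samples) "
                f"matrix with n_trials >= 1, got shape {self.trials.shape}"
            )
        if not np.all(np.isfinite(self.trials)):
            raise DatasetError(f"cell {self.cell_id}: non-finite V_m sample")
        if self.sampling_rate <= 0:
            raise DatasetError(f"cell {self.cell_id}: sampling_rate must be > 0")
        if self.stim_onset < 0:
            raise DatasetError(f"cell {self.cell_id}: stim_onset must be >= 0")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[1]

    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return np.arange(self.n_samples) / self.sampling_rate - self.stim_onset


@dataclass
class CellMeta:
    """Identity of a recorded cell."""

    cell_id: str
    slice_id: str
    mouse_id: str
    pathway: str
    cell_type: str
    layer: Optional[str] = None
    depth_um: Optional[float] = None
    condition: str = "control"

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise DatasetError(
                f"cell {self.cell_id}: unknown pathway {self.pathway!r}"
            )
        if self.cell_type not in CELL_TYPES:
            raise DatasetError(
                f"cell {self.cell_id}: unknown cell_type {self.cell_type!r}"
            )
        if self.layer is not None and self.layer not in LAYERS:
            raise DatasetError(f"cell {self.cell_id}: unknown layer {self.layer!r}")
        if self.condition not in CONDITIONS:
            raise DatasetError(
                f"cell {self.cell_id}: unknown condition {self.condition!r}"
            )
        if self.layer is None and self.depth_um is None:
            raise DatasetError(
                f"cell {self.cell_id}: at least one of layer, depth_um required"
            )


@dataclass
class EPSPFeatures:
    """Extracted EPSP features of one cell (times in ms after stimulus onset).

    ``t20_ms``, ``t50_ms`` and ``slope_mV_per_ms`` may be None when the
    trial-averaged trace has no identifiable rising phase (e.g. fully blocked
    responses); the peak amplitude is still reported in that case.
    """

    cell_id: str
    baseline_mV: float
    peak_amp_mV: float
    peak_latency_ms: float
    t20_ms: Optional[float] = None
    t50_ms: Optional[float] = None
    slope_mV_per_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.t20_ms is not None and self.t50_ms is not None:
            if not (self.t20_ms < self.t50_ms <= self.peak_latency_ms + 1e-9):
                raise DatasetError(
                    f"cell {self.cell_id}: require t20 < t50 <= peak latency "
                    f"({self.t20_ms}, {self.t50_ms}, {self.peak_latency_ms})"
                )
        if self.slope_mV_per_ms is not None and (
            self.t20_ms is None or self.t50_ms is None
        ):
            raise DatasetError(
                f"cell {self.cell_id}: slope defined without rise crossings"
            )


@dataclass
class NormalizedFeatures:
    """Per-slice reference-normalized EPSP features of one cell.

    ``norm_amp`` is the cell's peak amplitude divided by the mean peak
    amplitude of the reference-layer excitatory cells recorded in the same
    slice (reference cells included in their own denominator), which removes
    slice-to-slice variation in opsin expression level.
    """

    cell_id: str
    norm_amp: float
    norm_slope: Optional[float]
    ref_layer: str
    ref_amp_mean_mV: float
    ref_slope_mean: Optional[float]


@dataclass
class GroupSummary:
    """Descriptive statistics of one (pathway, cell type, layer) group."""

    pathway: Optional[str]
    cell_type: Optional[str]
    layer: Optional[str]
    n: int
    mean: float
    sd: Optional[float]
    sem: Optional[float]
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float


@dataclass
class LayerBoundaries:
    """Contiguous half-open depth bands [lo, hi) in µm from the pia.

    ``bands`` is an ordered list of (layer, depth_lo_um, depth_hi_um)
    covering the cortical depth from 0 without gaps or overlap.
    """

    bands: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.bands:
            raise DatasetError("LayerBoundaries requires at least one band")
        prev_hi = 0.0
        for layer, lo, hi in self.bands:
            if layer not in LAYERS:
                raise DatasetError(f"unknown layer {layer!r} in boundaries")
            if lo != prev_hi:
                raise DatasetError(
                    f"layer bands must be contiguous from 0: {layer} starts at "
                    f"{lo}, expected {prev_hi}"
                )
            if hi <= lo:
                raise DatasetError(f"layer {layer}: band must be increasing")
            prev_hi = hi

    @property
    def max_depth_um(self) -> float:
        return self.bands[-1][2]
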