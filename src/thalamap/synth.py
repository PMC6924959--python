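"""Generative simulator of the slice-optogenetics experiments.

A simulated cohort reproduces the statistical structure the analysis
assumes:

* per slice, a single opsin-expression scale factor multiplies all absolute
  EPSP amplitudes (log-normal across slices), which is exactly what the
  per-slice normalization is designed to remove;
* per (cell type, layer) group, normalized amplitudes are drawn from a
  log-normal moment-matched to the published group mean/SD, reproducing the
  strong right skew of the observed groups (printed medians far below
  means);
* per cell, ~20 stimulus-locked trials are synthesized as resting potential
  + Ornstein-Uhlenbeck membrane noise + a dual-exponential EPSP whose
  kinetics depend on cell type (fast PV, slow EXC) and whose per-trial
  amplitude jitters around the cell's mean;
* pharmacology conditions: glutamate-receptor blockade (CNQX/APV) forces
  the evoked amplitude to zero; a late recording time point applies a
  configurable multiplicative drift (zero by default, emulating the
  observed stability of optogenetic stimulation over ~1 h).

The same seed and configuration always produce a bit-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy.signal import lfilter

from . import params as published
from .types import CellMeta, DatasetError, SweepSet


# --------------------------------------------------------------------------
# configuration

@dataclass
class GroupParams:
    """Generative parameters of one (cell_type, layer) group."""

    mean_norm_amp: float
    sd_norm_amp: float
    n_cells: int


@dataclass
class SimulationConfig:
    """Full parameterization of one synthetic cohort (single pathway)."""

    pathway: str = "VPM"
    n_slices: int = 33
    group_params: dict[tuple[str, str], GroupParams] = field(default_factory=dict)
    #: median (mV) and log-space sigma of the per-slice reference-group
    #: absolute mean amplitude (log-normal across slices)
    ref_abs_amp_median_mV: float = 14.5
    ref_abs_amp_sigma_log: float = 0.4
    #: cell_type -> (tau_rise_ms, tau_decay_ms)
    kinetics_ms: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(published.KINETICS_MS)
    )
    ou_sigma_mV: float = 0.3
    ou_tau_ms: float = 10.0
    v_rest_mV: float = -70.0
    n_trials: int = 20
    sampling_rate: float = 20000.0
    trace_len_s: float = 0.3
    stim_onset_s: float = 0.12
    stim_duration_s: float = 0.001
    trial_amp_jitter_cv: float = 0.1
    drift_per_hour: float = 0.0
    condition: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        for ct, (tr, td) in self.kinetics_ms.items():
            if not tr < td:
                raise DatasetError(
                    f"kinetics for {ct}: tau_rise must be < tau_decay"
                )
        if self.n_trials < 1:
            raise DatasetError("n_trials must be >= 1")
        for key, gp in self.group_params.items():
            if gp.sd_norm_amp < 0:
                raise DatasetError(f"group {key}: SD must be >= 0")
        if self.stim_onset_s < 0.1:
            raise DatasetError(
                "stim_onset_s must leave >= 100 ms of pre-stimulus baseline"
            )

    @property
    def reference_layer(self) -> str:
        from .types import REFERENCE_LAYER

        return REFERENCE_LAYER[self.pathway]


def default_config(pathway: str = "VPM", **overrides) -> SimulationConfig:
    """Cohort configuration with the published group structure for a pathway."""
    gp = {
        key: GroupParams(mean, sd, n)
        for key, (mean, sd, n) in published.GROUP_NORM_AMP[pathway].items()
    }
    cfg = dict(
        pathway=pathway,
        n_slices=published.N_SLICES[pathway],
        group_params=gp,
        ref_abs_amp_median_mV=published.REF_ABS_AMP_MV[pathway],
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["group_params"] = {
        f"{ct}/{layer}": [gp.mean_norm_amp, gp.sd_norm_amp, gp.n_cells]
        for (ct, layer), gp in cfg.group_params.items()
    }
    d["kinetics_ms"] = {k: list(v) for k, v in cfg.kinetics_ms.items()}
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    gp = {}
    for key, (mean, sd, n) in d.get("group_params", {}).items():
        ct, layer = key.split("/")
        gp[(ct, layer)] = GroupParams(float(mean), float(sd), int(n))
    d["group_params"] = gp
    d["kinetics_ms"] = {
        k: (float(v[0]), float(v[1])) for k, v in d.get("kinetics_ms", {}).items()
    }
    return SimulationConfig(**d)


def load_config(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML (or JSON) file."""
    with open(path) as f:
        return config_from_dict(yaml.safe_load(f))


def save_config(cfg: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config_to_dict(cfg), f, sort_keys=True)


# --------------------------------------------------------------------------
# primitive generators

def waveform_peak_time_ms(tau_rise_ms: float, tau_decay_ms: float) -> float:
    """Analytic peak time of the dual-exponential waveform (ms)."""
    tr, td = tau_rise_ms, tau_decay_ms
    return tr * td / (td - tr) * np.log(td / tr)


def epsp_waveform(
    amplitude: float,
    tau_rise_ms: float,
    tau_decay_ms: float,
    t_ms: np.ndarray,
) -> np.ndarray:
    """Dual-exponential EPSP deflection, peak-normalized to ``amplitude``.

    w(t) = A (exp(-t/tau_d) - exp(-t/tau_r)) / N, with N chosen so the
    continuous-time maximum equals A; w(0) = 0 and w(t<0) = 0.
    """
    if not tau_rise_ms < tau_decay_ms:
        raise DatasetError("tau_rise must be < tau_decay")
    t = np.asarray(t_ms, dtype=np.float64)
    tstar = waveform_peak_time_ms(tau_rise_ms, tau_decay_ms)
    norm = np.exp(-tstar / tau_decay_ms) - np.exp(-tstar / tau_rise_ms)
    w = np.where(
        t >= 0,
        np.exp(-np.maximum(t, 0) / tau_decay_ms)
        - np.exp(-np.maximum(t, 0) / tau_rise_ms),
        0.0,
    )
    return amplitude * w / norm


def ou_noise(
    n_trials: int,
    n_samples: int,
    dt_s: float,
    sigma_mV: float,
    tau_ms: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck noise, exact discretization.

    x[k+1] = a x[k] + sqrt(1 - a^2) sigma eps, a = exp(-dt/tau); the first
    sample is drawn from the stationary distribution N(0, sigma^2).
    """
    if sigma_mV == 0:
        return np.zeros((n_trials, n_samples))
    a = np.exp(-dt_s * 1000.0 / tau_ms)
    eps = rng.standard_normal((n_trials, n_samples))
    drive = np.sqrt(1.0 - a * a) * sigma_mV * eps
    drive[:, 0] = sigma_mV * eps[:, 0]
    return lfilter([1.0], [1.0, -a], drive, axis=1)


def group_amplitude_rvs(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draws of a group's normalized amplitude: moment-matched log-normal.

    The log-normal with sigma^2 = ln(1 + (sd/mean)^2) and
    mu = ln(mean) - sigma^2/2 has exactly the requested mean and SD, is
    non-negative, and reproduces the strong right skew of the observed
    group distributions (group medians printed far below group means).
    sd = 0 (or mean <= 0) degenerates to a constant.
    """
    if mean <= 0:
        return np.zeros(size)
    if sd == 0:
        return np.full(size, mean)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return np.exp(mu + np.sqrt(sigma2) * rng.standard_normal(size))


def group_median(mean: float, sd: float) -> float:
    """Median of the moment-matched log-normal group distribution."""
    if mean <= 0 or sd == 0:
        return max(mean, 0.0)
    sigma2 = np.log1p((sd / mean) ** 2)
    return mean * np.exp(-sigma2 / 2.0)


# --------------------------------------------------------------------------
# cell- and cohort-level simulation

def simulate_cell(
    meta: CellMeta,
    amp_mean_mV: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SweepSet:
    """Synthesize one cell's trial matrix.

    Each trial is v_rest + OU noise + the cell-type waveform scaled by a
    per-trial amplitude max(0, Normal(amp_mean, cv * amp_mean)).  The
    CNQX/APV condition forces the evoked amplitude to zero; the
    late-time-point condition scales the mean by (1 + drift_per_hour).
    """
    if amp_mean_mV < 0:
        raise DatasetError(f"cell {meta.cell_id}: amp_mean must be >= 0")
    mean = amp_mean_mV
    if meta.condition == "CNQX_APV":
        mean = 0.0
    elif meta.condition == "late_timepoint":
        mean = amp_mean_mV * (1.0 + config.drift_per_hour)

    n_samples = int(round(config.trace_len_s * config.sampling_rate))
    cv = config.trial_amp_jitter_cv
    if mean > 0 and cv > 0:
        amps = np.maximum(
            0.0, rng.normal(mean, cv * mean, size=config.n_trials)
        )
    else:
        amps = np.full(config.n_trials, mean)

    trials = np.full((config.n_trials, n_samples), config.v_rest_mV)
    trials += ou_noise(
        config.n_trials,
        n_samples,
        1.0 / config.sampling_rate,
        config.ou_sigma_mV,
        config.ou_tau_ms,
        rng,
    )
    if mean > 0:
        tau_r, tau_d = config.kinetics_ms[meta.cell_type]
        t_ms = (
            np.arange(n_samples) / config.sampling_rate - config.stim_onset_s
        ) * 1000.0
        trials += amps[:, None] * epsp_waveform(1.0, tau_r, tau_d, t_ms)[None, :]
    return SweepSet(
        cell_id=meta.cell_id,
        trials=trials,
        sampling_rate=config.sampling_rate,
        stim_onset=config.stim_onset_s,
        stim_duration=config.stim_duration_s,
    )


def _plan_cohort(config: SimulationConfig) -> list[tuple[int, str, str]]:
    """Deterministic assignment of group cells to slices.

    Returns a list of (slice_index, cell_type, layer), ordered by slice.
    Reference-layer excitatory cells are spread first so that every slice
    gets at least one (two while supply lasts); remaining groups are dealt
    round-robin across slices.
    """
    ref_layer = config.reference_layer
    ref_key = ("EXC", ref_layer)
    if ref_key not in config.group_params:
        raise DatasetError(
            f"sampling rule provides no reference-layer EXC group ({ref_layer})"
        )
    n_ref = config.group_params[ref_key].n_cells
    S = config.n_slices
    if n_ref < S:
        raise DatasetError(
            f"{n_ref} reference cells cannot cover {S} slices: some slice "
            "would lack a reference cell"
        )
    plan: list[tuple[int, str, str]] = []
    # one reference cell per slice, then extras dealt from slice 0
    counts = [1] * S
    for i in range(n_ref - S):
        counts[i % S] += 1
    for si, c in enumerate(counts):
        plan.extend((si, "EXC", ref_layer) for _ in range(c))

    cursor = 0
    for (ct, layer) in sorted(k for k in config.group_params if k != ref_key):
        for _ in range(config.group_params[(ct, layer)].n_cells):
            plan.append((cursor % S, ct, layer))
            cursor += 1
    plan.sort(key=lambda x: x[0])
    return plan


def _layer_band(layer: str) -> tuple[float, float]:
    for name, lo, hi in published.DEFAULT_BOUNDARIES.bands:
        if name == layer:
            return lo, hi
    raise DatasetError(f"no depth band for layer {layer}")


def draw_cohort_amplitudes(
    config: SimulationConfig, rng: np.random.Generator
):
    """Draw the cohort's cell identities and generative amplitudes.

    Returns ``(metas, truth)`` where ``truth`` maps cell_id to a dict with
    the per-slice reference scale ``ref_abs_amp_mV``, the cell's normalized
    generative draw ``g`` and its absolute mean amplitude ``amp_mean_mV``.
    This is the trace-free statistical layer of the generative model, shared
    by the full simulator and by feature-level Monte-Carlo studies.
    """
    plan = _plan_cohort(config)
    S = config.n_slices
    ref_scale = config.ref_abs_amp_median_mV * np.exp(
        config.ref_abs_amp_sigma_log * rng.standard_normal(S)
    )
    metas: list[CellMeta] = []
    truth: dict[str, dict] = {}
    per_slice_counter = [0] * S
    for si, ct, layer in plan:
        k = per_slice_counter[si]
        per_slice_counter[si] += 1
        cell_id = f"{config.pathway}_sl{si:03d}_c{k:02d}"
        gp = config.group_params[(ct, layer)]
        g = float(group_amplitude_rvs(gp.mean_norm_amp, gp.sd_norm_amp, 1, rng)[0])
        lo, hi = _layer_band(layer)
        depth = float(rng.uniform(lo, hi))
        metas.append(
            CellMeta(
                cell_id=cell_id,
                slice_id=f"{config.pathway}_sl{si:03d}",
                mouse_id=f"{config.pathway}_m{si:03d}",
                pathway=config.pathway,
                cell_type=ct,
                layer=layer,
                depth_um=depth,
                condition=config.condition,
            )
        )
        truth[cell_id] = {
            "ref_abs_amp_mV": float(ref_scale[si]),
            "g": g,
            "amp_mean_mV": float(ref_scale[si]) * g,
        }
    return metas, truth


def draw_group_norm_values(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[tuple[str, str], np.ndarray]:
    """Feature-level cohort draw: normalized amplitudes per group.

    Draws the cohort's generative amplitudes and applies the per-slice
    reference normalization directly to them, skipping trace synthesis and
    feature extraction (whose contribution to group statistics is
    negligible relative to the between-cell spread).  Used for Monte-Carlo
    studies that need many cohort realizations.
    """
    metas, truth = draw_cohort_amplitudes(config, rng)
    by_slice: dict[str, list[CellMeta]] = {}
    for m in metas:
        by_slice.setdefault(m.slice_id, []).append(m)
    out: dict[tuple[str, str], list[float]] = {}
    for ms in by_slice.values():
        ref = [
            truth[m.cell_id]["amp_mean_mV"]
            for m in ms
            if m.cell_type == "EXC" and m.layer == config.reference_layer
        ]
        denom = float(np.mean(ref))
        for m in ms:
            out.setdefault((m.cell_type, m.layer), []).append(
                truth[m.cell_id]["amp_mean_mV"] / denom
            )
    return {k: np.asarray(v) for k, v in out.items()}


def simulate_dataset(
    config: SimulationConfig, return_truth: bool = False
):
    """Simulate a full cohort of SweepSets with metadata.

    Deterministic under ``config.seed``.  With ``return_truth=True`` the
    per-cell generative draws are returned as a third element.
    """
    rng = np.random.default_rng(config.seed)
    metas, truth = draw_cohort_amplitudes(config, rng)
    sweepsets = [
        simulate_cell(m, truth[m.cell_id]["amp_mean_mV"], config, rng)
        for m in metas
    ]
    if return_truth:
        return sweepsets, metas, truth
    return sweepsets, metas


def simulate_stability_pair(
    n_cells: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    amp_mean_mV: float | None = None,
) -> tuple[list[SweepSet], list[SweepSet], list[CellMeta]]:
    """Paired early/late recordings from the same cells.

    Emulates the stability control: each cell is measured right after
    break-in (control condition) and again ~1 h later (late_timepoint, with
    the configured drift).  Returns (early sweeps, late sweeps, metas).
    """
    amp = config.ref_abs_amp_median_mV if amp_mean_mV is None else amp_mean_mV
    early, late, metas = [], [], []
    for i in range(n_cells):
        base = CellMeta(
            cell_id=f"stab_c{i:02d}",
            slice_id=f"stab_sl{i:02d}",
            mouse_id=f"stab_m{i:02d}",
            pathway=config.pathway,
            cell_type="EXC",
            layer=config.reference_layer,
            condition="control",
        )
        cell_amp = float(
            group_amplitude_rvs(amp, 0.3 * amp, 1, rng)[0]
        )
        early.append(simulate_cell(base, cell_amp, config, rng))
        late_meta = CellMeta(
            cell_id=base.cell_id + "_late",
            slice_id=base.slice_id,
            mouse_id=base.mouse_id,
            pathway=base.pathway,
            cell_type=base.cell_type,
            layer=base.layer,
            condition="late_timepoint",
        )
        late.append(simulate_cell(late_meta, cell_amp, config, rng))
        metas.append(base)
    return early, late, metas
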