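"""Shared fixtures: small deterministic cohorts and noiseless traces."""

from __future__ import annotations

import numpy as np
import pytest

import thalamap as tm

#: fixed once for the whole suite; all test randomness derives from it
SUITE_SEED = 20201220


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SUITE_SEED)


def make_noiseless_config(pathway="VPM", **overrides):
    """Config with all randomness in the traces switched off."""
    defaults = dict(
        ou_sigma_mV=0.0,
        trial_amp_jitter_cv=0.0,
        ref_abs_amp_sigma_log=0.0,
        n_trials=2,
        trace_len_s=0.24,
        stim_onset_s=0.11,
    )
    defaults.update(overrides)
    return tm.default_config(pathway, **defaults)


def noiseless_sweepset(
    amp_mV,
    cell_type="EXC",
    fs=20000.0,
    stim_onset=0.11,
    trace_len=0.24,
    v_rest=-70.0,
    cell_id="cell",
):
    """Single noise-free trial built directly from the waveform model."""
    n = int(round(trace_len * fs))
    t_ms = (np.arange(n) / fs - stim_onset) * 1000.0
    tau_r, tau_d = tm.KINETICS_MS[cell_type]
    trace = v_rest + tm.epsp_waveform(amp_mV, tau_r, tau_d, t_ms)
    return tm.SweepSet(cell_id, trace[None, :], fs, stim_onset)


@pytest.fixture(scope="session")
def small_cohort():
    """Trace-level VPM cohort small enough for fast end-to-end tests."""
    cfg = tm.default_config(
        "VPM",
        n_slices=4,
        group_params={
            ("EXC", "L4"): tm.GroupParams(1.0, 0.37, 8),
            ("EXC", "L3"): tm.GroupParams(0.46, 0.50, 8),
            ("EXC", "L5A"): tm.GroupParams(0.14, 0.21, 6),
            ("PV", "L4"): tm.GroupParams(1.15, 0.92, 6),
            ("SST", "L4"): tm.GroupParams(0.09, 0.08, 4),
        },
        trace_len_s=0.24,
        stim_onset_s=0.11,
        seed=SUITE_SEED,
    )
    sweepsets, metas, truth = tm.simulate_dataset(cfg, return_truth=True)
    return cfg, sweepsets, metas, truth
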