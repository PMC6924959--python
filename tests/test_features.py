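"""Feature extraction against closed-form and brute-force oracles."""

import numpy as np
import pytest
from scipy.optimize import brentq

import thalamap as tm
from thalamap.features import (
    average_trace,
    compute_baseline,
    compute_peak,
    compute_rise_crossings,
    compute_slope,
)

from conftest import noiseless_sweepset

FS = 20000.0


def _flat_sweeps(value, n_trials=3, n_samples=4400, stim_onset=0.11):
    trials = np.full((n_trials, n_samples), float(value))
    return tm.SweepSet("flat", trials, FS, stim_onset)


# --------------------------------------------------------------------- mean

def test_average_of_identical_trials_is_any_trial(rng):
    trace = -70 + rng.standard_normal(1000)
    ss = tm.SweepSet("c", np.tile(trace, (20, 1)), FS, 0.02)
    _, mean = average_trace(ss)
    assert mean == pytest.approx(trace, abs=1e-12)


def test_average_is_pointwise_arithmetic_mean():
    ss = tm.SweepSet("c", np.vstack([np.zeros(100), 2 * np.ones(100)]), FS, 0.002)
    _, mean = average_trace(ss)
    assert np.allclose(mean, 1.0)


def test_average_noise_shrinks_as_sqrt_n(rng):
    """Sup-norm of averaged zero-mean OU noise scales ~ 1/sqrt(n_trials)."""
    dt = 1.0 / FS
    big = tm.ou_noise(2000, 1000, dt, 0.3, 10.0, rng).mean(axis=0)
    small = tm.ou_noise(20, 1000, dt, 0.3, 10.0, rng).mean(axis=0)
    ratio = np.abs(small).max() / np.abs(big).max()
    # expected sqrt(2000/20) = 10; generous band for the sup-norm statistic
    assert 3 < ratio < 30


# ----------------------------------------------------------------- baseline

def test_baseline_of_constant_trace():
    t_ms, mean = average_trace(_flat_sweeps(-70.0))
    assert compute_baseline(t_ms, mean) == -70.0


def test_baseline_of_linear_ramp_matches_closed_form():
    """Mean of a sampled ramp equals the arithmetic-sequence mean."""
    n = 4400
    stim = 0.11
    t_ms = (np.arange(n) / FS - stim) * 1000.0
    trace = np.zeros(n)
    mask = (t_ms >= -100.0) & (t_ms < 0)
    ramp = np.linspace(0.0, 1.0, mask.sum())
    trace[mask] = ramp
    expected = ramp.mean()  # = (0 + 1)/2 exactly for a symmetric sequence
    assert compute_baseline(t_ms, trace) == pytest.approx(expected, abs=1e-12)


def test_baseline_rejects_zero_window():
    t_ms, mean = average_trace(_flat_sweeps(-70.0))
    with pytest.raises(ValueError):
        compute_baseline(t_ms, mean, window_ms=0)


def test_baseline_rejects_short_prestim():
    ss = _flat_sweeps(-70.0, n_samples=2200, stim_onset=0.05)  # only 50 ms
    t_ms, mean = average_trace(ss)
    with pytest.raises(ValueError, match="pre-stimulus"):
        compute_baseline(t_ms, mean)


# --------------------------------------------------------------------- peak

def test_peak_recovers_waveform_amplitude():
    ss = noiseless_sweepset(14.5)
    f = tm.extract_features(ss)
    assert f.peak_amp_mV == pytest.approx(14.5, rel=1e-3)
    assert f.peak_latency_ms == pytest.approx(
        tm.waveform_peak_time_ms(2.0, 40.0), abs=0.05
    )


def test_peak_of_flat_trace_is_zero():
    t_ms, mean = average_trace(_flat_sweeps(-70.0))
    base = compute_baseline(t_ms, mean)
    amp, _ = compute_peak(t_ms, mean, base)
    assert amp == 0.0


def test_peak_tie_broken_by_earliest_sample():
    n = 4400
    stim = 0.11
    t_ms = (np.arange(n) / FS - stim) * 1000.0
    trace = np.zeros(n)
    i = np.flatnonzero(t_ms > 0)
    trace[i[10]] = trace[i[40]] = 5.0
    amp, lat = compute_peak(t_ms, trace, 0.0)
    assert amp == 5.0
    assert lat == pytest.approx(t_ms[i[10]])


# ---------------------------------------------------------------- crossings

def test_crossings_of_linear_ramp_are_proportional():
    """A straight 1 ms rise crosses 20%/50% at 0.2/0.5 ms after onset."""
    n = 4400
    stim = 0.11
    t_ms = (np.arange(n) / FS - stim) * 1000.0
    trace = np.interp(t_ms, [0.0, 1.0], [0.0, 10.0])
    trace[t_ms > 1.0] = 10.0
    trace[t_ms < 0.0] = 0.0
    amp, lat = compute_peak(t_ms, trace, 0.0)
    t20, t50 = compute_rise_crossings(t_ms, trace, 0.0, amp, lat)
    assert t20 == pytest.approx(0.2, abs=1e-9)
    assert t50 == pytest.approx(0.5, abs=1e-9)
    slope = compute_slope(t_ms, trace, t20, t50)
    assert slope == pytest.approx(10.0, rel=1e-9)


@pytest.mark.parametrize("cell_type", ["EXC", "PV", "SST", "VIP"])
def test_crossings_match_root_finding_on_analytic_waveform(cell_type):
    """Interpolated crossings agree with bisection on the closed form."""
    tau_r, tau_d = tm.KINETICS_MS[cell_type]
    A = 5.0
    ss = noiseless_sweepset(A, cell_type)
    f = tm.extract_features(ss)

    tstar = tm.waveform_peak_time_ms(tau_r, tau_d)
    w = lambda t: tm.epsp_waveform(A, tau_r, tau_d, np.array([t]))[0]
    t20_true = brentq(lambda t: w(t) - 0.2 * A, 1e-9, tstar)
    t50_true = brentq(lambda t: w(t) - 0.5 * A, 1e-9, tstar)
    dt_ms = 1000.0 / FS
    assert abs(f.t20_ms - t20_true) < dt_ms
    assert abs(f.t50_ms - t50_true) < dt_ms


def test_no_crossings_for_nonpositive_peak():
    t_ms, mean = average_trace(_flat_sweeps(-70.0))
    assert compute_rise_crossings(t_ms, mean, -70.0, 0.0, 1.0) == (None, None)


def test_single_sample_rise_gives_amplitude_without_slope():
    """A step at the first post-stimulus sample has no 20-50% rise period."""
    n = 4400
    stim = 0.11
    t_ms = (np.arange(n) / FS - stim) * 1000.0
    trace = np.where(t_ms > 0, 8.0, 0.0)
    ss = tm.SweepSet("step", trace[None, :], FS, stim)
    f = tm.extract_features(ss)
    assert f.peak_amp_mV == pytest.approx(8.0)
    assert f.slope_mV_per_ms is None and f.t20_ms is None


# -------------------------------------------------------------------- slope

def test_slope_oracle_dual_exponential():
    """OLS slope matches dense-grid OLS on the analytic waveform to <1%."""
    A, tau_r, tau_d = 5.0, 2.0, 40.0
    ss = noiseless_sweepset(A, "EXC")
    f = tm.extract_features(ss)
    tstar = tm.waveform_peak_time_ms(tau_r, tau_d)
    w = lambda t: tm.epsp_waveform(A, tau_r, tau_d, np.array([t]))[0]
    t20 = brentq(lambda t: w(t) - 0.2 * A, 1e-9, tstar)
    t50 = brentq(lambda t: w(t) - 0.5 * A, 1e-9, tstar)
    tg = np.arange(t20, t50, 0.001)
    oracle = np.polyfit(tg, tm.epsp_waveform(A, tau_r, tau_d, tg), 1)[0]
    assert f.slope_mV_per_ms == pytest.approx(oracle, rel=0.01)


def test_slope_invariant_to_constant_offset():
    ss = noiseless_sweepset(5.0)
    f0 = tm.extract_features(ss)
    shifted = tm.SweepSet("s", ss.trials + 12.5, FS, ss.stim_onset)
    f1 = tm.extract_features(shifted)
    assert f1.slope_mV_per_ms == pytest.approx(f0.slope_mV_per_ms, rel=1e-9)
    assert f1.peak_amp_mV == pytest.approx(f0.peak_amp_mV, rel=1e-9)


@pytest.mark.parametrize("scale", [0.5, 2.0, 7.0])
def test_amplitude_and_slope_scale_linearly(scale):
    base = tm.extract_features(noiseless_sweepset(4.0))
    scaled = tm.extract_features(noiseless_sweepset(4.0 * scale))
    assert scaled.peak_amp_mV == pytest.approx(base.peak_amp_mV * scale, rel=1e-6)
    assert scaled.slope_mV_per_ms == pytest.approx(
        base.slope_mV_per_ms * scale, rel=1e-4
    )


def test_pv_slope_exceeds_exc_slope_at_matched_amplitude():
    """Fast PV kinetics give strictly larger rise slopes than EXC kinetics."""
    for A in (1.0, 5.0, 20.0):
        pv = tm.extract_features(noiseless_sweepset(A, "PV"))
        exc = tm.extract_features(noiseless_sweepset(A, "EXC"))
        assert pv.slope_mV_per_ms > exc.slope_mV_per_ms


def test_blocked_cell_amplitude_at_noise_floor(rng):
    """Receptor-blocked cells report only residual noise as amplitude."""
    cfg = tm.default_config("VPM", trace_len_s=0.24, stim_onset_s=0.11)
    meta = tm.CellMeta("c", "sl", "m", "VPM", "EXC", "L4", None, "CNQX_APV")
    amps = [
        tm.extract_features(tm.simulate_cell(meta, 14.5, cfg, rng)).peak_amp_mV
        for _ in range(10)
    ]
    floor = 6 * cfg.ou_sigma_mV / np.sqrt(cfg.n_trials)
    assert max(np.abs(amps)) < floor
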