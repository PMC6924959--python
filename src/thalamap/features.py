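"""EPSP feature extraction from stimulus-aligned trial sets.

All features are computed on the trial-averaged trace: the mean trace is the
pointwise average over trials; the baseline is the mean membrane potential
over the 100 ms preceding stimulus onset; the peak amplitude is the maximum
of the mean trace in a post-stimulus search window minus the baseline; the
rise slope is an ordinary least-squares fit to the 20-50% rise-time period,
with the 20% and 50% crossing times located by backward search from the peak
with linear interpolation between samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .types import EPSPFeatures, SweepSet


@dataclass
class FeatureParams:
    """Tunable extraction parameters (ms)."""

    baseline_window_ms: float = 100.0
    peak_window_ms: float = 100.0


def average_trace(sweeps: SweepSet) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged trace and its time axis.

    Returns ``(t_ms, mean_mV)`` with time in ms relative to stimulus onset.
    """
    mean = sweeps.trials.mean(axis=0)
    t_ms = sweeps.times() * 1000.0
    return t_ms, mean


def compute_baseline(
    t_ms: np.ndarray, trace: np.ndarray, window_ms: float = 100.0
) -> float:
    """Mean V_m over the ``window_ms`` before stimulus onset."""
    if window_ms <= 0:
        raise ValueError("baseline window must be > 0 ms")
    mask = (t_ms >= -window_ms) & (t_ms < 0)
    if not mask.any() or t_ms[0] > -window_ms + 1e-9:
        raise ValueError(
            f"trace provides only {-t_ms[0]:.3f} ms of pre-stimulus data, "
            f"need {window_ms} ms"
        )
    return float(trace[mask].mean())


def compute_peak(
    t_ms: np.ndarray,
    trace: np.ndarray,
    baseline: float,
    peak_window_ms: float = 100.0,
) -> tuple[float, float]:
    """Peak amplitude (mV, relative to baseline) and latency (ms).

    The peak is searched in the half-open window (0, peak_window_ms] after
    stimulus onset; ties are broken by the earliest sample.
    """
    mask = (t_ms > 0) & (t_ms <= peak_window_ms)
    if not mask.any():
        raise ValueError("peak search window lies outside the trace")
    idx = np.flatnonzero(mask)
    seg = trace[idx]
    k = int(np.argmax(seg))  # argmax returns the first maximum: earliest tie
    return float(seg[k] - baseline), float(t_ms[idx[k]])


def _interp_crossing(
    t_ms: np.ndarray, trace: np.ndarray, i: int, thr: float
) -> float:
    """Linear-interpolated time where trace crosses ``thr`` in [i, i+1]."""
    v0, v1 = trace[i], trace[i + 1]
    if v1 == v0:
        return float(t_ms[i])
    frac = (thr - v0) / (v1 - v0)
    return float(t_ms[i] + frac * (t_ms[i + 1] - t_ms[i]))


def compute_rise_crossings(
    t_ms: np.ndarray,
    trace: np.ndarray,
    baseline: float,
    peak_amp: float,
    peak_latency_ms: float,
) -> tuple[Optional[float], Optional[float]]:
    """20% and 50% rise-crossing times (ms after stimulus onset).

    Starting from the peak sample, walks backward through the contiguous
    run of samples above each threshold and linearly interpolates the
    upward crossing at its start.  Returns (None, None) when the peak
    amplitude is non-positive or a crossing cannot be bracketed within
    [stimulus onset, peak].
    """
    if peak_amp <= 0:
        return None, None
    # index of the peak sample
    peak_idx = int(np.argmin(np.abs(t_ms - peak_latency_ms)))
    first_idx = int(np.searchsorted(t_ms, 0.0, side="right"))  # first t > 0

    times = []
    for frac in (0.2, 0.5):
        thr = baseline + frac * peak_amp
        i = peak_idx
        # walk back while still above threshold and after stimulus onset
        while i > first_idx and trace[i - 1] >= thr:
            i -= 1
        if i == first_idx and trace[i] >= thr:
            # already above threshold at the first post-stimulus sample:
            # the rise is sub-sample, no crossing resolvable in the window
            times.append(None)
            continue
        if trace[i] >= thr and i > 0:
            times.append(_interp_crossing(t_ms, trace, i - 1, thr))
        else:
            times.append(None)
    t20, t50 = times
    if t20 is None or t50 is None or not (t20 < t50):
        return None, None
    return t20, t50


def compute_slope(
    t_ms: np.ndarray,
    trace: np.ndarray,
    t20_ms: Optional[float],
    t50_ms: Optional[float],
) -> Optional[float]:
    """OLS slope (mV/ms) of the trace over [t20, t50]; None if undefined.

    The trace is resampled uniformly over the closed interval (linear
    interpolation between samples) before the least-squares fit, so the fit
    covers the full 20-50% rise period even when the digitization grid is
    coarse relative to the rise time; when the interval contains no interior
    sample this reduces to the secant through the interpolated endpoints.
    """
    if t20_ms is None or t50_ms is None:
        return None
    tg = np.linspace(t20_ms, t50_ms, 201)
    vg = np.interp(tg, t_ms, trace)
    return float(np.polyfit(tg, vg, 1)[0])


def extract_features(
    sweeps: SweepSet, params: FeatureParams | None = None
) -> EPSPFeatures:
    """Full feature chain: average -> baseline -> peak -> crossings -> slope."""
    params = params or FeatureParams()
    t_ms, mean = average_trace(sweeps)
    baseline = compute_baseline(t_ms, mean, params.baseline_window_ms)
    peak_amp, peak_lat = compute_peak(t_ms, mean, baseline, params.peak_window_ms)
    t20, t50 = compute_rise_crossings(t_ms, mean, baseline, peak_amp, peak_lat)
    slope = compute_slope(t_ms, mean, t20, t50)
    return EPSPFeatures(
        cell_id=sweeps.cell_id,
        baseline_mV=baseline,
        peak_amp_mV=peak_amp,
        peak_latency_ms=peak_lat,
        t20_ms=t20,
        t50_ms=t50,
        slope_mV_per_ms=slope,
    )


def extract_all(sweepsets, params: FeatureParams | None = None) -> list[EPSPFeatures]:
    return [extract_features(s, params) for s in sweepsets]
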