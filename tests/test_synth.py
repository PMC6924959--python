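"""Generative simulator: determinism, noise statistics, consistency."""

import numpy as np
import pytest

import thalamap as tm
from thalamap.synth import group_amplitude_rvs, group_median

from conftest import SUITE_SEED, make_noiseless_config


# ----------------------------------------------------------------- waveform

def test_waveform_zero_amplitude_is_zero():
    t = np.linspace(0, 100, 1000)
    assert np.all(tm.epsp_waveform(0.0, 2, 40, t) == 0.0)


def test_waveform_peak_matches_analytic_time_and_amplitude():
    """Analytic peak time agrees with brute-force argmax on a 1 us grid."""
    t = np.arange(0.0, 200.0, 0.001)
    w = tm.epsp_waveform(1.0, 2.0, 40.0, t)
    tstar = tm.waveform_peak_time_ms(2.0, 40.0)
    assert t[np.argmax(w)] == pytest.approx(tstar, abs=0.001)
    assert w.max() == pytest.approx(1.0, rel=1e-9)


def test_waveform_linearity():
    t = np.linspace(0, 100, 2000)
    w1 = tm.epsp_waveform(3.0, 2, 40, t)
    w2 = tm.epsp_waveform(6.0, 2, 40, t)
    assert np.allclose(w2, 2 * w1, rtol=1e-12)


def test_waveform_rejects_bad_kinetics():
    with pytest.raises(tm.DatasetError):
        tm.epsp_waveform(1.0, 40.0, 2.0, np.array([0.0]))


def test_waveform_zero_before_onset():
    t = np.array([-5.0, -0.001, 0.0])
    assert np.all(tm.epsp_waveform(1.0, 2, 40, t) == 0.0)


# ----------------------------------------------------------------- OU noise

def test_ou_variance_converges_to_sigma_squared(rng):
    """Sample variance of a long stationary OU trace approaches sigma^2."""
    sigma, tau_ms, fs = 0.3, 10.0, 20000.0
    n = 400000  # 20 s
    x = tm.ou_noise(1, n, 1.0 / fs, sigma, tau_ms, rng)[0]
    var = x.var()
    # SE of the variance of correlated samples: ~ sigma^2 sqrt(2 * 2tau/T)
    t_total_ms = n / fs * 1000.0
    se = sigma**2 * np.sqrt(4 * tau_ms / t_total_ms)
    assert abs(var - sigma**2) < 3 * se


def test_ou_autocorrelation_time_constant(rng):
    x = tm.ou_noise(200, 2000, 1.0 / 20000.0, 1.0, 10.0, rng)
    lag = 200  # = tau (10 ms at 20 kHz)
    r = np.mean(x[:, :-lag] * x[:, lag:])
    assert r == pytest.approx(np.exp(-1.0), abs=0.05)


# ------------------------------------------------------- group distribution

def test_group_draws_match_requested_moments(rng):
    mean, sd = 0.39, 0.79
    x = group_amplitude_rvs(mean, sd, 200000, rng)
    assert x.min() >= 0
    assert x.mean() == pytest.approx(mean, rel=0.02)
    assert x.std() == pytest.approx(sd, rel=0.05)
    assert np.median(x) == pytest.approx(group_median(mean, sd), rel=0.02)


def test_group_draws_degenerate_cases(rng):
    assert np.all(group_amplitude_rvs(0.0, 0.5, 10, rng) == 0.0)
    assert np.all(group_amplitude_rvs(0.7, 0.0, 10, rng) == 0.7)


# ------------------------------------------------------------ simulate_cell

def _meta(cond="control", ct="EXC"):
    return tm.CellMeta("c0", "sl0", "m0", "VPM", ct, "L4", None, cond)


def test_noiseless_cell_is_deterministic_and_recovers_amplitude():
    cfg = make_noiseless_config()
    rng = np.random.default_rng(SUITE_SEED)
    ss = tm.simulate_cell(_meta(), 5.0, cfg, rng)
    assert np.array_equal(ss.trials[0], ss.trials[1])
    f = tm.extract_features(ss)
    assert f.peak_amp_mV == pytest.approx(5.0, rel=1e-3)


def test_cnqx_cell_bounded_by_noise_envelope():
    cfg = tm.default_config("VPM", trace_len_s=0.24, stim_onset_s=0.11)
    rng = np.random.default_rng(SUITE_SEED)
    ss = tm.simulate_cell(_meta("CNQX_APV"), 14.5, cfg, rng)
    assert np.abs(ss.trials - cfg.v_rest_mV).max() < 6 * cfg.ou_sigma_mV


def test_zero_drift_late_timepoint_matches_control():
    cfg = make_noiseless_config(drift_per_hour=0.0)
    rng = np.random.default_rng(SUITE_SEED)
    a = tm.simulate_cell(_meta("control"), 7.0, cfg, rng)
    b = tm.simulate_cell(_meta("late_timepoint"), 7.0, cfg, rng)
    fa, fb = tm.extract_features(a), tm.extract_features(b)
    assert fb.peak_amp_mV == pytest.approx(fa.peak_amp_mV, rel=1e-9)


def test_nonzero_drift_scales_amplitude():
    cfg = make_noiseless_config(drift_per_hour=-0.2)
    rng = np.random.default_rng(SUITE_SEED)
    late = tm.simulate_cell(_meta("late_timepoint"), 10.0, cfg, rng)
    f = tm.extract_features(late)
    assert f.peak_amp_mV == pytest.approx(8.0, rel=1e-3)


# --------------------------------------------------------- simulate_dataset

def test_same_seed_gives_identical_datasets():
    cfg = tm.default_config(
        "VPM", n_slices=2,
        group_params={("EXC", "L4"): tm.GroupParams(1.0, 0.37, 4),
                      ("PV", "L4"): tm.GroupParams(1.15, 0.92, 2)},
        trace_len_s=0.22, stim_onset_s=0.11, seed=7,
    )
    s1, m1 = tm.simulate_dataset(cfg)
    s2, m2 = tm.simulate_dataset(cfg)
    assert m1 == m2
    for a, b in zip(s1, s2):
        assert a.cell_id == b.cell_id
        assert np.array_equal(a.trials, b.trials)


def test_degenerate_reference_group_equals_slice_scale():
    """With unit reference mean, zero SD and no noise, every reference
    cell's measured amplitude equals its slice's absolute scale."""
    cfg = make_noiseless_config(
        n_slices=3,
        group_params={("EXC", "L4"): tm.GroupParams(1.0, 0.0, 6)},
        ref_abs_amp_sigma_log=0.5,
        seed=11,
    )
    sweeps, metas, truth = tm.simulate_dataset(cfg, return_truth=True)
    for s, m in zip(sweeps, metas):
        f = tm.extract_features(s)
        assert f.peak_amp_mV == pytest.approx(
            truth[m.cell_id]["ref_abs_amp_mV"], rel=1e-3
        )


def test_slice_without_reference_cells_is_an_error():
    with pytest.raises(tm.DatasetError, match="reference"):
        tm.simulate_dataset(
            tm.default_config(
                "VPM", n_slices=5,
                group_params={("EXC", "L4"): tm.GroupParams(1.0, 0.37, 3)},
            )
        )
    with pytest.raises(tm.DatasetError, match="reference"):
        tm.simulate_dataset(
            tm.default_config(
                "VPM", n_slices=2,
                group_params={("EXC", "L3"): tm.GroupParams(1.0, 0.37, 8)},
            )
        )


def test_generative_consistency_noiseless_pipeline(small_cohort):
    """With noise off, the pipeline returns each cell's drawn normalized
    amplitude: extraction + normalization invert the generative model."""
    cfg = make_noiseless_config(
        n_slices=3,
        group_params={
            ("EXC", "L4"): tm.GroupParams(1.0, 0.37, 6),
            ("EXC", "L3"): tm.GroupParams(0.46, 0.50, 5),
            ("PV", "L4"): tm.GroupParams(1.15, 0.92, 3),
        },
        ref_abs_amp_sigma_log=0.4,
        seed=13,
    )
    sweeps, metas, truth = tm.simulate_dataset(cfg, return_truth=True)
    feats = tm.extract_all(sweeps)
    norm = tm.normalize_slice(feats, metas, "VPM")
    meta_by = {m.cell_id: m for m in metas}
    # realized per-slice reference means of the generative draws
    ref_mean = {}
    for m in metas:
        if m.cell_type == "EXC" and m.layer == "L4":
            ref_mean.setdefault(m.slice_id, []).append(truth[m.cell_id]["g"])
    ref_mean = {k: np.mean(v) for k, v in ref_mean.items()}
    for nf in norm:
        m = meta_by[nf.cell_id]
        expected = truth[nf.cell_id]["g"] / ref_mean[m.slice_id]
        tol = 1e-6 if m.cell_type == "EXC" else 1e-3  # grid factor per kinetics
        assert nf.norm_amp == pytest.approx(expected, rel=tol)


def test_monotonicity_in_group_mean():
    """Raising a group's generative mean raises its extracted group mean."""
    means = []
    for mu in (0.2, 0.8):
        cfg = tm.default_config(
            "VPM", n_slices=4,
            group_params={("EXC", "L4"): tm.GroupParams(1.0, 0.37, 8),
                          ("EXC", "L3"): tm.GroupParams(mu, 0.3, 12)},
            trace_len_s=0.22, stim_onset_s=0.11, seed=5,
        )
        sweeps, metas = tm.simulate_dataset(cfg)
        pooled = tm.pool_groups(
            tm.normalize_slice(tm.extract_all(sweeps), metas, "VPM"), metas
        )
        row = pooled[(pooled.cell_type == "EXC") & (pooled.layer == "L3")]
        means.append(float(row.amp_mean.iloc[0]))
    assert means[1] > means[0]


def test_config_yaml_round_trip(tmp_path):
    cfg = tm.default_config("POm", seed=42)
    path = tmp_path / "cfg.yaml"
    tm.save_config(cfg, path)
    back = tm.load_config(path)
    assert back == cfg
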