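"""Denoising chain: FD, censoring, gates, 36-parameter regression, band-pass."""

import numpy as np
import pytest

from delnet.denoise import (GateResult, MotionRecord, RankDeficiencyWarning,
                            RoiTimeSeriesMatrix, bandpass, build_36p_design,
                            censor_volumes, compute_fd, denoise_subject,
                            drop_initial_volumes, duration_gate,
                            nuisance_regress, subject_motion_gate)
from delnet.synthetic import SimulationConfig, simulate_subject, \
    gen_base_correlation


def make_series(n_regions=5, n_volumes=238, tr=2.0, rng=None):
    rng = rng or np.random.default_rng(0)
    return RoiTimeSeriesMatrix(rng.standard_normal((n_regions, n_volumes)), tr)


# ---------------------------------------------------------------------------
# initial-volume deletion


def test_drop_initial_volumes_counts():
    s = make_series(n_volumes=238)
    out = drop_initial_volumes(s)
    assert out.n_volumes == 223
    out = drop_initial_volumes(make_series(n_volumes=16))
    assert out.n_volumes == 1
    with pytest.raises(ValueError):
        drop_initial_volumes(make_series(n_volumes=15))


def test_drop_initial_volumes_trims_paired_motion():
    s = make_series(n_volumes=30)
    m = MotionRecord(np.arange(180, dtype=float).reshape(30, 6))
    s2, m2 = drop_initial_volumes(s, m, n_drop=5)
    assert s2.n_volumes == 25 and m2.n_volumes == 25
    assert m2.params[0, 0] == 30.0


# ---------------------------------------------------------------------------
# framewise displacement


def test_fd_constant_parameters_zero():
    m = MotionRecord(np.ones((10, 6)))
    assert np.all(compute_fd(m) == 0)


def test_fd_translation_and_rotation_steps():
    p = np.zeros((4, 6))
    p[2:, 3] = 0.1  # x translation step of 0.1 mm at volume 2
    fd = compute_fd(MotionRecord(p))
    assert fd[0] == 0 and fd[1] == 0
    assert fd[2] == pytest.approx(0.1)
    assert fd[3] == 0
    p = np.zeros((3, 6))
    p[1:, 0] = 0.002  # rotation step of 0.002 rad -> 50 * 0.002 = 0.1 mm
    assert compute_fd(MotionRecord(p))[1] == pytest.approx(0.1)


# ---------------------------------------------------------------------------
# censoring and gates


def test_censoring_is_strict_and_keeps_values():
    s = make_series(n_volumes=5)
    fd = np.array([0.0, 0.1, 0.25, 0.3, 0.05])
    out = censor_volumes(s, fd)
    assert list(np.flatnonzero(out.retained_mask)) == [0, 1, 4]
    assert np.array_equal(out.values, s.values)  # values never altered
    # exact threshold is retained ("exceeded" is strict)
    out = censor_volumes(s, np.array([0.0, 0.2, 0.2, 0.2, 0.2]))
    assert out.retained_mask.all()
    out = censor_volumes(s, np.full(5, 0.05))
    assert out.retained_mask.all()


def test_subject_motion_gate_strict_threshold():
    assert not subject_motion_gate(MotionRecord(np.zeros((3, 6)),
                                                mean_rel_displacement=0.21))
    assert subject_motion_gate(MotionRecord(np.zeros((3, 6)),
                                            mean_rel_displacement=0.2))
    assert subject_motion_gate(MotionRecord(np.zeros((3, 6)),
                                            mean_rel_displacement=0.05))
    res = subject_motion_gate(None)
    assert not res and res.reason == "missing_motion"


def test_motion_gate_mean_fd_proxy():
    p = np.zeros((5, 6))
    p[1:, 3] = np.cumsum([0.5, 0.5, 0.5, 0.5])  # fd = 0.5 from volume 1
    res = subject_motion_gate(MotionRecord(p))
    assert not res and res.reason == "motion"
    assert res.value == pytest.approx(0.4)  # mean of [0, .5, .5, .5, .5]


def test_duration_gate_boundaries():
    def series_with_retained(k, total=300, tr=2.0):
        s = make_series(n_volumes=total, tr=tr)
        s.retained_mask[:] = False
        s.retained_mask[:k] = True
        return s

    assert duration_gate(series_with_retained(120))        # 240 s: strict "<"
    assert not duration_gate(series_with_retained(119))    # 238 s
    assert duration_gate(series_with_retained(223))


# ---------------------------------------------------------------------------
# 36-parameter design and regression


def test_36p_design_structure(rng):
    m = MotionRecord(rng.standard_normal((50, 6)))
    wm, csf, gs = rng.standard_normal((3, 50))
    d = build_36p_design(m, wm, csf, gs)
    assert d.columns.shape == (50, 36)
    assert len(set(d.column_names)) == 36
    # derivative columns start at 0, squares are elementwise squares
    base = d.columns[:, :9]
    deriv = d.columns[:, 9:18]
    assert np.all(deriv[0] == 0)
    assert np.allclose(deriv[1:], np.diff(base, axis=0))
    assert np.allclose(d.columns[:, 18:27], base**2)
    assert np.allclose(d.columns[:, 27:], deriv**2)


def test_36p_design_constant_column_and_rank_warning(rng):
    m = MotionRecord(np.zeros((40, 6)))
    with pytest.warns(RankDeficiencyWarning):
        d = build_36p_design(m, np.zeros(40), np.zeros(40), np.zeros(40))
    assert np.all(d.columns == 0)
    # constant (non-zero) base column has an all-zero derivative
    p = rng.standard_normal((40, 6))
    p[:, 2] = 3.14
    d = build_36p_design(MotionRecord(p), *rng.standard_normal((3, 40)))
    assert np.all(d.columns[:, 9 + 2] == 0)


def test_regression_orthogonality_and_oracle(rng):
    """Residuals match the explicit normal-equations solution."""
    m = MotionRecord(rng.standard_normal((100, 6)))
    wm, csf, gs = rng.standard_normal((3, 100))
    d = build_36p_design(m, wm, csf, gs)
    s = make_series(n_regions=10, n_volumes=100, rng=rng)
    out = nuisance_regress(s, d)
    X = np.column_stack([np.ones(100), d.columns])
    # independent oracle: beta = (X'X)^-1 X'y per region
    beta = np.linalg.solve(X.T @ X, X.T @ s.values.T)
    oracle = s.values.T - X @ beta
    assert np.allclose(out.values, oracle.T, atol=1e-8)
    # orthogonality to every design column
    dots = out.values @ d.columns
    scale = np.abs(s.values @ d.columns).max()
    assert np.abs(dots).max() <= 1e-8 * max(scale, 1.0)


def test_regression_reproduces_design_column_and_is_idempotent(rng):
    m = MotionRecord(rng.standard_normal((80, 6)))
    d = build_36p_design(m, *rng.standard_normal((3, 80)))
    vals = np.vstack([d.columns[:, 4], rng.standard_normal(80)])
    s = RoiTimeSeriesMatrix(vals, 2.0)
    out = nuisance_regress(s, d)
    assert np.abs(out.values[0]).max() < 1e-10  # a design column regresses to 0
    twice = nuisance_regress(out, d)
    assert np.allclose(twice.values, out.values, atol=1e-8)


# ---------------------------------------------------------------------------
# band-pass


def sine_series(freq_hz, tr=2.0, n=223):
    t = np.arange(n) * tr
    return RoiTimeSeriesMatrix(np.sin(2 * np.pi * freq_hz * t)[None, :], tr)


def amplitude_ratio(freq_hz):
    s = sine_series(freq_hz)
    out = bandpass(s)
    # compare RMS over the central portion to avoid edge transients
    sl = slice(40, -40)
    return float(np.sqrt(np.mean(out.values[0, sl] ** 2) /
                         np.mean(s.values[0, sl] ** 2)))


def test_bandpass_pass_and_stop_bands():
    assert amplitude_ratio(0.04) >= 0.9   # pass band
    assert amplitude_ratio(0.2) <= 0.1    # stop band (2.5x the high cut)


def test_bandpass_removes_dc_and_validates_band():
    s = RoiTimeSeriesMatrix(np.full((2, 200), 7.0), 2.0)
    out = bandpass(s)
    assert np.abs(out.values).max() < 1e-6
    with pytest.raises(ValueError):
        bandpass(make_series(), low_hz=0.01, high_hz=0.3)  # above Nyquist
    with pytest.raises(ValueError):
        bandpass(make_series(), low_hz=0.0, high_hz=0.08)


# ---------------------------------------------------------------------------
# end-to-end subject chain


def test_censored_volumes_equal_constructed_spikes():
    """Spike-only contamination: censored set == constructed spike set."""
    cfg = SimulationConfig(n_subjects=1, n_regions=12, n_volumes=238,
                           n_modules=3, motion_spike_prob=0.12, seed=42)
    base = gen_base_correlation(cfg)
    sub = simulate_subject(cfg, base, 0, 0.0)
    res = denoise_subject(sub.series, sub.motion, sub.wm, sub.csf,
                          sub.global_sig)
    assert res.passed
    censored = np.flatnonzero(~res.series.retained_mask)
    spikes = np.flatnonzero(sub.spikes[15:])  # after initial-volume deletion
    assert np.array_equal(censored, spikes)
    assert res.qc["n_censored"] == len(spikes)


def test_denoise_subject_gates_report_reasons():
    cfg = SimulationConfig(n_subjects=1, n_regions=10, n_volumes=238,
                           n_modules=2, motion_spike_prob=0.9, seed=3)
    base = gen_base_correlation(cfg)
    sub = simulate_subject(cfg, base, 0, 0.0)
    res = denoise_subject(sub.series, sub.motion, sub.wm, sub.csf,
                          sub.global_sig)
    # with 90% spikes the mean-displacement gate must trip
    assert not res.passed and res.reason == "motion"
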