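"""Reporter-trace pipeline: detrending, smoothing, damped-cosine fits."""

import numpy as np
import pytest

from circlock import lumi
from circlock.lumi import (
    CosineFit,
    FixtureSpec,
    LuminescenceTrace,
    detrend,
    fit_damped_cosine,
    fold_change_vs_control,
    generate_fixture,
    smooth,
)


def flat_trace(value=100.0, t_end=7 * 24.0, dt=0.5):
    t = np.arange(0.0, t_end + dt / 2, dt)
    return LuminescenceTrace(t, np.full_like(t, value), condition="flat")


def test_trace_invariants_enforced():
    t = np.arange(0, 48.5, 0.5)
    with pytest.raises(ValueError):
        LuminescenceTrace(t, -np.ones_like(t))
    with pytest.raises(ValueError):
        LuminescenceTrace(t[::-1], np.ones_like(t))


def test_detrending_a_constant_gives_unity():
    d = detrend(flat_trace())
    np.testing.assert_allclose(d.counts, 1.0)


def test_detrending_removes_exponential_trend():
    """trend x cosine: after dividing by the 24 h running mean of the
    trend the residual is ~ 1 + cosine (the analytic running mean of
    exp(-kt) over +/-12 h equals exp(-kt)*sinh(12k)/(12k))."""
    t = np.arange(0.0, 7 * 24.0 + 0.25, 0.5)
    k = 0.01
    osc = 0.3 * np.cos(2 * np.pi * t / 24.0)
    raw = 500.0 * np.exp(-k * t) * (1.0 + osc)
    d = detrend(LuminescenceTrace(t, raw))
    interior = (t > 24.0) & (t < t[-1] - 24.0)
    # cosine averages out of the running mean; trend correction factor:
    expected = (1.0 + osc) * (12 * k) / np.sinh(12 * k)
    # small trend-x-cosine cross term remains in the running mean: O(k*A)
    assert np.max(np.abs(d.counts[interior] - expected[interior])) < 0.02


def test_detrending_is_nearly_idempotent():
    # residual ripple after one pass scales like amplitude*damping*P/2pi,
    # so a moderately damped fixture stays within the 1% band
    traces = generate_fixture(FixtureSpec(damping=0.005, noise_sd=5.0, seed=3))
    once = detrend(traces[0])
    twice = detrend(once)
    interior = (once.times > 24.0) & (once.times < once.times[-1] - 24.0)
    rel = np.abs(twice.counts - once.counts)[interior] / once.counts[interior]
    assert np.max(rel) < 0.01


def test_detrend_rejects_short_traces():
    t = np.arange(0.0, 20.0, 0.5)
    with pytest.raises(ValueError):
        detrend(LuminescenceTrace(t, np.ones_like(t)))


def test_smoothing_constant_unchanged_and_ramp_interior_unchanged():
    s = smooth(flat_trace(5.0))
    np.testing.assert_allclose(s.counts, 5.0)
    t = np.arange(0.0, 48.5, 0.5)
    ramp = LuminescenceTrace(t, 10.0 + 2.0 * t)
    s = smooth(ramp)
    interior = (t >= 2.0) & (t <= 46.0)
    np.testing.assert_allclose(s.counts[interior], ramp.counts[interior],
                               rtol=1e-12)


def test_smoothing_reduces_white_noise_sd_by_sqrt_window():
    rng = np.random.default_rng(11)
    t = np.arange(0.0, 96.25, 0.5)
    sigma = 5.0
    tr = LuminescenceTrace(t, 100.0 + rng.normal(0, sigma, t.shape))
    s = smooth(tr)
    interior = (t > 2.0) & (t < 94.0)
    # 4 h window at 0.5 h sampling averages ~8-9 samples
    assert np.std(s.counts[interior]) == pytest.approx(
        sigma / np.sqrt(8), rel=0.35
    )


def test_noiseless_fit_recovers_period_and_damping():
    spec = FixtureSpec(period=24.0, damping=0.01, noise_sd=0.0, seed=0)
    trace = generate_fixture(spec)[0]
    fit = fit_damped_cosine(detrend(trace))
    assert fit.converged
    assert fit.period == pytest.approx(24.0, abs=0.05)
    assert fit.damping == pytest.approx(0.01, rel=0.10)


def test_undamped_fixture_fits_negligible_damping():
    spec = FixtureSpec(period=24.0, damping=0.0, trend_decay=0.0, seed=0)
    fit = fit_damped_cosine(detrend(generate_fixture(spec)[0]))
    assert fit.damping <= 1e-3


def test_noisy_replicates_recover_period_within_tolerance():
    errors = []
    for seed in range(20):
        spec = FixtureSpec(
            period=24.0, damping=0.008, amplitude=0.4,
            noise_sd=0.1 * 0.4 * 1000.0, seed=seed,
        )
        fit = fit_damped_cosine(detrend(generate_fixture(spec)[0]))
        errors.append(abs(fit.period - 24.0))
    assert np.median(errors) < 0.3


def test_fit_requires_two_cycles():
    t = np.arange(0.0, 30.0, 0.5)
    with pytest.raises(ValueError):
        fit_damped_cosine(LuminescenceTrace(t, np.ones_like(t)))


def test_fold_change_identity_and_doubling():
    ctrl = generate_fixture(FixtureSpec(seed=1, n_replicates=2))
    fold, _ = fold_change_vs_control(ctrl, ctrl)
    assert fold == pytest.approx(1.0)
    doubled = [
        LuminescenceTrace(tr.times, 2 * tr.counts, "2x", tr.replicate)
        for tr in ctrl
    ]
    fold, scaled = fold_change_vs_control(doubled, ctrl)
    assert fold == pytest.approx(2.0)
    # the scale is applied to the detrended traces
    assert np.mean(scaled[0].counts) == pytest.approx(2.0, rel=0.02)


def test_fold_change_rejects_zero_control():
    ctrl = [flat_trace(0.0)]
    cond = [flat_trace(10.0)]
    with pytest.raises(ValueError):
        fold_change_vs_control(cond, ctrl)


def test_fixture_generation_is_seed_deterministic():
    spec = FixtureSpec(noise_sd=30.0, n_replicates=3, seed=1)
    a, b = generate_fixture(spec), generate_fixture(spec)
    for ta, tb in zip(a, b):
        assert np.array_equal(ta.counts, tb.counts)


def test_overexpression_like_fixture_shows_fold_below_one_and_more_damping():
    """A lower-magnitude, faster-damping condition (the repressor
    overexpression signature) yields fold < 1 and larger fitted damping
    than its control."""
    ctrl_spec = FixtureSpec(period=24.0, damping=0.005, baseline=1000.0,
                            noise_sd=10.0, seed=5, condition="control")
    cond_spec = FixtureSpec(period=24.0, damping=0.03, baseline=400.0,
                            noise_sd=10.0, seed=6, condition="repressorOE")
    ctrl = generate_fixture(ctrl_spec)
    cond = generate_fixture(cond_spec)
    fold, _ = fold_change_vs_control(cond, ctrl)
    assert fold < 1.0
    fit_ctrl = fit_damped_cosine(detrend(ctrl[0]))
    fit_cond = fit_damped_cosine(detrend(cond[0]))
    assert fit_cond.damping > fit_ctrl.damping


def test_plate_csv_roundtrip(tmp_path):
    spec = FixtureSpec(noise_sd=5.0, n_replicates=2, seed=9, condition="GFP")
    traces = generate_fixture(spec)
    path = tmp_path / "plate.csv"
    lumi.write_plate_csv(traces, path)
    back = lumi.read_plate_csv(path)
    assert len(back) == 2
    np.testing.assert_allclose(back[0].counts, traces[0].counts)
    report = lumi.fit_report(back)
    assert {"period_h", "damping_per_h", "converged"} <= set(report.columns)
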