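"""Rhythm metrics on analytic signals with known ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.interpolate import CubicSpline

import circlock as cl
from circlock import rhythms
from circlock.rhythms import (
    ArrhythmicError,
    PhenotypeClass,
    classify_phenotype,
    estimate_period,
    find_peaks,
    inhibition_release_times,
    mean_level,
    spectral_period,
    summarize,
)


def cosine(period=24.0, amplitude=1.0, mean=2.0, damping=0.0, phase=0.0):
    def f(t):
        return mean + amplitude * np.exp(-damping * t) * np.cos(
            2 * np.pi * (t - phase) / period
        )
    return f


def pool_trajectory(make_synthetic_trajectory, signal_fn, **kw):
    """Synthetic trajectory carrying the signal on both pool complexes."""
    traj = make_synthetic_trajectory(signal_fn, **kw)
    states = traj.states.copy()
    states[:, 1] = traj.states[:, 0] / 2
    states[:, 2] = traj.states[:, 0] / 2
    return cl.Trajectory(traj.times, states, traj.settings)


def test_peaks_of_pure_cosine_found_at_multiples_of_period(
    make_synthetic_trajectory,
):
    traj = make_synthetic_trajectory(cosine(24.0), t_end=72.0, dt=0.01)
    peaks = find_peaks(traj, "CLOCK/BMAL", window=(0.0, 72.0))
    times = [t for t, _ in peaks]
    # interior peaks (t=0/72 are window edges and not strict maxima)
    assert times == pytest.approx([24.0, 48.0], abs=0.005)


def test_constant_series_has_no_peaks(make_synthetic_trajectory):
    traj = make_synthetic_trajectory(lambda t: np.full_like(t, 3.0), t_end=48.0)
    assert find_peaks(traj, "CLOCK/BMAL", window=(0.0, 48.0)) == []
    with pytest.raises(ArrhythmicError):
        estimate_period(traj, "CLOCK/BMAL", window=(0.0, 48.0))


def test_refined_peaks_match_dense_spline_argmax(make_synthetic_trajectory):
    """Quadratic refinement agrees with brute-force argmax on a 1e-4 h
    resampled cubic spline to <= 0.01 h."""
    sig = cosine(23.1, amplitude=0.7, damping=0.004, phase=3.3)
    traj = make_synthetic_trajectory(sig, t_end=120.0, dt=0.05)
    spline = CubicSpline(traj.times, traj.states[:, 0])
    for t_peak, _ in find_peaks(traj, "CLOCK/BMAL", window=(0.0, 120.0)):
        dense = np.arange(t_peak - 1.0, t_peak + 1.0, 1e-4)
        brute = dense[np.argmax(spline(dense))]
        assert abs(t_peak - brute) <= 0.01


@pytest.mark.parametrize("true_period", [20.0, 23.5, 28.0])
@pytest.mark.parametrize("per_cycle_damping", [1.0, 0.85, 0.7])
def test_period_recovered_on_damped_cosines(
    make_synthetic_trajectory, true_period, per_cycle_damping
):
    lam = -np.log(per_cycle_damping) / true_period
    traj = make_synthetic_trajectory(
        cosine(true_period, damping=lam), t_end=10 * 24.0, dt=0.05
    )
    p = estimate_period(traj, "CLOCK/BMAL", window=(0.0, 240.0))
    assert p == pytest.approx(true_period, rel=0.005)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(
    period=st.floats(18.0, 30.0),
    phase=st.floats(0.0, 30.0),
    per_cycle=st.floats(0.7, 1.0),
    mean=st.floats(0.5, 5.0),
)
def test_period_estimation_property_over_waveform_space(
    period, phase, per_cycle, mean
):
    """Any damped cosine with >= 0.7/cycle persistence is recovered to
    0.5% regardless of phase, mean level or damping."""
    lam = -np.log(per_cycle) / period
    times = np.arange(0.0, 240.0 + 0.025, 0.05)
    states = np.ones((len(times), 19))
    states[:, 0] = cosine(period, amplitude=0.4 * mean, mean=mean,
                          damping=lam, phase=phase)(times)
    traj = cl.Trajectory(
        times, states,
        cl.SimulationSettings(t_end=240.0, output_step=0.05,
                              transient_discard=0.0),
    )
    p = estimate_period(traj, "CLOCK/BMAL", window=(0.0, 240.0))
    assert abs(p - period) / period < 0.005


def test_peak_and_spectral_period_agree_on_clean_signal(
    make_synthetic_trajectory,
):
    traj = make_synthetic_trajectory(cosine(24.0), t_end=20 * 24.0, dt=0.05)
    p_peak = estimate_period(traj, "CLOCK/BMAL", window=(0.0, 480.0))
    p_spec = spectral_period(traj, "CLOCK/BMAL", window=(0.0, 480.0))
    assert p_peak == pytest.approx(24.0, abs=0.01)
    assert p_spec == pytest.approx(24.0, rel=0.05)  # periodogram bin width


def test_mean_level_is_cycle_average_not_window_average(
    make_synthetic_trajectory,
):
    # a window of 4.6 cycles: plain averaging is biased, cycle-trimmed is not
    traj = make_synthetic_trajectory(cosine(24.0, mean=2.0), t_end=110.4, dt=0.01)
    m = mean_level(traj, "CLOCK/BMAL", window=(0.0, 110.4))
    assert m == pytest.approx(2.0, abs=0.01)


def test_pure_cosine_pool_has_symmetric_inhibition_release(
    make_synthetic_trajectory,
):
    traj = pool_trajectory(
        make_synthetic_trajectory, cosine(24.0), t_end=120.0, dt=0.01
    )
    timing = inhibition_release_times(traj, window=(0.0, 120.0))
    assert timing.it == pytest.approx(12.0, abs=0.05)
    assert timing.rt == pytest.approx(12.0, abs=0.05)


def test_inhibition_plus_release_partitions_the_period(wt_trajectory):
    timing = inhibition_release_times(wt_trajectory)
    period = estimate_period(wt_trajectory, "percry_pool")
    assert timing.it + timing.rt == pytest.approx(period, abs=0.1)
    assert timing.it > 0 and timing.rt > 0


def test_summary_classes_on_synthetic_signals(make_synthetic_trajectory):
    sustained = make_synthetic_trajectory(cosine(24.0), t_end=240.0, dt=0.05)
    s = summarize(sustained, "CLOCK/BMAL", window=(0.0, 240.0))
    assert s.oscillation_class == "sustained"
    assert s.damping_ratio == pytest.approx(1.0, abs=0.01)

    lam = -np.log(0.6) / 24.0  # 0.6 per cycle: damped
    damped = make_synthetic_trajectory(
        cosine(24.0, damping=lam), t_end=240.0, dt=0.05
    )
    s = summarize(damped, "CLOCK/BMAL", window=(0.0, 240.0),
                  wt_relative_amplitude=1.0)
    assert s.oscillation_class == "damped"
    assert s.damping_ratio == pytest.approx(0.6, abs=0.05)

    flat = make_synthetic_trajectory(
        lambda t: 2.0 + 1e-5 * np.cos(2 * np.pi * t / 24.0),
        t_end=240.0, dt=0.05,
    )
    s = summarize(flat, "CLOCK/BMAL", window=(0.0, 240.0),
                  wt_relative_amplitude=1.0)
    assert s.oscillation_class == "arrhythmic"


def make_wt_summary():
    return rhythms.RhythmSummary(
        period=23.5, period_sd=0.0, relative_amplitude=1.0, mean_level=1.0,
        peak_time=0.0, damping_ratio=1.0, oscillation_class="sustained",
    )


@pytest.mark.parametrize("factor,expected", [
    (1.005, PhenotypeClass.WT),     # +0.5%: inside the +/-1% band
    (1.02, PhenotypeClass.PLUS),
    (0.98, PhenotypeClass.MINUS),
])
def test_period_change_classification_rule(
    make_synthetic_trajectory, factor, expected
):
    traj = make_synthetic_trajectory(
        cosine(23.5 * factor), t_end=24 * 24.0, dt=0.05
    )
    assert classify_phenotype(make_wt_summary(), traj, "CLOCK/BMAL") is expected


def test_damped_signal_classifies_arrhythmic_with_short_transient_flagged(
    make_synthetic_trajectory,
):
    # shortened period early, oscillation gone late -> "- then AR"
    def sig(t):
        return 1.0 + np.exp(-t / 40.0) * np.cos(2 * np.pi * t / 21.0)

    traj = make_synthetic_trajectory(sig, t_end=24 * 24.0, dt=0.05)
    label = classify_phenotype(make_wt_summary(), traj, "CLOCK/BMAL")
    assert label is PhenotypeClass.MINUS_THEN_AR

    # same decay but wild-type period -> plain AR
    def sig2(t):
        return 1.0 + np.exp(-t / 40.0) * np.cos(2 * np.pi * t / 23.5)

    traj2 = make_synthetic_trajectory(sig2, t_end=24 * 24.0, dt=0.05)
    assert classify_phenotype(make_wt_summary(), traj2, "CLOCK/BMAL") is (
        PhenotypeClass.AR
    )
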