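"""Rhythm metrics: period, amplitude, phase, damping, phenotype classes.

Period estimation is peak-based (mean successive peak-to-peak interval
with quadratic sub-grid refinement), matching how this model family
reasons about waveforms (inhibition/release times are peak/trough
quantities).  A periodogram estimator is provided as a diagnostic
cross-check only.

Phenotype coding follows the standard in-silico mutant convention:
``+``/``-`` for a period change of more than 1% of wild type, ``WT``
within +/-1%, ``AR`` when oscillations damp out or vanish, and
``- then AR`` when a shortened-period transient precedes arrhythmicity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

from .simulate import Trajectory

__all__ = [
    "ArrhythmicError",
    "RhythmSummary",
    "PhenotypeClass",
    "InhibitionTiming",
    "find_peaks",
    "find_troughs",
    "estimate_period",
    "mean_level",
    "summarize",
    "classify_phenotype",
    "inhibition_release_times",
    "peak_phase",
    "spectral_period",
]

#: per-cycle damping-ratio band separating sustained / damped / arrhythmic
DAMPING_SUSTAINED = 0.95
DAMPING_VANISHED = 0.2
#: relative-amplitude floor (fraction of the WT relative amplitude) below
#: which a signal counts as flat
AMPLITUDE_FLOOR_FRAC = 0.01
#: period-change significance threshold of the phenotype coding
PERIOD_SIGNIFICANCE = 0.01


class ArrhythmicError(ValueError):
    """Signal has too few peaks for a period estimate."""


class PhenotypeClass(enum.Enum):
    WT = "WT"
    PLUS = "+"
    MINUS = "-"
    AR = "AR"
    MINUS_THEN_AR = "- then AR"


@dataclass(frozen=True)
class RhythmSummary:
    """Rhythm descriptors of one species over one analysis window."""

    period: float | None
    period_sd: float | None
    relative_amplitude: float
    mean_level: float
    peak_time: float | None
    damping_ratio: float | None
    oscillation_class: str  # sustained | damped | arrhythmic

    @property
    def sustained(self) -> bool:
        return self.oscillation_class == "sustained"


@dataclass(frozen=True)
class InhibitionTiming:
    """PER/CRY-pool waveform timing: trough->peak (it), peak->trough (rt)."""

    it: float
    rt: float

    @property
    def period(self) -> float:
        return self.it + self.rt


def _series_window(traj: Trajectory, species: str, window):
    t = traj.times
    x = traj.series(species)
    if window is None:
        t0, t1 = traj.settings.transient_discard, t[-1]
    else:
        t0, t1 = window
    sel = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
    if sel.sum() < 3:
        raise ValueError("window must contain at least 3 samples")
    return t[sel], x[sel]


def _refine(t, x, i):
    """Quadratic interpolation through the three samples bracketing i."""
    if i == 0 or i == len(x) - 1:
        return t[i], x[i]
    y0, y1, y2 = x[i - 1], x[i], x[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return t[i], x[i]
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    dt = t[i + 1] - t[i]
    return t[i] + delta * dt, y1 - 0.25 * (y0 - y2) * delta


def find_peaks(
    traj: Trajectory, species: str, window=None
) -> list[tuple[float, float]]:
    """Local maxima (time, value), sub-grid refined. Empty if none."""
    t, x = _series_window(traj, species, window)
    prom = 1e-8 * max(1.0, float(np.max(np.abs(x))))
    idx, _ = _scipy_find_peaks(x, prominence=prom)
    return [_refine(t, x, i) for i in idx]


def find_troughs(
    traj: Trajectory, species: str, window=None
) -> list[tuple[float, float]]:
    t, x = _series_window(traj, species, window)
    prom = 1e-8 * max(1.0, float(np.max(np.abs(x))))
    idx, _ = _scipy_find_peaks(-x, prominence=prom)
    return [(_refine(t, -x, i)[0], x[i]) for i in idx]


def estimate_period(traj: Trajectory, species: str, window=None) -> float:
    """Mean successive peak-to-peak interval, in hours."""
    period, _ = estimate_period_sd(traj, species, window)
    return period


def estimate_period_sd(
    traj: Trajectory, species: str, window=None
) -> tuple[float, float]:
    peaks = find_peaks(traj, species, window)
    if len(peaks) < 3:
        raise ArrhythmicError(
            f"{species}: {len(peaks)} peak(s) in window; need >= 3 for a period"
        )
    times = np.array([p[0] for p in peaks])
    gaps = np.diff(times)
    return float(gaps.mean()), float(gaps.std())


def mean_level(traj: Trajectory, species: str, window=None) -> float:
    """Trapezoidal time average over an integer number of cycles.

    The averaging interval is the largest whole number of periods that
    fits at the end of the window; if the signal is arrhythmic the plain
    window average is returned.
    """
    t, x = _series_window(traj, species, window)
    try:
        period = estimate_period(traj, species, window)
        n_cyc = int((t[-1] - t[0]) / period)
        if n_cyc >= 1:
            t0 = t[-1] - n_cyc * period
            sel = t >= t0 - 1e-9
            t, x = t[sel], x[sel]
    except ArrhythmicError:
        pass
    return float(np.trapezoid(x, t) / (t[-1] - t[0]))


def _damping_ratio(peak_vals, trough_vals) -> float | None:
    """Geometric-mean ratio of successive cycle amplitudes (peak - trough)."""
    n = min(len(peak_vals), len(trough_vals))
    amps = np.asarray(peak_vals[:n]) - np.asarray(trough_vals[:n])
    amps = amps[amps > 0]
    if len(amps) < 2:
        return None
    ratios = amps[1:] / amps[:-1]
    return float(np.exp(np.mean(np.log(ratios))))


def summarize(
    traj: Trajectory,
    species: str,
    window=None,
    wt_relative_amplitude: float | None = None,
) -> RhythmSummary:
    """Full rhythm summary of one species over one window.

    ``wt_relative_amplitude`` sets the flatness floor (1% of it); without
    it, an absolute floor of 1e-3 is used.
    """
    t, x = _series_window(traj, species, window)
    mean = float(np.trapezoid(x, t) / (t[-1] - t[0]))
    rel_amp = float((x.max() - x.min()) / mean) if mean > 0 else 0.0
    floor = (
        AMPLITUDE_FLOOR_FRAC * wt_relative_amplitude
        if wt_relative_amplitude is not None
        else 1e-3
    )

    peaks = find_peaks(traj, species, window)
    troughs = find_troughs(traj, species, window)
    damping = _damping_ratio(
        [v for _, v in peaks], [v for _, v in troughs]
    )

    period = period_sd = peak_time = None
    if len(peaks) >= 3:
        times = np.array([p[0] for p in peaks])
        gaps = np.diff(times)
        period, period_sd = float(gaps.mean()), float(gaps.std())
        peak_time = float(times[-1] % period)

    if rel_amp < floor or period is None or (
        damping is not None and damping < DAMPING_VANISHED
    ):
        klass = "arrhythmic"
    elif damping is not None and damping < DAMPING_SUSTAINED:
        klass = "damped"
    else:
        klass = "sustained"
    return RhythmSummary(
        period=period,
        period_sd=period_sd,
        relative_amplitude=rel_amp,
        mean_level=mean,
        peak_time=peak_time,
        damping_ratio=damping,
        oscillation_class=klass,
    )


#: windows of the phenotype coding: early transient (RNAi-style readout)
#: and the long-run steady window (last 4 simulated days)
TRANSIENT_WINDOW_H = (0.0, 6 * 24.0)
STEADY_WINDOW_DAYS = 4


def classify_phenotype(
    wt: RhythmSummary,
    traj: Trajectory,
    species: str = "Bmal",
    transient: bool = False,
) -> PhenotypeClass:
    """Phenotype of a perturbed run against the wild-type summary.

    Long-run rhythmicity is judged on the last 4 simulated days; with
    ``transient=True`` the period is scored on days 0-6 instead (the
    RNAi-transient readout), still reporting ``- then AR`` when the
    long run is arrhythmic.
    """
    if not wt.sustained or wt.period is None:
        raise ValueError("wild-type reference must be a sustained rhythm")
    t_end = traj.times[-1]
    steady = (t_end - STEADY_WINDOW_DAYS * 24.0, t_end)
    s_steady = summarize(
        traj, species, steady, wt_relative_amplitude=wt.relative_amplitude
    )

    if s_steady.oscillation_class != "sustained":
        # arrhythmic in the long run: does a shortened-period transient precede?
        try:
            p_tr = estimate_period(traj, species, TRANSIENT_WINDOW_H)
        except ArrhythmicError:
            return PhenotypeClass.AR
        if (p_tr - wt.period) / wt.period < -PERIOD_SIGNIFICANCE:
            return PhenotypeClass.MINUS_THEN_AR
        return PhenotypeClass.AR

    window = TRANSIENT_WINDOW_H if transient else steady
    try:
        period = estimate_period(traj, species, window)
    except ArrhythmicError:
        return PhenotypeClass.AR
    change = (period - wt.period) / wt.period
    if change > PERIOD_SIGNIFICANCE:
        return PhenotypeClass.PLUS
    if change < -PERIOD_SIGNIFICANCE:
        return PhenotypeClass.MINUS
    return PhenotypeClass.WT


def inhibition_release_times(traj: Trajectory, window=None) -> InhibitionTiming:
    """Mean trough->peak (it) and peak->trough (rt) times of the PER/CRY pool."""
    peaks = find_peaks(traj, "percry_pool", window)
    troughs = find_troughs(traj, "percry_pool", window)
    if len(peaks) < 1 or len(troughs) < 1:
        raise ArrhythmicError("PER/CRY pool has no full cycle in window")
    pt = [t for t, _ in peaks]
    tt = [t for t, _ in troughs]
    its, rts = [], []
    for trough in tt:
        nxt = [p for p in pt if p > trough]
        if nxt:
            its.append(nxt[0] - trough)
    for peak in pt:
        nxt = [t for t in tt if t > peak]
        if nxt:
            rts.append(nxt[0] - peak)
    if not its or not rts:
        raise ArrhythmicError("PER/CRY pool has no full cycle in window")
    return InhibitionTiming(it=float(np.mean(its)), rt=float(np.mean(rts)))


def peak_phase(
    traj: Trajectory, species: str, anchor: str = "Bmal", window=None
) -> float:
    """Peak time of ``species`` relative to the ``anchor`` peak, in hours
    within one cycle (the model has no absolute circadian-time anchor)."""
    period = estimate_period(traj, anchor, window)
    p_anchor = find_peaks(traj, anchor, window)[-1][0]
    p_species = find_peaks(traj, species, window)[-1][0]
    return float((p_species - p_anchor) % period)


def spectral_period(traj: Trajectory, species: str, window=None) -> float:
    """Periodogram-based period (diagnostic cross-check of the peak method)."""
    t, x = _series_window(traj, species, window)
    x = x - x.mean()
    dt = t[1] - t[0]
    freqs = np.fft.rfftfreq(len(x), dt)
    power = np.abs(np.fft.rfft(x * np.hanning(len(x)))) ** 2
    i = int(np.argmax(power[1:])) + 1
    return float(1.0 / freqs[i])
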