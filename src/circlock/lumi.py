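"""Bioluminescence-reporter analysis: detrend, smooth, damped-cosine fit.

Mirrors the standard plate-recording pipeline for circadian reporters
(7-day recordings at ~0.5 h sampling): raw counts are de-trended by
dividing a centered 24 h running average, periods/amplitudes come from a
least-squares damped-cosine fit of the de-trended signal, a 4 h running
average is applied for visualization only (never before fitting), and
condition traces are expressed as fold change relative to controls.

A seeded fixture generator emulates such recordings (trend x damped
cosine + noise), optionally driven by a simulated Bmal mRNA trajectory,
so the whole pipeline is testable without any recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "LuminescenceTrace",
    "CosineFit",
    "FixtureSpec",
    "detrend",
    "smooth",
    "fit_damped_cosine",
    "fold_change_vs_control",
    "generate_fixture",
    "generate_model_driven_fixture",
    "read_plate_csv",
    "write_plate_csv",
    "fit_report",
]


@dataclass(frozen=True)
class LuminescenceTrace:
    """One well's reporter time series (times in h, counts arbitrary)."""

    times: np.ndarray
    counts: np.ndarray
    condition: str = ""
    replicate: int = 0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and counts must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("counts must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "counts", c)

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])


def _running_mean(times: np.ndarray, values: np.ndarray, window: float) -> np.ndarray:
    """Centered time-based running mean; edge windows shrink."""
    half = window / 2.0
    out = np.empty_like(values)
    lo = np.searchsorted(times, times - half, side="left")
    hi = np.searchsorted(times, times + half, side="right")
    csum = np.concatenate(([0.0], np.cumsum(values)))
    for i in range(len(values)):
        out[i] = (csum[hi[i]] - csum[lo[i]]) / (hi[i] - lo[i])
    return out


def detrend(trace: LuminescenceTrace, window: float = 24.0) -> LuminescenceTrace:
    """Divide pointwise by the centered 24 h running average."""
    if trace.span <= window:
        raise ValueError(
            f"trace spans {trace.span:.1f} h; detrending needs more than "
            f"{window:.0f} h"
        )
    baseline = _running_mean(trace.times, trace.counts, window)
    if np.any(baseline <= 0):
        raise ValueError("running average hit zero; cannot divide")
    return replace(trace, counts=trace.counts / baseline)


def smooth(trace: LuminescenceTrace, window: float = 4.0) -> LuminescenceTrace:
    """Centered 4 h running average (visualization only; fit on detrended)."""
    if trace.span <= window:
        raise ValueError("trace shorter than the smoothing window")
    return replace(trace, counts=_running_mean(trace.times, trace.counts, window))


@dataclass(frozen=True)
class CosineFit:
    """baseline + amplitude * exp(-damping*t) * cos(2*pi*(t-phase)/period)"""

    period: float
    amplitude: float
    phase: float
    damping: float
    baseline: float
    rmse: float
    converged: bool

    def predict(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return self.baseline + self.amplitude * np.exp(-self.damping * t) * np.cos(
            2 * np.pi * (t - self.phase) / self.period
        )


PERIOD_RANGE = (16.0, 32.0)


def fit_damped_cosine(
    trace: LuminescenceTrace, edge_crop: float = 12.0
) -> CosineFit:
    """Least-squares damped-cosine fit of a de-trended trace.

    Multi-starts the period over 16-32 h to avoid local minima; the
    damping rate is constrained nonnegative.  Requires at least two
    short-period cycles of data.

    ``edge_crop`` drops that many hours from each end before fitting
    (when enough data remains): the shrinking edge windows of the
    running-average detrend bias those samples, and including them
    biases the fitted period.
    """
    t = trace.times
    y = trace.counts
    if edge_crop > 0 and trace.span - 2 * edge_crop >= 2 * PERIOD_RANGE[0]:
        sel = (t >= t[0] + edge_crop) & (t <= t[-1] - edge_crop)
        t, y = t[sel], y[sel]
    t = t - t[0]
    if t[-1] < 2 * PERIOD_RANGE[0]:
        raise ValueError("need at least ~2 cycles (32 h) of data to fit")

    amp0 = max(1e-6, float(np.std(y)) * np.sqrt(2.0))
    base0 = float(np.mean(y))

    def residual(theta):
        period, amp, phase, lam, base = theta
        return (
            base + amp * np.exp(-lam * t) * np.cos(2 * np.pi * (t - phase) / period)
            - y
        )

    best = None
    for period0 in np.linspace(*PERIOD_RANGE, 9):
        for phase0 in (0.0, period0 / 2.0):
            try:
                res = least_squares(
                    residual,
                    x0=[period0, amp0, phase0, 0.005, base0],
                    bounds=(
                        [PERIOD_RANGE[0], 0.0, -48.0, 0.0, -np.inf],
                        [PERIOD_RANGE[1], np.inf, 48.0, 1.0, np.inf],
                    ),
                    method="trf",
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        return CosineFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.inf, False)
    period, amp, phase, lam, base = best.x
    if amp < 0:  # canonicalize sign into the phase
        amp, phase = -amp, phase + period / 2.0
    phase = float(phase % period)
    rmse = float(np.sqrt(np.mean(best.fun**2)))
    return CosineFit(
        period=float(period), amplitude=float(amp), phase=phase,
        damping=float(lam), baseline=float(base), rmse=rmse,
        converged=bool(best.success),
    )


def fold_change_vs_control(
    condition: Sequence[LuminescenceTrace],
    control: Sequence[LuminescenceTrace],
) -> tuple[float, list[LuminescenceTrace]]:
    """Fold change in raw signal vs controls, applied to detrended traces.

    Returns (fold, scaled detrended condition traces): the ratio of raw
    condition mean to raw control mean scales the detrended condition
    traces, so different basal reporter levels stay visible after
    detrending.
    """
    if not condition or not control:
        raise ValueError("need at least one condition and one control trace")
    grid = condition[0].times

    def raw_mean(traces):
        vals = []
        for tr in traces:
            if tr.times.shape == grid.shape and np.allclose(tr.times, grid):
                vals.append(tr.counts)
            else:
                vals.append(np.interp(grid, tr.times, tr.counts))
        return np.mean([np.mean(v) for v in vals])

    ctrl_mean = raw_mean(control)
    if ctrl_mean == 0:
        raise ValueError("control mean is zero; fold change undefined")
    fold = float(raw_mean(condition) / ctrl_mean)
    scaled = [
        replace(d, counts=d.counts * fold) for d in (detrend(tr) for tr in condition)
    ]
    return fold, scaled


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Synthetic plate recording: trend x damped cosine + Gaussian noise.

    Defaults emulate a 7-day recording at 0.5 h sampling with a slowly
    decaying baseline trend.
    """

    period: float = 24.0
    damping: float = 0.01          # per h
    amplitude: float = 0.4         # relative modulation depth
    phase: float = 0.0             # h
    baseline: float = 1000.0       # counts
    trend_decay: float = 0.008     # per h, baseline signal decay
    trend_poly: tuple[float, ...] = ()   # extra polynomial trend coefficients
    noise_sd: float = 0.0          # counts, additive
    n_replicates: int = 1
    t_end: float = 7 * 24.0
    dt: float = 0.5
    seed: int = 0
    condition: str = "synthetic"


def _fixture_signal(spec: FixtureSpec, times: np.ndarray) -> np.ndarray:
    trend = spec.baseline * np.exp(-spec.trend_decay * times)
    if spec.trend_poly:
        trend = trend + np.polyval(list(spec.trend_poly)[::-1], times)
    osc = 1.0 + spec.amplitude * np.exp(-spec.damping * times) * np.cos(
        2 * np.pi * (times - spec.phase) / spec.period
    )
    return trend * osc


def generate_fixture(spec: FixtureSpec) -> list[LuminescenceTrace]:
    """Deterministic (seeded) synthetic traces following ``spec``."""
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, spec.t_end + spec.dt / 2, spec.dt)
    clean = _fixture_signal(spec, times)
    traces = []
    for rep in range(spec.n_replicates):
        noise = rng.normal(0.0, spec.noise_sd, size=times.shape)
        counts = np.clip(clean + noise, 0.0, None)
        traces.append(
            LuminescenceTrace(times, counts, condition=spec.condition,
                              replicate=rep)
        )
    return traces


def generate_model_driven_fixture(
    model,
    gene_overexpressed: str | None = None,
    fold: float = 0.0,
    spec: FixtureSpec | None = None,
) -> list[LuminescenceTrace]:
    """Fixture whose oscillation is a simulated Bmal reporter trajectory.

    The clock model (optionally with constitutive overexpression of one
    gene) is integrated for the recording span; the Bmal mRNA time course
    modulates the fixture's trend, and seeded noise is added.
    """
    from .experiments import WT_SETTINGS
    from .rhythms import mean_level
    from .simulate import SimulationSettings, integrate, with_exogenous_rna

    spec = spec or FixtureSpec(condition="model")
    if gene_overexpressed is not None and fold > 0:
        wt = integrate(model, WT_SETTINGS)
        model = with_exogenous_rna(
            model, gene_overexpressed, fold=fold, reference=wt
        )
    settings = SimulationSettings(
        t_end=spec.t_end, output_step=spec.dt, transient_discard=0.0
    )
    traj = integrate(model, settings)
    bmal = traj.series("Bmal")
    signal = bmal / np.mean(bmal)
    rng = np.random.default_rng(spec.seed)
    trend = spec.baseline * np.exp(-spec.trend_decay * traj.times)
    traces = []
    for rep in range(spec.n_replicates):
        noise = rng.normal(0.0, spec.noise_sd, size=traj.times.shape)
        counts = np.clip(trend * signal + noise, 0.0, None)
        traces.append(
            LuminescenceTrace(traj.times.copy(), counts,
                              condition=spec.condition, replicate=rep)
        )
    return traces


# ---------------------------------------------------------------------------
# plate CSV I/O and reporting
# ---------------------------------------------------------------------------

def write_plate_csv(traces: Sequence[LuminescenceTrace], path) -> None:
    """Long format: time_h, well, condition, counts."""
    frames = []
    for i, tr in enumerate(traces):
        frames.append(pd.DataFrame({
            "time_h": tr.times,
            "well": f"{tr.condition or 'well'}_{tr.replicate}",
            "condition": tr.condition,
            "counts": tr.counts,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_plate_csv(path) -> list[LuminescenceTrace]:
    df = pd.read_csv(path)
    required = {"time_h", "well", "condition", "counts"}
    if not required.issubset(df.columns):
        raise ValueError(f"plate CSV needs columns {sorted(required)}")
    traces = []
    for rep, (well, grp) in enumerate(df.groupby("well", sort=True)):
        grp = grp.sort_values("time_h")
        traces.append(LuminescenceTrace(
            grp["time_h"].to_numpy(), grp["counts"].to_numpy(),
            condition=str(grp["condition"].iloc[0]), replicate=rep,
        ))
    return traces


def fit_report(traces: Sequence[LuminescenceTrace]) -> pd.DataFrame:
    """Detrend and damped-cosine-fit every trace; one row per well."""
    rows = []
    for tr in traces:
        fit = fit_damped_cosine(detrend(tr))
        rows.append({
            "condition": tr.condition, "replicate": tr.replicate,
            "period_h": fit.period, "amplitude": fit.amplitude,
            "phase_h": fit.phase, "damping_per_h": fit.damping,
            "baseline": fit.baseline, "rmse": fit.rmse,
            "converged": fit.converged,
        })
    return pd.DataFrame(rows)
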