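"""In-silico experiment drivers: knockouts, RNAi, scans, decoupling,
RORE competition, rainbow profiles, constitutive overexpression, FASPS.

Every driver is a thin declarative layer: it builds perturbation lists,
runs :func:`circlock.simulate.integrate`, scores the outcome with
:mod:`circlock.rhythms`, and returns a tidy :class:`pandas.DataFrame`
(one row per grid point).  The standard protocol simulates 24 days and
scores the last 4 (transient readouts use days 0-6); the wild-type
reference runs 40 days with a 20-day transient discard.

``Bmal`` mRNA is the default reporter: period statements refer to it
unless a driver says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import ModelDefinition
from .rhythms import (
    ArrhythmicError,
    PhenotypeClass,
    RhythmSummary,
    classify_phenotype,
    estimate_period,
    mean_level,
    peak_phase,
    summarize,
)
from .simulate import (
    Perturbation,
    SimulationSettings,
    Trajectory,
    clamp_at_mean,
    integrate,
    with_exogenous_rna,
)
from .species import GENES, gene_by_name

__all__ = [
    "ExperimentContext",
    "knockout_scan",
    "sirna_scan",
    "transcription_gradient",
    "degradation_scan",
    "decouple_rbr",
    "decouple_pc",
    "pc_robustness",
    "rore_competition",
    "rainbow_scan",
    "overexpression",
    "fasps_scenarios",
    "table1_replica",
    "REFERENCE_PHENOTYPES",
    "table1_agreement",
]

#: per-gene parameter names, in the canonical gene order
VMAX = {"Per": "V1max", "Cry": "V2max", "Rev-Erb": "V3max",
        "Ror": "V4max", "Bmal": "V5max"}
TRANSLATION = {"Per": "kp1", "Cry": "kp2", "Rev-Erb": "kp3",
               "Ror": "kp4", "Bmal": "kp5"}
MRNA_DEGRADATION = {"Per": "dy1", "Cry": "dy2", "Rev-Erb": "dy3",
                    "Ror": "dy4", "Bmal": "dy5"}

#: standard run: 24 simulated days, last 4 scored
SCAN_SETTINGS = SimulationSettings(
    t_end=24 * 24.0, output_step=0.05, transient_discard=20 * 24.0
)
#: wild-type reference: 40 days, discard 20
WT_SETTINGS = SimulationSettings(
    t_end=40 * 24.0, output_step=0.05, transient_discard=20 * 24.0
)
REPORTER = "Bmal"


@dataclass
class ExperimentContext:
    """Wild-type reference shared by the drivers (computed once)."""

    model: ModelDefinition
    wt_trajectory: Trajectory
    wt_summary: RhythmSummary

    @classmethod
    def create(cls, model: ModelDefinition) -> "ExperimentContext":
        traj = integrate(model, WT_SETTINGS)
        return cls(model, traj, summarize(traj, REPORTER))

    def wt_mean(self, species: str) -> float:
        return mean_level(self.wt_trajectory, species)

    def snapshot(self) -> np.ndarray:
        """Limit-cycle state used to start perturbation runs: screens
        emulate perturbing cells that are already oscillating, so their
        transient window shows the WT-cycle-to-new-attractor transition."""
        return self.wt_trajectory.states[-1].copy()

    def scan_settings(self) -> SimulationSettings:
        return SimulationSettings(
            t_end=SCAN_SETTINGS.t_end,
            output_step=SCAN_SETTINGS.output_step,
            transient_discard=SCAN_SETTINGS.transient_discard,
            initial_state=self.snapshot(),
        )


def _ensure_context(model_or_ctx) -> ExperimentContext:
    if isinstance(model_or_ctx, ExperimentContext):
        return model_or_ctx
    return ExperimentContext.create(model_or_ctx)


def _run_row(
    ctx: ExperimentContext,
    perturbations: Sequence[Perturbation],
    species: str = REPORTER,
    transient: bool = False,
    settings: SimulationSettings | None = None,
) -> dict:
    if settings is None:
        settings = ctx.scan_settings()
    elif settings.initial_state is None:
        from dataclasses import replace as _replace

        settings = _replace(settings, initial_state=ctx.snapshot())
    traj = integrate(ctx.model, settings, perturbations)
    t_end = traj.times[-1]
    s = summarize(
        traj, species, (t_end - 4 * 24.0, t_end),
        wt_relative_amplitude=ctx.wt_summary.relative_amplitude,
    )
    label = classify_phenotype(ctx.wt_summary, traj, species, transient=transient)
    return {
        "period": s.period,
        "relative_amplitude": s.relative_amplitude,
        "mean_level": s.mean_level,
        "damping_ratio": s.damping_ratio,
        "oscillation_class": s.oscillation_class,
        "phenotype": label.value,
    }


# ---------------------------------------------------------------------------
# knockout / RNAi screens
# ---------------------------------------------------------------------------

def knockout_scan(model_or_ctx) -> pd.DataFrame:
    """90% transcription reduction per gene entity (in-silico mutant)."""
    ctx = _ensure_context(model_or_ctx)
    rows = []
    for gene in GENES:
        pert = Perturbation("scale_parameter", VMAX[gene], 0.1)
        rows.append({"gene": gene, "perturbation": pert.describe(),
                     **_run_row(ctx, [pert])})
    return pd.DataFrame(rows)


def sirna_scan(
    model_or_ctx,
    mode: str = "rna_degradation",
    levels: Iterable[float] = (0.1, 0.5, 0.7, 1.0),
) -> pd.DataFrame:
    """RNAi emulation: mRNA degradation up or translation down, per gene.

    ``levels`` are fractional knockdown strengths; 1.0 is the two-fold
    column (degradation doubled / translation halved) and is scored on
    the 0-6 day transient, the other levels on the steady window.
    """
    if mode not in ("rna_degradation", "translation"):
        raise ValueError("mode must be 'rna_degradation' or 'translation'")
    ctx = _ensure_context(model_or_ctx)
    rows = []
    for gene in GENES:
        for level in levels:
            if mode == "rna_degradation":
                pert = Perturbation(
                    "scale_parameter", MRNA_DEGRADATION[gene], 1.0 + level
                )
            else:
                pert = Perturbation(
                    "scale_parameter", TRANSLATION[gene], 1.0 - level / 2.0
                    if level == 1.0 else 1.0 - level
                )
            transient = level == 1.0
            rows.append({
                "gene": gene, "mode": mode, "level": level,
                "perturbation": pert.describe(),
                "scored_on": "transient" if transient else "steady",
                **_run_row(ctx, [pert], transient=transient),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# transcription / degradation response curves
# ---------------------------------------------------------------------------

def transcription_gradient(
    model_or_ctx, gene: str, factors: Sequence[float] | None = None
) -> pd.DataFrame:
    """Period response to a transcription-rate gradient (default 0.1x-10x)."""
    ctx = _ensure_context(model_or_ctx)
    gene = gene_by_name(gene)
    if factors is None:
        factors = np.round(np.logspace(-1, 1, 15), 4)
    if np.any(np.asarray(factors) <= 0):
        raise ValueError("factors must be > 0")
    rows = []
    for factor in factors:
        pert = Perturbation("scale_parameter", VMAX[gene], float(factor))
        rows.append({"gene": gene, "factor": float(factor),
                     **_run_row(ctx, [pert])})
    return pd.DataFrame(rows)


def degradation_scan(
    model_or_ctx,
    parameter: str = "dy1",
    lo: float = 0.0,
    hi: float = 1.0,
    n_points: int = 101,
) -> pd.DataFrame:
    """Period vs a degradation rate on a uniform grid (default: Per mRNA
    degradation from 0 to 1, i.e. up to 3.3x its wild-type value).

    The returned frame carries ``df.attrs['extremum']`` with the interior
    extremum of the period curve over the rhythmic region, if any.
    """
    ctx = _ensure_context(model_or_ctx)
    values = np.linspace(lo, hi, n_points)
    rows = []
    for v in values:
        pert = Perturbation("set_parameter", parameter, float(v))
        try:
            row = _run_row(ctx, [pert])
        except Exception:
            row = {"period": None, "relative_amplitude": np.nan,
                   "mean_level": np.nan, "damping_ratio": None,
                   "oscillation_class": "arrhythmic",
                   "phenotype": PhenotypeClass.AR.value}
        rows.append({"parameter": parameter, "value": float(v), **row})
    df = pd.DataFrame(rows)
    df.attrs["extremum"] = _interior_extremum(df)
    return df


def _interior_extremum(df: pd.DataFrame) -> dict | None:
    ok = df[df["oscillation_class"] == "sustained"].dropna(subset=["period"])
    if len(ok) < 3:
        return None
    v = ok["value"].to_numpy()
    p = ok["period"].to_numpy()
    i_min, i_max = int(np.argmin(p)), int(np.argmax(p))
    for i, kind in ((i_min, "minimum"), (i_max, "maximum")):
        if 0 < i < len(p) - 1:
            return {"kind": kind, "value": float(v[i]), "period": float(p[i])}
    return None


# ---------------------------------------------------------------------------
# loop decoupling and clamp experiments
# ---------------------------------------------------------------------------

RBR_SPECIES = ("Bmal", "Rev-Erb", "Ror", "CLOCK/BMAL", "REV-ERB_N", "ROR_N",
               "BMAL_N", "REV-ERB_C", "ROR_C", "BMAL_C")
PC_SPECIES = ("Per", "Cry", "percry_pool")


def decouple_rbr(model_or_ctx) -> pd.DataFrame:
    """RBR subsystem: the PER/CRY pool is replaced by its wild-type mean,
    turning the PC loop into a constitutive inhibitor."""
    ctx = _ensure_context(model_or_ctx)
    clamp = clamp_at_mean(ctx.model, "percry_pool", ctx.wt_trajectory)
    from dataclasses import replace as _replace
    settings = _replace(WT_SETTINGS, initial_state=ctx.snapshot())
    traj = integrate(ctx.model, settings, [clamp])
    rows = []
    for sp in RBR_SPECIES:
        s = summarize(traj, sp,
                      wt_relative_amplitude=ctx.wt_summary.relative_amplitude)
        rows.append({"species": sp, "clamp": clamp.value, "period": s.period,
                     "relative_amplitude": s.relative_amplitude,
                     "mean_level": s.mean_level,
                     "damping_ratio": s.damping_ratio,
                     "oscillation_class": s.oscillation_class})
    return pd.DataFrame(rows)


def decouple_pc(model_or_ctx) -> pd.DataFrame:
    """PC subsystem: CLOCK/BMAL and REV-ERB_N are replaced by their
    wild-type means (constitutive activator and inhibitor).

    The subsystem is a damped oscillator, so its period is scored on
    the first 5 days of the decaying transient: later cycles flatten
    and their spacing drifts toward the focus frequency."""
    ctx = _ensure_context(model_or_ctx)
    clamps = [clamp_at_mean(ctx.model, "CLOCK/BMAL", ctx.wt_trajectory),
              clamp_at_mean(ctx.model, "REV-ERB_N", ctx.wt_trajectory)]
    settings = SimulationSettings(
        t_end=10 * 24.0, output_step=0.05, transient_discard=0.0
    )
    traj = integrate(ctx.model, settings, clamps)
    rows = []
    for sp in PC_SPECIES:
        s = summarize(traj, sp, (0.0, 5 * 24.0),
                      wt_relative_amplitude=ctx.wt_summary.relative_amplitude)
        rows.append({"species": sp,
                     "clamp_clock_bmal": clamps[0].value,
                     "clamp_reverb_n": clamps[1].value,
                     "period": s.period,
                     "relative_amplitude": s.relative_amplitude,
                     "damping_ratio": s.damping_ratio,
                     "oscillation_class": s.oscillation_class})
    return pd.DataFrame(rows)


def pc_robustness(
    model_or_ctx, deltas: Sequence[float] = (-0.5, -0.2, -0.1, 0.1, 0.2, 0.5)
) -> pd.DataFrame:
    """RBR oscillation under perturbed constitutive PER/CRY pool levels."""
    ctx = _ensure_context(model_or_ctx)
    pc_wt = ctx.wt_mean("percry_pool")
    rows = []
    for delta in deltas:
        pert = Perturbation("clamp_species", "percry_pool", pc_wt * (1 + delta))
        rows.append({"delta": delta, "clamp": pert.value,
                     **_run_row(ctx, [pert], settings=WT_SETTINGS)})
    return pd.DataFrame(rows)


def rore_competition(
    model_or_ctx, recovery_factors: Sequence[float] = (1.25, 1.5, 2.0, 3.0)
) -> dict:
    """Constitutive-nuclear-receptor experiments on the Bmal RORE.

    Returns a report with: the REV-ERB_N mean clamp (expected loss of all
    oscillations), an elevated-clamp scan (expected recovery of Bmal
    oscillation at some factor), the ROR_N mean clamp (expected sustained
    Bmal with reduced amplitude), and the REV-ERB_N/ROR_N phase
    difference on the wild-type cycle (near anti-phase).
    """
    ctx = _ensure_context(model_or_ctx)
    x5_mean = ctx.wt_mean("REV-ERB_N")
    x6_mean = ctx.wt_mean("ROR_N")

    rev_clamp = _run_row(
        ctx, [Perturbation("clamp_species", "REV-ERB_N", x5_mean)],
        settings=WT_SETTINGS,
    )
    recovery = []
    for f in recovery_factors:
        row = _run_row(
            ctx, [Perturbation("clamp_species", "REV-ERB_N", f * x5_mean)],
            settings=WT_SETTINGS,
        )
        recovery.append({"factor": f, **row})
    ror_clamp = _run_row(
        ctx, [Perturbation("clamp_species", "ROR_N", x6_mean)],
        settings=WT_SETTINGS,
    )
    period = ctx.wt_summary.period
    dphi = peak_phase(ctx.wt_trajectory, "REV-ERB_N", anchor="ROR_N")
    dphi = min(dphi, period - dphi)  # unsigned separation within a cycle
    return {
        "reverb_mean_clamp": rev_clamp,
        "reverb_recovery_scan": pd.DataFrame(recovery),
        "ror_mean_clamp": {
            **ror_clamp,
            "wt_relative_amplitude": ctx.wt_summary.relative_amplitude,
        },
        "ror_reverb_phase_separation_h": dphi,
        "clamp_levels": {"REV-ERB_N": x5_mean, "ROR_N": x6_mean},
    }


# ---------------------------------------------------------------------------
# rainbow profiles and constitutive overexpression
# ---------------------------------------------------------------------------

def rainbow_scan(
    model_or_ctx, gene: str, n: int = 10, max_factor: float = 3.0
) -> dict:
    """Steady-window expression profiles across a transcription gradient.

    ``n`` equally spaced maximal-transcription values from 0 to
    ``max_factor`` x wild type, plus the wild-type profile: the overlay
    stands in for a bifurcation diagram.  Profiles cover the last 4 of
    24 simulated days for the gene's own transcript.
    """
    ctx = _ensure_context(model_or_ctx)
    gene = gene_by_name(gene)
    factors = list(np.linspace(0.0, max_factor, n))
    profiles, classes = {}, {}
    times = None
    for label, factor in [(f"{f:.3g}x" , f) for f in factors] + [("WT", 1.0)]:
        perts = []
        if label != "WT":
            perts = [Perturbation("scale_parameter", VMAX[gene], float(factor))]
        traj = integrate(ctx.model, ctx.scan_settings(), perts)
        t_end = traj.times[-1]
        tw, xw = traj.window(t_end - 4 * 24.0, t_end)
        s = summarize(traj, gene, (t_end - 4 * 24.0, t_end),
                      wt_relative_amplitude=ctx.wt_summary.relative_amplitude)
        if times is None:
            times = tw - tw[0]
        profiles[label] = traj.series(gene)[traj.times >= t_end - 4 * 24.0 - 1e-9]
        classes[label] = s.oscillation_class
    oscillatory = [lbl for lbl, c in classes.items() if c == "sustained"]
    return {"gene": gene, "times": times, "factors": factors,
            "profiles": profiles, "classes": classes,
            "oscillatory_region": oscillatory}


def overexpression(
    model_or_ctx,
    gene: str,
    amounts: Sequence[float],
    as_fold: bool = True,
    days: float = 6.0,
) -> pd.DataFrame:
    """Constitutive exogenous RNA added to the endogenous transcript.

    ``amounts`` are folds of the endogenous wild-type mRNA mean (or
    absolute amounts with ``as_fold=False``).  Scores Bmal over the
    experimental display window (default 6 days) and over the long run.
    """
    ctx = _ensure_context(model_or_ctx)
    gene = gene_by_name(gene)
    rows = []
    for amount in amounts:
        if as_fold:
            model = with_exogenous_rna(
                ctx.model, gene, fold=amount, reference=ctx.wt_trajectory
            )
        else:
            model = with_exogenous_rna(ctx.model, gene, amount)
        from dataclasses import replace as _replace

        traj = integrate(model, _replace(SCAN_SETTINGS,
                                         initial_state=ctx.snapshot()))
        t_end = traj.times[-1]
        early = summarize(traj, REPORTER, (0.0, days * 24.0),
                          wt_relative_amplitude=ctx.wt_summary.relative_amplitude)
        late = summarize(traj, REPORTER, (t_end - 4 * 24.0, t_end),
                         wt_relative_amplitude=ctx.wt_summary.relative_amplitude)
        lost_by_day6 = late.oscillation_class != "sustained"
        rows.append({
            "gene": gene, "amount": amount,
            "unit": "fold of endogenous mean" if as_fold else "a.u.",
            "bmal_mean_day0_6": early.mean_level,
            "bmal_relative_amplitude_day0_6": early.relative_amplitude,
            "damping_ratio_day0_6": early.damping_ratio,
            "steady_class": late.oscillation_class,
            "oscillations_lost": lost_by_day6,
        })
    return pd.DataFrame(rows)


def fasps_scenarios(model_or_ctx) -> pd.DataFrame:
    """Two advanced-sleep-phase scenarios on the phosphorylated nuclear
    PER/CRY complex: raised nuclear export (kex2=0.05) and raised nuclear
    degradation (dx2=0.1).  Both should shorten the period and reduce the
    Per mRNA amplitude."""
    ctx = _ensure_context(model_or_ctx)
    wt_per = summarize(ctx.wt_trajectory, "Per")
    rows = []
    for name, value in (("kex2", 0.05), ("dx2", 0.1)):
        from dataclasses import replace as _replace

        pert = Perturbation("set_parameter", name, value)
        traj = integrate(ctx.model,
                         _replace(WT_SETTINGS, initial_state=ctx.snapshot()),
                         [pert])
        s = summarize(traj, "Per",
                      wt_relative_amplitude=wt_per.relative_amplitude)
        label = classify_phenotype(ctx.wt_summary, traj, "Per")
        rows.append({
            "scenario": f"{name}={value}",
            "parameter": name, "value": value,
            "wt_value": ctx.model.params[name],
            "period": s.period,
            "wt_period": wt_per.period,
            "per_relative_amplitude": s.relative_amplitude,
            "wt_per_relative_amplitude": wt_per.relative_amplitude,
            "phenotype": label.value,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Table-1-style phenotype replica
# ---------------------------------------------------------------------------

#: Published in-silico phenotype pattern for the five gene entities
#: (mutant = 90% transcription reduction; RNAi = mRNA degradation up /
#: translation down at the stated strengths; the two-fold columns are
#: scored on the early transient).  Used to validate the calibration.
REFERENCE_PHENOTYPES: dict[str, dict[str, str]] = {
    "Per":     {"mutant": "AR", "deg+10": "WT", "tln-10": "+",
                "deg+50": "+", "tln-50": "+", "deg+70": "+", "tln-70": "+",
                "deg2x": "+", "tln2x": "+"},
    "Cry":     {"mutant": "+", "deg+10": "WT", "tln-10": "WT",
                "deg+50": "WT", "tln-50": "+", "deg+70": "+", "tln-70": "+",
                "deg2x": "WT", "tln2x": "+"},
    "Rev-Erb": {"mutant": "AR", "deg+10": "WT", "tln-10": "WT",
                "deg+50": "AR", "tln-50": "AR", "deg+70": "AR", "tln-70": "AR",
                "deg2x": "- then AR", "tln2x": "- then AR"},
    "Ror":     {"mutant": "- then AR", "deg+10": "-", "tln-10": "WT",
                "deg+50": "AR", "tln-50": "AR", "deg+70": "AR", "tln-70": "AR",
                "deg2x": "- then AR", "tln2x": "- then AR"},
    "Bmal":    {"mutant": "AR", "deg+10": "WT", "tln-10": "WT",
                "deg+50": "AR", "tln-50": "AR", "deg+70": "AR", "tln-70": "AR",
                "deg2x": "- then AR", "tln2x": "- then AR"},
}


def table1_replica(model_or_ctx) -> pd.DataFrame:
    """Recompute every in-silico phenotype cell of the knockout/RNAi table."""
    ctx = _ensure_context(model_or_ctx)
    ko = knockout_scan(ctx).set_index("gene")
    deg = sirna_scan(ctx, "rna_degradation").set_index(["gene", "level"])
    tln = sirna_scan(ctx, "translation").set_index(["gene", "level"])
    rows = []
    for gene in GENES:
        rows.append({
            "gene": gene,
            "mutant": ko.loc[gene, "phenotype"],
            "deg+10": deg.loc[(gene, 0.1), "phenotype"],
            "tln-10": tln.loc[(gene, 0.1), "phenotype"],
            "deg+50": deg.loc[(gene, 0.5), "phenotype"],
            "tln-50": tln.loc[(gene, 0.5), "phenotype"],
            "deg+70": deg.loc[(gene, 0.7), "phenotype"],
            "tln-70": tln.loc[(gene, 0.7), "phenotype"],
            "deg2x": deg.loc[(gene, 1.0), "phenotype"],
            "tln2x": tln.loc[(gene, 1.0), "phenotype"],
        })
    return pd.DataFrame(rows).set_index("gene")


def table1_agreement(replica: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Cell-by-cell agreement of a replica with the reference pattern.

    Returns (fraction agreeing, boolean frame of matches)."""
    matches = {}
    for gene, expected in REFERENCE_PHENOTYPES.items():
        matches[gene] = {
            col: replica.loc[gene, col] == want for col, want in expected.items()
        }
    mdf = pd.DataFrame(matches).T
    return float(mdf.to_numpy().mean()), mdf
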