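"""Integration of the clock model under declarative perturbations.

Perturbations are data, not code: parameter scaling/overrides, species
clamps (substitution into the RHS, so clamped species are exactly
constant) and constitutive exogenous RNA.  The integrator is an adaptive
Runge-Kutta (Dormand-Prince) run at tight tolerances (1e-9 by default),
sampled on a uniform output grid; a fixed-step RK4 driver is available as
an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernel
from .model import ModelDefinition, percry_pool
from .parameters import ClockParameters
from .species import (
    GENE_TO_MRNA,
    GENES,
    N_SPECIES,
    PERCRY_POOL,
    SPECIES,
    gene_by_name,
    species_by_name,
    species_index,
)

__all__ = [
    "Perturbation",
    "SimulationSettings",
    "Trajectory",
    "IntegrationError",
    "integrate",
    "clamp_at_mean",
    "with_exogenous_rna",
]

PerturbationKind = Literal[
    "scale_parameter", "set_parameter", "clamp_species", "exogenous_rna"
]


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Perturbation:
    """A declarative change to the model.

    kind:
      * ``scale_parameter`` — multiply parameter ``target`` by ``value``;
      * ``set_parameter`` — set parameter ``target`` to ``value``;
      * ``clamp_species`` — hold species ``target`` (or ``percry_pool``)
        at the constant ``value``;
      * ``exogenous_rna`` — add a constant amount ``value`` of ``target``
        gene's mRNA as translation substrate.

    ``schedule`` is kept for bookkeeping; the model is autonomous and all
    perturbations act from the start of the simulated interval.
    """

    kind: PerturbationKind
    target: str
    value: float
    schedule: Literal["always", "from_t0"] = "always"

    def __post_init__(self):
        if self.kind not in (
            "scale_parameter", "set_parameter", "clamp_species", "exogenous_rna"
        ):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "exogenous_rna" and self.value < 0:
            raise ValueError("exogenous RNA amount must be >= 0")
        if self.kind == "clamp_species" and self.target != PERCRY_POOL:
            species_by_name(self.target)  # raises on unknown species

    def describe(self) -> str:
        return f"{self.kind}({self.target}={self.value:g})"


@dataclass(frozen=True)
class SimulationSettings:
    """Integration control.

    Times in hours.  Defaults follow the package's standard protocol:
    integrate 40 days, analyse after a 20-day transient, sample every
    0.01 h with absolute/relative tolerances of 1e-9.
    """

    t_end: float = 40 * 24.0
    output_step: float = 0.01
    rtol: float = 1e-9
    atol: float = 1e-9
    transient_discard: float = 20 * 24.0
    initial_state: np.ndarray | None = None
    method: str = "RK45"

    def __post_init__(self):
        if not (self.t_end > self.transient_discard >= 0):
            raise ValueError("need t_end > transient_discard >= 0")
        if self.rtol <= 0 or self.atol <= 0 or self.output_step <= 0:
            raise ValueError("tolerances and output_step must be > 0")

    def start_state(self) -> np.ndarray:
        if self.initial_state is None:
            # normalization baseline: every species at 1.0
            return np.ones(N_SPECIES)
        y0 = np.asarray(self.initial_state, dtype=float)
        if y0.shape != (N_SPECIES,) or not np.all(np.isfinite(y0)):
            raise ValueError("initial_state must be 19 finite concentrations")
        return y0.copy()


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled solution of one simulation run."""

    times: np.ndarray
    states: np.ndarray
    settings: SimulationSettings
    perturbations: tuple[Perturbation, ...] = ()

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in SPECIES)

    def series(self, species: str) -> np.ndarray:
        """Time course of one species, or of the nuclear PER/CRY pool."""
        if species.strip().lower() in (PERCRY_POOL, "pc", "per/cry_pool"):
            return self.pool()
        return self.states[:, species_index(species)]

    def pool(self) -> np.ndarray:
        pool = percry_pool(self.states)
        for p in self.perturbations:
            if p.kind == "clamp_species" and p.target == PERCRY_POOL:
                pool = np.full_like(self.times, p.value)
        return pool

    def window(self, t0: float | None = None, t1: float | None = None):
        """(times, states) restricted to [t0, t1]; defaults to the
        post-transient analysis window."""
        if t0 is None:
            t0 = self.settings.transient_discard
        if t1 is None:
            t1 = self.times[-1]
        sel = (self.times >= t0 - 1e-9) & (self.times <= t1 + 1e-9)
        return self.times[sel], self.states[sel]

    def to_frame(self, tidy: bool = False):
        """Wide (time x species) or tidy (time, species, value) DataFrame."""
        import pandas as pd

        wide = pd.DataFrame(self.states, columns=list(self.species_names))
        wide.insert(0, "time_h", self.times)
        if not tidy:
            return wide
        return wide.melt(id_vars="time_h", var_name="species", value_name="value")


def _apply_perturbations(
    model: ModelDefinition, perturbations: Sequence[Perturbation]
):
    p = model.params
    mask = np.zeros(N_SPECIES, dtype=np.bool_)
    clamp = np.zeros(N_SPECIES, dtype=np.float64)
    pool_clamp = _kernel.NO_POOL_CLAMP
    exo = model.exo_array().copy()
    for pert in perturbations:
        if pert.kind == "scale_parameter":
            p = p.scaled(pert.target, pert.value)
        elif pert.kind == "set_parameter":
            p = p.replace(**{pert.target: pert.value})
        elif pert.kind == "clamp_species":
            if pert.target == PERCRY_POOL:
                pool_clamp = float(pert.value)
            else:
                i = species_index(pert.target)
                mask[i] = True
                clamp[i] = float(pert.value)
        elif pert.kind == "exogenous_rna":
            exo[GENES.index(gene_by_name(pert.target))] += float(pert.value)
    return p, mask, clamp, pool_clamp, exo


def integrate(
    model: ModelDefinition,
    settings: SimulationSettings | None = None,
    perturbations: Sequence[Perturbation] = (),
) -> Trajectory:
    """Integrate the (possibly perturbed) model and sample uniformly.

    Clamped species are reported as constant columns.  Raises
    :class:`IntegrationError` on solver failure or non-finite states,
    naming the failure time / offending species.
    """
    settings = settings or SimulationSettings()
    params, mask, clamp, pool_clamp, exo = _apply_perturbations(
        model, perturbations
    )
    y0 = settings.start_state()
    y0[mask] = clamp[mask]
    pvec = params.as_array()

    n_out = int(round(settings.t_end / settings.output_step)) + 1
    t_eval = np.linspace(0.0, settings.t_end, n_out)

    sol = solve_ivp(
        _kernel.rhs_kernel,
        (0.0, settings.t_end),
        y0,
        method=settings.method,
        t_eval=t_eval,
        rtol=settings.rtol,
        atol=settings.atol,
        args=(pvec, mask, clamp, pool_clamp, exo),
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed at t={sol.t[-1] if sol.t.size else 0.0:.3f} h: "
            f"{sol.message}"
        )
    states = sol.y.T
    if not np.all(np.isfinite(states)):
        bad = np.argwhere(~np.isfinite(states))
        it, isp = bad[0]
        raise IntegrationError(
            f"non-finite value for species {SPECIES[isp].name!r} "
            f"at t={sol.t[it]:.3f} h"
        )
    states[:, mask] = clamp[mask]
    # flag excursions clearly below the negativity the tolerance explains
    floor = -10.0 * max(settings.atol, 1e-12)
    if states.min() < floor:
        isp = int(np.argmin(states.min(axis=0)))
        raise IntegrationError(
            f"species {SPECIES[isp].name!r} fell below {floor:g} "
            f"(min {states.min():g}); integration unreliable"
        )
    return Trajectory(sol.t, states, settings, tuple(perturbations))


def integrate_fixed_step(
    model: ModelDefinition,
    settings: SimulationSettings | None = None,
    perturbations: Sequence[Perturbation] = (),
    step: float = 1e-3,
) -> Trajectory:
    """Fixed-step classical RK4 run (the integrator cross-check oracle)."""
    settings = settings or SimulationSettings()
    params, mask, clamp, pool_clamp, exo = _apply_perturbations(
        model, perturbations
    )
    y0 = settings.start_state()
    y0[mask] = clamp[mask]
    record_every = max(1, int(round(settings.output_step / step)))
    times, states = _kernel.rk4_sample(
        y0, 0.0, settings.t_end, step, record_every,
        params.as_array(), mask, clamp, pool_clamp, exo,
    )
    states = states.copy()
    states[:, mask] = clamp[mask]
    return Trajectory(times, states, settings, tuple(perturbations))


def clamp_at_mean(
    model: ModelDefinition,
    species: str,
    reference: Trajectory,
) -> Perturbation:
    """Clamp a species (or ``percry_pool``) at its limit-cycle mean.

    The mean is the trapezoidal time average over an integer number of
    cycles at the end of the reference's analysis window; ``reference``
    must cover at least one full period after its transient.
    """
    from .rhythms import mean_level

    value = mean_level(reference, species)
    name = species if species.strip().lower() in (PERCRY_POOL,) else (
        species_by_name(species).name
    )
    return Perturbation("clamp_species", name, value)


def with_exogenous_rna(
    model: ModelDefinition,
    gene: str,
    amount: float | None = None,
    *,
    fold: float | None = None,
    reference: Trajectory | None = None,
) -> ModelDefinition:
    """Model with constitutive exogenous RNA for one gene entity.

    ``amount`` is in normalized concentration units; alternatively
    ``fold`` expresses the exogenous amount as a multiple of the
    endogenous mRNA's mean on ``reference`` (a wild-type trajectory).
    """
    gene = gene_by_name(gene)
    if (amount is None) == (fold is None):
        raise ValueError("give exactly one of amount= or fold=")
    if fold is not None:
        if fold < 0:
            raise ValueError("fold must be >= 0")
        if reference is None:
            raise ValueError("fold= requires a wild-type reference trajectory")
        from .rhythms import mean_level

        amount = fold * mean_level(reference, gene)
    return model.with_exogenous(gene, float(amount))
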