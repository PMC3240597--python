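"""Model definition: wiring, kinetic laws, RHS evaluation, Jacobian.

The network is assembled from mass-action kinetics with linear degradation
for every species; nonlinearity enters only through the transcription
laws (saturating Hill activation by CLOCK/BMAL, Hill inhibition by the
nuclear PER/CRY pool, REV-ERB_N repression of *Cry*, and a competitive
RORE function for *Bmal* with ROR_N in the numerator and REV-ERB_N in the
denominator).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from . import _kernel
from .parameters import ClockParameters, PARAM_NAMES
from .species import GENES, N_SPECIES, SPECIES, species_index

__all__ = [
    "ModelDefinition",
    "build_default_model",
    "rhs",
    "percry_pool",
    "jacobian",
    "WIRING",
]

#: Regulatory wiring: promoter -> (activators, inhibitors).
WIRING: dict[str, dict[str, tuple[str, ...]]] = {
    "Per": {"activators": ("CLOCK/BMAL",), "inhibitors": ("percry_pool",)},
    "Cry": {
        "activators": ("CLOCK/BMAL",),
        "inhibitors": ("percry_pool", "REV-ERB_N"),
    },
    "Rev-Erb": {"activators": ("CLOCK/BMAL",), "inhibitors": ("percry_pool",)},
    "Ror": {"activators": ("CLOCK/BMAL",), "inhibitors": ("percry_pool",)},
    "Bmal": {"activators": ("ROR_N",), "inhibitors": ("REV-ERB_N",)},
}


@dataclass(frozen=True)
class ModelDefinition:
    """Species registry, wiring, kinetic laws and parameters of the clock.

    ``exogenous`` holds a constant exogenous mRNA amount per gene entity
    (Per, Cry, Rev-Erb, Ror, Bmal order); it feeds translation alongside
    the endogenous transcript and models constitutive overexpression.
    """

    params: ClockParameters
    exogenous: tuple[float, float, float, float, float] = (0.0,) * 5

    species = SPECIES
    wiring = WIRING

    def __post_init__(self):
        if len(self.exogenous) != 5 or any(e < 0 for e in self.exogenous):
            raise ValueError("exogenous must be 5 nonnegative amounts")

    @property
    def n_species(self) -> int:
        return N_SPECIES

    @property
    def n_params(self) -> int:
        return len(self.params)

    def exo_array(self) -> np.ndarray:
        return np.asarray(self.exogenous, dtype=float)

    def with_params(self, params: ClockParameters) -> "ModelDefinition":
        return ModelDefinition(params, self.exogenous)

    def with_exogenous(self, gene: str, amount: float) -> "ModelDefinition":
        from .species import gene_by_name

        if amount < 0:
            raise ValueError("exogenous RNA amount must be >= 0")
        exo = list(self.exogenous)
        exo[GENES.index(gene_by_name(gene))] = float(amount)
        return ModelDefinition(self.params, tuple(exo))

    def rhs(self, state: np.ndarray, t: float = 0.0) -> np.ndarray:
        return rhs(state, self, t)

    def jacobian(self, state: np.ndarray) -> np.ndarray:
        return jacobian(state, self)


def build_default_model() -> ModelDefinition:
    """The calibrated wild-type model (19 species, 71 parameters)."""
    return ModelDefinition(ClockParameters.default())


def rhs(state: np.ndarray, model: ModelDefinition, t: float = 0.0) -> np.ndarray:
    """Time derivative of every species, in h^-1.

    The system is autonomous; ``t`` is accepted for integrator interfaces
    only.  Each derivative is production - transport out + transport in -
    degradation per the Fig.-style wiring above.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (N_SPECIES,):
        raise ValueError(f"state must have shape ({N_SPECIES},)")
    if not np.all(np.isfinite(state)):
        raise ValueError("state contains non-finite entries")
    mask, clamp, pool, exo = _kernel.neutral_perturbation_args()
    return _kernel.rhs_kernel(
        t, state, model.params.as_array(), mask, clamp, pool, model.exo_array()
    )


def percry_pool(state: np.ndarray) -> np.ndarray | float:
    """Pooled nuclear inhibitor: PER/CRY_N + PERp/CRY_N.

    Accepts a single state vector or a (time x species) matrix.
    """
    state = np.asarray(state, dtype=float)
    i, j = species_index("PERp/CRY_N"), species_index("PER/CRY_N")
    if state.ndim == 1:
        return float(state[i] + state[j])
    return state[..., i] + state[..., j]


# --------------------------------------------------------------------------
# symbolic twin: powers the analytic Jacobian and the SBML export
# --------------------------------------------------------------------------

_SYM_STATE_NAMES = tuple(
    s.name.replace("/", "_").replace("-", "_") for s in SPECIES
)


@functools.lru_cache(maxsize=1)
def symbolic_system() -> tuple[tuple[sp.Symbol, ...], tuple[sp.Symbol, ...], tuple[sp.Expr, ...]]:
    """(state symbols, parameter symbols, rhs expressions) of the base model.

    Valid on the nonnegative orthant (the saturating terms are written
    without the clipping guard the numerical kernel applies to tiny
    negative integrator excursions).
    """
    ys = sp.symbols(_SYM_STATE_NAMES, nonnegative=True)
    ps = sp.symbols(PARAM_NAMES, positive=True)
    p = dict(zip(PARAM_NAMES, ps))
    (x1, x2, x3, x4, x5, x6,
     y1, y2, y3, y4, y5,
     z1, z2, z3, z4, z5, z6, z7, z8) = ys

    pc = x2 + x3
    h = [
        (x1 / p["ka1"]) ** p["b1"],
        (x1 / p["ka2"]) ** p["b2"],
        (x1 / p["ka3"]) ** p["b3"],
        (x1 / p["ka4"]) ** p["b4"],
        (x6 / p["ka5"]) ** p["b5"],
    ]
    v_per = (p["V1max"] * (1 + p["f1"] * h[0]) / (1 + h[0])
             / (1 + (pc / p["ki1"]) ** p["c1"]))
    v_cry = (p["V2max"] * (1 + p["f2"] * h[1]) / (1 + h[1])
             / (1 + (pc / p["ki2"]) ** p["c2"])
             / (1 + (x5 / p["ki6"]) ** p["c6"]))
    v_rev = (p["V3max"] * (1 + p["f3"] * h[2]) / (1 + h[2])
             / (1 + (pc / p["ki3"]) ** p["c3"]))
    v_ror = (p["V4max"] * (1 + p["f4"] * h[3]) / (1 + h[3])
             / (1 + (pc / p["ki4"]) ** p["c4"]))
    v_bmal = (p["V5max"] * (1 + p["f5"] * h[4])
              / (1 + h[4] + (x5 / p["ki5"]) ** p["c5"]))

    a4 = p["kfz4"] * z2 * z3
    s4 = p["kdz4"] * z4
    a5 = p["kfz5"] * z1 * z3
    s5 = p["kdz5"] * z5
    ax1 = p["kfx1"] * x4
    sx1 = p["kdx1"] * x1

    exprs = (
        ax1 - sx1 - p["dx1"] * x1,
        p["kiz4"] * z4 - p["kex2"] * x2 - p["dx2"] * x2,
        p["kiz5"] * z5 - p["kex1"] * x3 - p["dx3"] * x3,
        p["kiz8"] * z8 - ax1 + sx1 - p["dx4"] * x4,
        p["kiz6"] * z6 - p["dx5"] * x5,
        p["kiz7"] * z7 - p["dx6"] * x6,
        v_per - p["dy1"] * y1,
        v_cry - p["dy2"] * y2,
        v_rev - p["dy3"] * y3,
        v_ror - p["dy4"] * y4,
        v_bmal - p["dy5"] * y5,
        (p["kp1"] * y1 - p["kphos"] * z1 + p["kdphos"] * z2
         - a5 + s5 - p["dz1"] * z1),
        p["kphos"] * z1 - p["kdphos"] * z2 - a4 + s4 - p["dz2"] * z2,
        p["kp2"] * y2 - a4 + s4 - a5 + s5 - p["dz3"] * z3,
        a4 - s4 - p["kiz4"] * z4 + p["kex2"] * x2 - p["dz4"] * z4,
        a5 - s5 - p["kiz5"] * z5 + p["kex1"] * x3 - p["dz5"] * z5,
        p["kp3"] * y3 - p["kiz6"] * z6 - p["dz6"] * z6,
        p["kp4"] * y4 - p["kiz7"] * z7 - p["dz7"] * z7,
        p["kp5"] * y5 - p["kiz8"] * z8 - p["dz8"] * z8,
    )
    return tuple(ys), tuple(ps), exprs


@functools.lru_cache(maxsize=1)
def _lambdified():
    ys, ps, exprs = symbolic_system()
    f = sp.lambdify((ys, ps), sp.Matrix(exprs), modules="numpy")
    jac = sp.Matrix(exprs).jacobian(sp.Matrix(ys))
    jf = sp.lambdify((ys, ps), jac, modules="numpy")
    return f, jf


def rhs_reference(state: np.ndarray, model: ModelDefinition) -> np.ndarray:
    """Sympy-derived RHS of the unperturbed model (cross-check route)."""
    f, _ = _lambdified()
    out = np.asarray(f(tuple(state), tuple(model.params.as_array())), dtype=float)
    return out.ravel()


def jacobian(state: np.ndarray, model: ModelDefinition) -> np.ndarray:
    """Analytic 19x19 Jacobian d(rhs_i)/d(state_j) of the base model.

    Derived symbolically; exogenous RNA adds only constant terms and does
    not change the Jacobian.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("state contains non-finite entries")
    _, jf = _lambdified()
    return np.asarray(jf(tuple(state), tuple(model.params.as_array())), dtype=float)


def find_fixed_point(
    model: ModelDefinition, guess: np.ndarray | None = None
) -> np.ndarray:
    """Locate a fixed point of the flow by Newton iteration.

    Without an explicit guess, starts from the time average of a short
    wild-type run (the unstable focus sits near the cycle's centroid)
    and falls back to a few scaled baselines.
    """
    guesses = []
    if guess is not None:
        guesses.append(np.asarray(guess, dtype=float))
    else:
        from .simulate import SimulationSettings, integrate

        traj = integrate(
            model,
            SimulationSettings(t_end=12 * 24.0, output_step=0.2,
                               transient_discard=6 * 24.0, rtol=1e-7,
                               atol=1e-7),
        )
        _, states = traj.window()
        guesses.append(states.mean(axis=0))
        guesses.extend(c * np.ones(N_SPECIES) for c in (1.0, 1.5, 0.5))

    for g in guesses:
        y = np.clip(np.asarray(g, dtype=float), 1e-12, None)
        for _ in range(200):
            f = rhs(y, model)
            norm = np.linalg.norm(f)
            if norm < 1e-11:
                return y
            try:
                step = np.linalg.solve(jacobian(y, model), -f)
            except np.linalg.LinAlgError:
                break
            lam = 1.0  # backtracking line search, states kept nonnegative
            while lam > 1e-7:
                y_new = np.clip(y + lam * step, 1e-12, None)
                if np.linalg.norm(rhs(y_new, model)) < norm:
                    break
                lam *= 0.5
            else:
                break
            y = y_new
    raise RuntimeError("fixed-point search failed: Newton did not converge")
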