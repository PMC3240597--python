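"""Numerical right-hand-side kernel shared by all integrators.

The kernel is compiled with numba and takes the full perturbation state
explicitly, so one function covers the wild type as well as every
declarative perturbation used by the in-silico experiments:

* ``clamp_mask``/``clamp_values`` — species held at a constant; the
  constant is substituted wherever the species appears and its own
  derivative is zero (clamping by substitution, not by stiff relaxation);
* ``pool_clamp`` — if >= 0, replaces the nuclear PER/CRY pool seen by the
  E-box promoters (transcriptional inhibition reads the pooled sum, never
  the individual complexes); the complexes themselves keep evolving;
* ``exo`` — constant exogenous mRNA per gene entity, added to the
  endogenous transcript *only* in the translation terms (constitutive
  overexpression feeds protein production but is not itself produced or
  degraded).

State order and parameter order are fixed by ``species.SPECIES`` and
``parameters.PARAM_NAMES``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["rhs_kernel", "rk4_sample", "NO_POOL_CLAMP"]

#: sentinel meaning "no pool clamp" (pool concentrations are >= 0)
NO_POOL_CLAMP = -1.0


@njit(cache=False, fastmath=False)
def rhs_kernel(t, y, p, clamp_mask, clamp_values, pool_clamp, exo):  # noqa: C901
    d = np.zeros(19)

    # effective (possibly clamped) state
    x1 = clamp_values[0] if clamp_mask[0] else y[0]
    x2 = clamp_values[1] if clamp_mask[1] else y[1]
    x3 = clamp_values[2] if clamp_mask[2] else y[2]
    x4 = clamp_values[3] if clamp_mask[3] else y[3]
    x5 = clamp_values[4] if clamp_mask[4] else y[4]
    x6 = clamp_values[5] if clamp_mask[5] else y[5]
    y1 = clamp_values[6] if clamp_mask[6] else y[6]
    y2 = clamp_values[7] if clamp_mask[7] else y[7]
    y3 = clamp_values[8] if clamp_mask[8] else y[8]
    y4 = clamp_values[9] if clamp_mask[9] else y[9]
    y5 = clamp_values[10] if clamp_mask[10] else y[10]
    z1 = clamp_values[11] if clamp_mask[11] else y[11]
    z2 = clamp_values[12] if clamp_mask[12] else y[12]
    z3 = clamp_values[13] if clamp_mask[13] else y[13]
    z4 = clamp_values[14] if clamp_mask[14] else y[14]
    z5 = clamp_values[15] if clamp_mask[15] else y[15]
    z6 = clamp_values[16] if clamp_mask[16] else y[16]
    z7 = clamp_values[17] if clamp_mask[17] else y[17]
    z8 = clamp_values[18] if clamp_mask[18] else y[18]

    pc = pool_clamp if pool_clamp >= 0.0 else x2 + x3

    # nonneg projections for the saturating (fractional-power) terms only
    x1p = x1 if x1 > 0.0 else 0.0
    x5p = x5 if x5 > 0.0 else 0.0
    x6p = x6 if x6 > 0.0 else 0.0
    pcp = pc if pc > 0.0 else 0.0

    (V1, V2, V3, V4, V5,
     ka1, ka2, ka3, ka4, ka5,
     b1, b2, b3, b4, b5,
     f1, f2, f3, f4, f5,
     ki1, ki2, ki3, ki4, ki5, ki6,
     c1, c2, c3, c4, c5, c6,
     kp1, kp2, kp3, kp4, kp5,
     kphos, kdphos,
     kfz4, kdz4, kfz5, kdz5, kfx1, kdx1,
     kiz4, kiz5, kiz6, kiz7, kiz8, kex1, kex2,
     dy1, dy2, dy3, dy4, dy5,
     dz1, dz2, dz3, dz4, dz5, dz6, dz7, dz8,
     dx1, dx2, dx3, dx4, dx5, dx6) = (
        p[0], p[1], p[2], p[3], p[4],
        p[5], p[6], p[7], p[8], p[9],
        p[10], p[11], p[12], p[13], p[14],
        p[15], p[16], p[17], p[18], p[19],
        p[20], p[21], p[22], p[23], p[24], p[25],
        p[26], p[27], p[28], p[29], p[30], p[31],
        p[32], p[33], p[34], p[35], p[36],
        p[37], p[38],
        p[39], p[40], p[41], p[42], p[43], p[44],
        p[45], p[46], p[47], p[48], p[49], p[50], p[51],
        p[52], p[53], p[54], p[55], p[56],
        p[57], p[58], p[59], p[60], p[61], p[62], p[63], p[64],
        p[65], p[66], p[67], p[68], p[69], p[70])

    # transcription: CLOCK/BMAL-activated E-box promoters inhibited by the
    # PER/CRY pool; Cry additionally repressed by REV-ERB_N; Bmal driven by
    # RORE competition (ROR_N activates, REV-ERB_N represses).
    h1 = (x1p / ka1) ** b1
    h2 = (x1p / ka2) ** b2
    h3 = (x1p / ka3) ** b3
    h4 = (x1p / ka4) ** b4
    h5 = (x6p / ka5) ** b5

    v_per = V1 * (1.0 + f1 * h1) / (1.0 + h1) / (1.0 + (pcp / ki1) ** c1)
    v_cry = (V2 * (1.0 + f2 * h2) / (1.0 + h2)
             / (1.0 + (pcp / ki2) ** c2) / (1.0 + (x5p / ki6) ** c6))
    v_rev = V3 * (1.0 + f3 * h3) / (1.0 + h3) / (1.0 + (pcp / ki3) ** c3)
    v_ror = V4 * (1.0 + f4 * h4) / (1.0 + h4) / (1.0 + (pcp / ki4) ** c4)
    v_bmal = V5 * (1.0 + f5 * h5) / (1.0 + h5 + (x5p / ki5) ** c5)

    # mass-action fluxes
    a4 = kfz4 * z2 * z3   # PERp_C + CRY_C -> PERp/CRY_C
    s4 = kdz4 * z4
    a5 = kfz5 * z1 * z3   # PER_C + CRY_C -> PER/CRY_C
    s5 = kdz5 * z5
    ax1 = kfx1 * x4       # BMAL_N (+CLOCK) -> CLOCK/BMAL
    sx1 = kdx1 * x1

    # nucleus
    d[0] = ax1 - sx1 - dx1 * x1
    d[1] = kiz4 * z4 - kex2 * x2 - dx2 * x2
    d[2] = kiz5 * z5 - kex1 * x3 - dx3 * x3
    d[3] = kiz8 * z8 - ax1 + sx1 - dx4 * x4
    d[4] = kiz6 * z6 - dx5 * x5
    d[5] = kiz7 * z7 - dx6 * x6
    # mRNA
    d[6] = v_per - dy1 * y1
    d[7] = v_cry - dy2 * y2
    d[8] = v_rev - dy3 * y3
    d[9] = v_ror - dy4 * y4
    d[10] = v_bmal - dy5 * y5
    # cytoplasm (exogenous constitutive mRNA feeds translation only)
    d[11] = (kp1 * (y1 + exo[0]) - kphos * z1 + kdphos * z2
             - a5 + s5 - dz1 * z1)
    d[12] = kphos * z1 - kdphos * z2 - a4 + s4 - dz2 * z2
    d[13] = kp2 * (y2 + exo[1]) - a4 + s4 - a5 + s5 - dz3 * z3
    d[14] = a4 - s4 - kiz4 * z4 + kex2 * x2 - dz4 * z4
    d[15] = a5 - s5 - kiz5 * z5 + kex1 * x3 - dz5 * z5
    d[16] = kp3 * (y3 + exo[2]) - kiz6 * z6 - dz6 * z6
    d[17] = kp4 * (y4 + exo[3]) - kiz7 * z7 - dz7 * z7
    d[18] = kp5 * (y5 + exo[4]) - kiz8 * z8 - dz8 * z8

    for i in range(19):
        if clamp_mask[i]:
            d[i] = 0.0
    return d


@njit(cache=False)
def rk4_sample(y0, t0, t_end, step, record_every,
               p, clamp_mask, clamp_values, pool_clamp, exo):
    """Classical fixed-step 4th-order Runge-Kutta with strided sampling.

    Returns (times, states) with one row every ``record_every`` steps.
    Serves as the independent cross-check for the adaptive integrator and
    as the fast engine for parameter calibration.
    """
    n_steps = int(np.ceil((t_end - t0) / step))
    n_rec = n_steps // record_every + 1
    times = np.empty(n_rec)
    states = np.empty((n_rec, y0.shape[0]))
    y = y0.copy()
    t = t0
    times[0] = t
    states[0] = y
    rec = 1
    for i in range(1, n_steps + 1):
        k1 = rhs_kernel(t, y, p, clamp_mask, clamp_values, pool_clamp, exo)
        k2 = rhs_kernel(t + 0.5 * step, y + 0.5 * step * k1,
                        p, clamp_mask, clamp_values, pool_clamp, exo)
        k3 = rhs_kernel(t + 0.5 * step, y + 0.5 * step * k2,
                        p, clamp_mask, clamp_values, pool_clamp, exo)
        k4 = rhs_kernel(t + step, y + step * k3,
                        p, clamp_mask, clamp_values, pool_clamp, exo)
        y = y + (step / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t = t0 + i * step
        if i % record_every == 0 and rec < n_rec:
            times[rec] = t
            states[rec] = y
            rec += 1
    return times[:rec], states[:rec]


def neutral_perturbation_args():
    """(clamp_mask, clamp_values, pool_clamp, exo) for the unperturbed model."""
    return (
        np.zeros(19, dtype=np.bool_),
        np.zeros(19, dtype=np.float64),
        NO_POOL_CLAMP,
        np.zeros(5, dtype=np.float64),
    )
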