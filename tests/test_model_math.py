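"""Mathematical properties of the RHS, Jacobian and kinetic laws."""

import numpy as np
import pytest

import circlock as cl
from circlock.model import find_fixed_point, rhs_reference
from circlock.species import species_index

RNG = np.random.default_rng(42)


def transcription_rates(model, state):
    """Back out the five transcription fluxes from the RHS (v = dy + d*y)."""
    d = cl.rhs(state, model)
    p = model.params
    rates = {}
    for gene, idx, deg in (
        ("Per", 6, "dy1"), ("Cry", 7, "dy2"), ("Rev-Erb", 8, "dy3"),
        ("Ror", 9, "dy4"), ("Bmal", 10, "dy5"),
    ):
        rates[gene] = d[idx] + p[deg] * state[idx]
    return rates


def test_rhs_at_zero_state_leaves_only_basal_transcription(model):
    d = cl.rhs(np.zeros(19), model)
    # mass action, transport and linear degradation all vanish at 0
    for i in range(19):
        if i in (6, 7, 8, 9, 10):
            assert d[i] >= 0.0  # basal transcription
        else:
            assert d[i] == pytest.approx(0.0, abs=1e-15)


def test_complex_association_flux_is_stoichiometric(model):
    """The PER/CRY_C association flux enters -1/-1/+1 in PER_C, CRY_C and
    the complex (checked by switching the association rate off)."""
    state = RNG.uniform(0.2, 2.0, size=19)
    d_on = cl.rhs(state, model)
    m_off = model.with_params(model.params.replace(kfz5=0.0))
    d_off = cl.rhs(state, m_off)
    flux = model.params["kfz5"] * state[11] * state[13]
    delta = d_on - d_off
    expected = np.zeros(19)
    expected[11] -= flux   # PER_C consumed
    expected[13] -= flux   # CRY_C consumed
    expected[15] += flux   # PER/CRY_C produced
    np.testing.assert_allclose(delta, expected, atol=1e-12)


def test_kernel_agrees_with_symbolically_derived_rhs(model):
    for _ in range(20):
        state = RNG.uniform(0.0, 5.0, size=19)
        np.testing.assert_allclose(
            cl.rhs(state, model), rhs_reference(state, model),
            rtol=1e-12, atol=1e-12,
        )


def test_rhs_matches_finite_difference_of_trajectory(model):
    """Centered differences of a finely sampled, accurately integrated
    trajectory reproduce the RHS to <= 1e-4 relative error."""
    traj = cl.integrate(
        model,
        cl.SimulationSettings(t_end=48.0, output_step=0.005,
                              transient_discard=0.0),
    )
    t, x = traj.times, traj.states
    dt = t[1] - t[0]
    for i in range(2000, 2100):
        fd = (x[i + 1] - x[i - 1]) / (2 * dt)
        an = cl.rhs(x[i], model)
        scale = np.maximum(np.abs(an), 1e-2)
        assert np.max(np.abs(fd - an) / scale) < 1e-4


def test_jacobian_matches_central_differences(model):
    state = RNG.uniform(0.3, 2.0, size=19)
    J = cl.jacobian(state, model)
    num = np.zeros_like(J)
    for j in range(19):
        h = 1e-6 * max(1.0, abs(state[j]))
        sp_, sm = state.copy(), state.copy()
        sp_[j] += h
        sm[j] -= h
        num[:, j] = (cl.rhs(sp_, model) - cl.rhs(sm, model)) / (2 * h)
    scale = np.maximum(np.abs(J), 1e-3)
    assert np.max(np.abs(J - num) / scale) < 1e-6


def test_mrna_jacobian_diagonal_bounded_by_degradation(model):
    """Linear decay puts -d on the diagonal; inhibitor feedback can only
    push mRNA diagonals further down (pool inhibition is monotone)."""
    p = model.params
    for _ in range(5):
        state = RNG.uniform(0.2, 3.0, size=19)
        J = cl.jacobian(state, model)
        for idx, deg in ((6, "dy1"), (7, "dy2"), (8, "dy3"), (9, "dy4"), (10, "dy5")):
            assert J[idx, idx] <= -p[deg] + 1e-12


@pytest.mark.parametrize("regulator,genes,sign", [
    ("CLOCK/BMAL", ("Per", "Cry", "Rev-Erb", "Ror"), +1),
    ("PERp/CRY_N", ("Per", "Cry", "Rev-Erb", "Ror"), -1),
    ("PER/CRY_N", ("Per", "Cry", "Rev-Erb", "Ror"), -1),
    ("REV-ERB_N", ("Cry", "Bmal"), -1),
    ("ROR_N", ("Bmal",), +1),
])
def test_transcription_monotone_in_each_regulator(model, regulator, genes, sign):
    idx = species_index(regulator)
    for _ in range(10):
        state = RNG.uniform(0.1, 4.0, size=19)
        lo = transcription_rates(model, state)
        hi_state = state.copy()
        hi_state[idx] *= 1.5
        hi = transcription_rates(model, hi_state)
        for gene in genes:
            assert sign * (hi[gene] - lo[gene]) >= -1e-12


def test_percry_pool_is_the_sum_of_the_nuclear_complexes():
    state = np.zeros(19)
    assert cl.percry_pool(state) == 0.0
    state[species_index("PER/CRY_N")] = 0.8
    state[species_index("PERp/CRY_N")] = 0.91
    assert cl.percry_pool(state) == pytest.approx(1.71)


def test_positivity_invariance_from_random_nonnegative_states(model):
    settings = cl.SimulationSettings(
        t_end=6 * 24.0, output_step=0.1, transient_discard=0.0
    )
    for seed in range(3):
        rng = np.random.default_rng(seed)
        y0 = rng.uniform(0.0, 3.0, size=19)
        traj = cl.integrate(
            model,
            cl.SimulationSettings(
                t_end=settings.t_end, output_step=settings.output_step,
                transient_discard=0.0, initial_state=y0,
            ),
        )
        assert traj.states.min() >= -10 * settings.atol


def test_concentration_rescaling_symmetry_preserves_period(model, wt_summary):
    """Multiplying concentration-like constants and the state by c (and
    dividing bimolecular rates by c) rescales units without changing the
    period."""
    for c in (0.5, 2.0):
        p = model.params
        scaled = p.replace(
            **{k: p[k] * c for k in ("V1max", "V2max", "V3max", "V4max", "V5max",
                                      "ka1", "ka2", "ka3", "ka4", "ka5",
                                      "ki1", "ki2", "ki3", "ki4", "ki5", "ki6")},
            kfz4=p["kfz4"] / c,
            kfz5=p["kfz5"] / c,
        )
        m2 = model.with_params(scaled)
        traj = cl.integrate(
            m2,
            cl.SimulationSettings(
                t_end=40 * 24.0, output_step=0.05,
                transient_discard=20 * 24.0,
                initial_state=np.full(19, c),
            ),
        )
        period = cl.estimate_period(traj, "Bmal")
        assert period == pytest.approx(wt_summary.period, abs=0.01)


def test_wt_fixed_point_is_unstable_spiral(model):
    """The limit cycle surrounds an unstable fixed point whose leading
    eigenvalues are a complex pair with positive real part."""
    fp = find_fixed_point(model)
    assert np.max(np.abs(cl.rhs(fp, model))) < 1e-9
    eig = np.linalg.eigvals(cl.jacobian(fp, model))
    lead = eig[np.argmax(eig.real)]
    assert lead.real > 0
    assert abs(lead.imag) > 0
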