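import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampmm import autodiff as ad
from ampmm.coupling import (es_qmmm, f_switch, lj_qmmm, polarization_update,
                            radial_T, switched_coulomb_qm,
                            total_energy_forces)
from ampmm.model import _envelope_var
from ampmm.surrogate import make_system
from ampmm.system import MMZone, QMZone, SimulationSystem
from ampmm.units import KE


def test_switch_boundaries_and_monotonicity():
    assert f_switch(0.0, 5.0) == 1.0
    assert f_switch(5.0, 5.0) == 0.0
    assert f_switch(7.0, 5.0) == 0.0
    r = np.linspace(0, 5, 200)
    f = f_switch(r, 5.0)
    assert np.all(np.diff(f) <= 0)
    assert 0.0 < f_switch(2.5, 5.0) < 1.0
    with pytest.raises(ValueError):
        f_switch(1.0, 0.0)


@settings(derandomize=True, max_examples=60)
@given(r=st.floats(0.0, 30.0), r_c=st.floats(0.1, 20.0))
def test_switch_bounded_and_zero_beyond_cutoff(r, r_c):
    f = f_switch(r, r_c)
    assert 0.0 <= f <= 1.0
    if r >= r_c:
        assert f == 0.0


def test_switch_c2_at_both_ends():
    h = 1e-5
    for r0 in (0.0, 5.0):
        d1 = (f_switch(r0 + h, 5.0) - f_switch(max(r0 - h, 0.0), 5.0)) / (2 * h)
        assert abs(d1) < 1e-8 or r0 == 0.0  # one-sided at 0
    # second derivative ~ 0 near the cutoff
    d2 = (f_switch(5 - 2 * h, 5.0) - 2 * f_switch(5 - h, 5.0)
          + f_switch(5.0, 5.0)) / h ** 2
    assert abs(d2) < 1e-3


def test_envelope_var_matches_f_switch():
    r = np.linspace(0.01, 6.0, 50)
    env = _envelope_var(ad.Var(r), 5.0).data
    assert np.allclose(env, f_switch(r, 5.0), atol=1e-12)


def test_switched_coulomb_beyond_cutoff_is_plain():
    v = switched_coulomb_qm([1.0, -1.0],
                            [[0, 0, 0], [10.0, 0, 0]], r_graph=5.0)
    assert np.isclose(v, -KE / 10.0, rtol=1e-12)     # -13.8935 kJ/mol
    assert np.isclose(v, -13.8935458, atol=1e-4)


def test_switched_coulomb_damped_at_contact():
    v = switched_coulomb_qm([1.0, -1.0], [[0, 0, 0], [1e-3, 0, 0]])
    assert abs(v) < 1e-2     # (1 - f)/r stays bounded, O(r^2) energy


def test_switched_coulomb_single_atom_zero():
    assert switched_coulomb_qm([1.0], [[0, 0, 0]]) == 0.0


def test_radial_t_values():
    assert radial_T(0, 2.0) == 0.5
    assert radial_T(2, 1.0) == 3.0
    assert radial_T(1, 10.0) == pytest.approx(0.01)
    with pytest.raises(ValueError):
        radial_T(3, 1.0)
    with pytest.raises(ValueError):
        radial_T(0, 0.0)


def test_es_monopole_equals_coulomb():
    v = es_qmmm([1.0], np.zeros((1, 3)), np.zeros((1, 3, 3)),
                [[0, 0, 0]], [[10.0, 0, 0]], [1.0])
    assert np.isclose(v, KE / 10.0, rtol=1e-12)


def test_es_dipole_perpendicular_is_zero():
    mu = np.array([[0.0, 1.0, 0.0]])   # perpendicular to u = +x
    v = es_qmmm([0.0], mu, np.zeros((1, 3, 3)),
                [[0, 0, 0]], [[10.0, 0, 0]], [1.0])
    assert v == 0.0


def test_es_dipole_matches_shrinking_point_charges():
    """Finite dipole of +/- dq at separation d converges with O(d^2)."""
    mu_mag, r = 0.3, 8.0
    axis = np.array([1.0, 0, 0])
    mm_pos, mm_q = [[r, 0, 0]], [0.7]
    exact = es_qmmm([0.0], mu_mag * axis[None], np.zeros((1, 3, 3)),
                    [[0, 0, 0]], mm_pos, mm_q)
    errs = []
    for d in (0.4, 0.2, 0.1):
        dq = mu_mag / d
        v = (KE * dq * mm_q[0] / (r - d / 2)
             - KE * dq * mm_q[0] / (r + d / 2))
        errs.append(abs(v - exact))
    errs = np.array(errs)
    assert errs[-1] < 1e-3
    ratio = errs[:-1] / errs[1:]
    assert np.all(ratio > 3.2)         # halving d ~ quarters the error


def test_lj_examples():
    def dimer(r):
        qm = QMZone([6], [[0, 0, 0]], lj_epsilon=[0.5], lj_sigma=[3.0])
        mm = MMZone(np.array([[r, 0, 0]]), np.zeros(1), np.array([0.5]),
                    np.array([3.0]), np.zeros(1, dtype=int))
        return SimulationSystem(qm, mm)

    assert abs(lj_qmmm(dimer(3.0))) < 1e-12
    assert np.isclose(lj_qmmm(dimer(2 ** (1 / 6) * 3.0)), -0.5, rtol=1e-10)
    v_far = lj_qmmm(dimer(12.0))
    assert -1e-3 < v_far < 0.0


def _pol_setup(tiny_model, mm_positions, mm_charges):
    Z = np.array([6, 8])
    R = ad.Var(np.array([[[0.0, 0, 0], [1.3, 0, 0]]]))
    p = tiny_model.param_vars()
    C = tiny_model.config.n_multipole_channels
    rng = np.random.default_rng(0)
    M = (ad.Var(rng.normal(size=(1, 2, C))),
         ad.Var(rng.normal(size=(1, 2, C, 3))),
         ad.Var(rng.normal(size=(1, 2, C, 3, 3))))
    h = ad.Var(rng.normal(size=(1, 2, tiny_model.config.node_size)))
    m = len(mm_charges)
    pq, pm = np.meshgrid(np.arange(2), np.arange(m), indexing="ij")
    mm = {"R": ad.Var(np.asarray(mm_positions, dtype=float)[None]),
          "q": ad.Var(np.asarray(mm_charges, dtype=float)[None]),
          "pol_pairs": (pq.ravel(), pm.ravel())}
    return p, M, h, R, mm


def test_polarization_no_charges_leaves_state(tiny_model):
    p, M, h, R, mm = _pol_setup(tiny_model, np.zeros((0, 3)), [])
    mm["pol_pairs"] = (np.zeros(0, dtype=int), np.zeros(0, dtype=int))
    M2 = polarization_update(tiny_model, p, M, h, R, mm)
    for a, b in zip(M, M2):
        assert np.array_equal(a.data, b.data)


def test_polarization_inversion_symmetric_charges(tiny_model):
    """Charges inversion-symmetric about an atom induce no dipole there."""
    Z = np.array([6])
    R = ad.Var(np.zeros((1, 1, 3)))
    p = tiny_model.param_vars()
    C = tiny_model.config.n_multipole_channels
    M = (ad.Var(np.zeros((1, 1, C))), ad.Var(np.zeros((1, 1, C, 3))),
         ad.Var(np.zeros((1, 1, C, 3, 3))))
    h = ad.Var(np.ones((1, 1, tiny_model.config.node_size)))
    mm_pos = np.array([[3.0, 1.0, 0.5], [-3.0, -1.0, -0.5],
                       [0.0, 4.0, 0.0], [0.0, -4.0, 0.0]])
    mm_q = np.array([0.3, 0.3, -0.2, -0.2])
    pq = np.zeros(4, dtype=int)
    pm = np.arange(4)
    mm = {"R": ad.Var(mm_pos[None]), "q": ad.Var(mm_q[None]),
          "pol_pairs": (pq, pm)}
    out = polarization_update(tiny_model, p, M, h, R, mm)
    assert np.abs(out[1].data).max() < 1e-6


def test_polarization_linear_in_mm_charges(tiny_model):
    mm_pos = np.array([[3.0, 1.0, 0.0], [0.0, 4.0, 1.0]])
    p, M, h, R, mm = _pol_setup(tiny_model, mm_pos, [0.3, -0.2])
    base = polarization_update(tiny_model, p, M, h, R, mm)
    d_base = base[1].data - M[1].data
    mm2 = dict(mm)
    mm2["q"] = ad.Var(mm["q"].data * 2.5)
    scaled = polarization_update(tiny_model, p, M, h, R, mm2)
    d_scaled = scaled[1].data - M[1].data
    # the explicit q_j factor scales linearly (network b held fixed)
    assert np.allclose(d_scaled, 2.5 * d_base, rtol=1e-10)


def test_breakdown_sums_and_empty_mm(tiny_model, spec):
    sys_ = SimulationSystem(QMZone(spec.atomic_numbers, spec.positions0))
    b, f = total_energy_forces(sys_, tiny_model)
    assert b.V_ES_QMMM == 0.0 and b.V_LJ_QMMM == 0.0 and b.V_MM == 0.0
    assert f.f_mm.shape == (0, 3)
    parts = b.V_AMP + b.V_ES_QM + b.V_ES_QMMM + b.V_LJ_QMMM + b.V_MM
    assert abs(b.V_total - parts) <= 1e-9 * max(1.0, abs(parts))


def test_total_energy_translation_invariant(tiny_model, solvated_system):
    b1, _ = total_energy_forces(solvated_system, tiny_model)
    moved = copy.deepcopy(solvated_system)
    moved.qm.positions = moved.qm.positions + 11.3
    moved.mm.positions = moved.mm.positions + 11.3
    b2, _ = total_energy_forces(moved, tiny_model)
    assert abs(b1.V_total - b2.V_total) < 1e-6


def test_newtons_third_law(tiny_model, solvated_system):
    _, f = total_energy_forces(solvated_system, tiny_model)
    total = f.f_qm.sum(axis=0) + f.f_mm.sum(axis=0)
    assert np.abs(total).max() < 1e-6
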