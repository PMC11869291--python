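import numpy as np
import pytest

from ampmm.dynamics import (DegenerateDihedralError, IntegratorConfig,
                            Restraint, UmbrellaWindow, cumulative_sampling_ns,
                            dihedral_angle, integrate, kinetic_energy,
                            maxwell_boltzmann, mm_forcefield,
                            restraint_energy, run_umbrella, sd_step,
                            umbrella_schedule)
from ampmm.surrogate import toy_dimer
from ampmm.system import MMZone
from ampmm.units import KB, KE


# -- restraints ---------------------------------------------------------

def test_restraint_zero_at_center():
    rest = Restraint("distance", (0, 1), 2.0, 100.0)
    e, f = restraint_energy(rest, [[0, 0, 0], [2.0, 0, 0]])
    assert e == 0.0 and np.allclose(f, 0.0)


def test_distance_restraint_value():
    rest = Restraint("distance", (0, 1), 2.0, 100.0)
    e, _ = restraint_energy(rest, [[0, 0, 0], [2.1, 0, 0]])
    assert np.isclose(e, 0.5, atol=1e-10)      # 1/2 * 100 * 0.01


def test_dihedral_wrapping_short_way():
    """+179 deg against a center of -179 deg deviates by 2, not 358."""
    rest = Restraint("dihedral", (0, 1, 2, 3), -179.0, 1.0)
    pos = np.array([[1.0, 0.1, -1.0], [0, 0, -1], [0, 0, 0], [0, 0, 0]])
    # build a geometry with dihedral ~ +179
    phi_target = np.radians(179.0)
    pos[3] = [np.cos(phi_target), np.sin(phi_target), 1.0]
    pos[0] = [1.0, 0.0, -1.0]
    phi, _ = dihedral_angle(pos, (0, 1, 2, 3))
    assert abs(phi - 179.0) < 1e-6
    e, _ = restraint_energy(rest, pos)
    assert np.isclose(e, 0.5 * 2.0 ** 2, atol=1e-6)


def test_restraint_forces_match_finite_differences():
    rng = np.random.default_rng(0)
    cases = [
        (Restraint("distance", (0, 1), 2.5, 37.0), rng.normal(size=(2, 3)) * 2),
        (Restraint("dihedral", (0, 1, 2, 3), 40.0, 0.03),
         rng.normal(size=(4, 3)) * 1.5),
    ]
    h = 1e-6
    for rest, x in cases:
        _, f = restraint_energy(rest, x)
        for i in np.ndindex(x.shape):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            fd = -(restraint_energy(rest, xp)[0]
                   - restraint_energy(rest, xm)[0]) / (2 * h)
            assert abs(fd - f[i]) < 1e-5 * max(1.0, abs(f[i]))


def test_collinear_dihedral_raises():
    pos = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
    with pytest.raises(DegenerateDihedralError):
        dihedral_angle(pos, (0, 1, 2, 3))


def test_restraint_argument_validation():
    with pytest.raises(ValueError):
        Restraint("distance", (0, 1, 2), 1.0, 1.0)
    with pytest.raises(ValueError):
        Restraint("dihedral", (0, 1, 2, 3), 0.0, -1.0)


# -- integrator ---------------------------------------------------------

def test_zero_force_zero_friction_is_straight_line():
    cfg = IntegratorConfig(dt=1.0, scheme="nve", friction=0.0)
    x = np.zeros((1, 3))
    v = np.array([[0.1, 0.0, 0.0]])
    f = np.zeros((1, 3))
    pot = lambda y: (0.0, np.zeros_like(y))
    for _ in range(10):
        x, v, f, _ = sd_step(x, v, f, [12.0], pot, cfg,
                             np.random.default_rng(0))
    assert np.allclose(x, [[1.0, 0, 0]], atol=1e-12)


def test_nve_energy_conservation_on_dimer():
    dimer = toy_dimer()
    cfg = IntegratorConfig(dt=0.1, scheme="nve", friction=0.0, seed=4)
    rng = np.random.default_rng(4)
    x = dimer.start_positions(3.0)
    v = maxwell_boltzmann(dimer.masses, 298.0, rng)
    e0 = dimer.potential(x)[0] + kinetic_energy(v, dimer.masses)
    _, f = dimer.potential(x)
    drift = 0.0
    for _ in range(10000):
        x, v, f, e_pot = sd_step(x, v, f, dimer.masses, dimer.potential, cfg,
                                 rng)
        drift = max(drift, abs(e_pot + kinetic_energy(v, dimer.masses) - e0))
    assert drift < 0.1


def test_equipartition_of_sd_oscillator():
    """1-D harmonic oscillator under Langevin dynamics: mean kinetic
    energy per particle approaches (3/2) kT."""
    k_spring, T = 50.0, 298.0
    cfg = IntegratorConfig(dt=1.0, temperature=T, friction=10.0, seed=9)
    rng = np.random.default_rng(9)
    m = np.array([12.0])
    pot = lambda y: (0.5 * k_spring * float(y[0] @ y[0]), -k_spring * y)
    x = np.zeros((1, 3))
    v = maxwell_boltzmann(m, T, rng)
    _, f = pot(x)
    ke = 0.0
    n = 10 ** 6
    for step in range(n):
        x, v, f, _ = sd_step(x, v, f, m, pot, cfg, rng)
        ke += kinetic_energy(v, m)
    assert np.isclose(ke / n, 1.5 * KB * T, rtol=0.03)


def test_integrate_aborts_on_blowup():
    pot = lambda y: (0.0, np.full_like(y, 1e12))
    with pytest.raises(FloatingPointError):
        integrate(np.zeros((1, 3)), [1.0], pot,
                  IntegratorConfig(dt=1.0), 5)


# -- MM force field -----------------------------------------------------

def _mm_pair(r, q=0.0, eps=0.3, sigma=3.0):
    return MMZone(np.array([[0, 0, 0], [r, 0, 0.0]]), np.array([q, -q]),
                  np.full(2, eps), np.full(2, sigma), np.arange(2))


def test_mm_lj_minimum():
    v, f = mm_forcefield(_mm_pair(2 ** (1 / 6) * 3.0))
    assert np.isclose(v, -0.3, rtol=1e-10)
    assert np.abs(f).max() < 1e-9


def test_mm_truncation_beyond_cutoff():
    v, _ = mm_forcefield(_mm_pair(15.0, q=0.5, eps=0.0))
    assert v == 0.0


def test_mm_reaction_field_limits_to_direct_coulomb():
    """dielectric -> 1 and cutoff -> infinity recovers the bare sum."""
    r, q = 4.0, 0.5
    direct = -KE * q * q / r
    for cutoff in (20.0, 100.0, 400.0):
        v, _ = mm_forcefield(_mm_pair(r, q=q, eps=0.0), cutoff=cutoff,
                             dielectric=1.0)
        assert abs(v - direct) < abs(direct) * (r / cutoff) * 1.1
    v, _ = mm_forcefield(_mm_pair(r, q=q, eps=0.0), cutoff=400.0,
                         dielectric=1.0)
    assert np.isclose(v, direct, rtol=0.01)


def test_mm_forces_match_finite_differences():
    rng = np.random.default_rng(3)
    pos = rng.uniform(0, 8, size=(5, 3))
    mm = MMZone(pos, rng.normal(size=5) * 0.3, np.full(5, 0.2),
                np.full(5, 3.0), np.arange(5))
    v, f = mm_forcefield(mm, dielectric=40.0)
    h = 1e-6
    for i in np.ndindex(pos.shape):
        mm2 = MMZone(pos.copy(), mm.charges, mm.lj_epsilon, mm.lj_sigma,
                     mm.group_ids)
        mm2.positions[i] += h
        vp, _ = mm_forcefield(mm2, dielectric=40.0)
        mm2.positions[i] -= 2 * h
        vm, _ = mm_forcefield(mm2, dielectric=40.0)
        assert abs(-(vp - vm) / (2 * h) - f[i]) < 1e-4


# -- umbrella machinery -------------------------------------------------

def test_dihedral_grid_has_hundred_windows():
    windows = umbrella_schedule("dihedral_2d", 10)
    assert len(windows) == 100
    centers = {w.restraints[0].center for w in windows}
    assert len(centers) == 10
    assert all(-180.0 < c <= 180.0 for c in centers)


def test_distance_grid_end_points():
    w = umbrella_schedule("distance_1d", 45)
    assert w[0].restraints[0].center == 2.0
    assert w[-1].restraints[0].center == 20.0
    w2 = umbrella_schedule("distance_1d", 2)
    assert [x.restraints[0].center for x in w2] == [2.0, 20.0]
    with pytest.raises(ValueError):
        umbrella_schedule("distance_1d", 1)


def test_cumulative_sampling_arithmetic():
    assert cumulative_sampling_ns(45, 3, 1.0) == 135.0
    assert cumulative_sampling_ns(42, 3, 1.0) == 126.0


def test_umbrella_sampling_variance_matches_closed_form():
    """Harmonic potential + harmonic restraint at the same center: the
    sampled coordinate is Gaussian with variance kT/(k_pot + k_rest)."""
    k_pot, k_rest, T = 30.0, 20.0, 298.0
    r0 = 5.0

    def pot(x):
        d = x[1] - x[0]
        r = np.linalg.norm(d)
        u = d / r
        g = k_pot * (r - r0) * u
        return 0.5 * k_pot * (r - r0) ** 2, np.array([g, -g])

    windows = [UmbrellaWindow([Restraint("distance", (0, 1), r0, k_rest)],
                              equilibration_steps=2000,
                              production_steps=60000, output_stride=5)]
    cfg = IntegratorConfig(dt=1.0, temperature=T, friction=10.0, seed=12)
    x0 = np.array([[0.0, 0, 0], [r0, 0, 0]])
    done = run_umbrella(x0, [14.0, 14.0], pot, windows, cfg, replicates=3)
    samples = np.concatenate(done[0].series)
    var = samples.var()
    expect = KB * T / (k_pot + k_rest)
    assert np.isclose(var, expect, rtol=0.05)


def test_umbrella_deterministic_for_fixed_seed():
    dimer = toy_dimer()
    windows = umbrella_schedule("distance_1d", 2, lo=2.5, hi=4.0,
                                force_constant=10.0,
                                equilibration_steps=50,
                                production_steps=200, output_stride=10)
    cfg = IntegratorConfig(dt=1.0, seed=7, friction=5.0)
    kw = dict(replicates=3,
              initialize=lambda w: dimer.start_positions(
                  w.restraints[0].center))
    a = run_umbrella(dimer.start_positions(3.0), dimer.masses,
                     dimer.potential, windows, cfg, **kw)
    b = run_umbrella(dimer.start_positions(3.0), dimer.masses,
                     dimer.potential, windows, cfg, **kw)
    for wa, wb in zip(a, b):
        for sa, sb in zip(wa.series, wb.series):
            assert np.array_equal(sa, sb)


def test_umbrella_zero_production_steps_rejected():
    dimer = toy_dimer()
    w = UmbrellaWindow([Restraint("distance", (0, 1), 3.0, 10.0)],
                       production_steps=0)
    with pytest.raises(ValueError):
        run_umbrella(dimer.start_positions(3.0), dimer.masses,
                     dimer.potential, [w], IntegratorConfig())
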