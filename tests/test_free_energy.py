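"""WHAM, Jacobian correction, and dissociation free energies, validated
against direct sampling from known distributions (no MD needed here)."""

import numpy as np
import pytest

from ampmm.dynamics import Restraint, UmbrellaWindow
from ampmm.free_energy import (PMFResult, bootstrap_errors, delta_g,
                               jacobian_correct, wham)
from ampmm.units import KB

KT = KB * 298.0


def _boltzmann_samples(u_fun, lo, hi, n, rng):
    """Inverse-CDF sampling from p(x) ~ exp(-u(x)/kT) on [lo, hi]."""
    grid = np.linspace(lo, hi, 4001)
    p = np.exp(-u_fun(grid) / KT)
    cdf = np.cumsum(p)
    cdf /= cdf[-1]
    return np.interp(rng.uniform(size=n), cdf, grid)


def _window(center, k, samples):
    w = UmbrellaWindow([Restraint("distance", (0, 1), center, k)])
    w.series = [np.asarray(samples)]
    return w


def test_flat_potential_yields_flat_pmf():
    rng = np.random.default_rng(0)
    k = 5.0
    windows = []
    for c in np.linspace(2.0, 8.0, 7):
        bias = lambda x, c=c: 0.5 * k * (x - c) ** 2
        windows.append(_window(c, k, _boltzmann_samples(
            bias, 0.0, 10.0, 20000, rng)))
    pmf = wham(windows, bins=40, coordinate_range=(2.0, 8.0))
    ok = np.isfinite(pmf.free_energy)
    assert pmf.free_energy[ok].max() < 0.35      # sampling noise only


def test_wham_recovers_double_well():
    rng = np.random.default_rng(1)
    u = lambda x: 4.0 * ((x - 4.0) ** 2) * ((x - 6.0) ** 2) / 4.0
    k = 30.0
    windows = []
    for c in np.linspace(3.0, 7.0, 11):
        total = lambda x, c=c: u(x) + 0.5 * k * (x - c) ** 2
        windows.append(_window(c, k, _boltzmann_samples(
            total, 2.0, 8.0, 30000, rng)))
    pmf = wham(windows, bins=60, coordinate_range=(3.0, 7.0))
    ref = u(pmf.bin_centers)
    ref -= ref.min()
    ok = np.isfinite(pmf.free_energy) & (ref < 12.0)
    assert np.abs(pmf.free_energy[ok] - ref[ok]).max() < 0.5


def test_two_identical_windows_match_pooled_window():
    rng = np.random.default_rng(2)
    k = 10.0
    samp = _boltzmann_samples(lambda x: 0.5 * k * (x - 5.0) ** 2,
                              2.0, 8.0, 20000, rng)
    a, b = samp[:10000], samp[10000:]
    two = [_window(5.0, k, a), _window(5.0, k, b)]
    pooled = _window(5.0, k, samp)
    pmf2 = wham(two, bins=30, coordinate_range=(3.5, 6.5))
    pmf1 = wham([pooled], bins=30, coordinate_range=(3.5, 6.5))
    ok = np.isfinite(pmf1.free_energy) & np.isfinite(pmf2.free_energy)
    assert np.abs(pmf1.free_energy[ok] - pmf2.free_energy[ok]).max() < 1e-9


def test_wham_requires_samples():
    w = UmbrellaWindow([Restraint("distance", (0, 1), 3.0, 5.0)])
    with pytest.raises(ValueError):
        wham([w])


def test_2d_periodic_bias_wraps():
    rng = np.random.default_rng(3)
    w = UmbrellaWindow([Restraint("dihedral", (0, 1, 2, 3), 175.0, 0.05),
                        Restraint("dihedral", (1, 2, 3, 4), 0.0, 0.05)])
    phi = 175.0 + rng.normal(0, 8, size=5000)
    phi = -((-phi + 180.0) % 360.0 - 180.0)   # wrapped samples
    psi = rng.normal(0, 8, size=5000)
    w.series = [np.stack([phi, psi], axis=1)]
    pmf = wham([w], bins=(36, 36), periodic=True)
    assert pmf.free_energy.shape == (36, 36)
    # minimum sits in the row nearest +/-180, not mid-range
    imin = np.unravel_index(np.nanargmin(pmf.free_energy),
                            pmf.free_energy.shape)
    phi_min = pmf.bin_centers[imin[0], imin[1], 0]
    assert abs(abs(phi_min) - 175.0) < 15.0


def test_jacobian_flat_for_ideal_gas():
    """Radial histogram of a free particle gives G_raw = -kT ln(4 pi r^2);
    the corrected profile is flat."""
    r = np.linspace(2.0, 10.0, 50)
    g_raw = -KT * np.log(4 * np.pi * r ** 2)
    pmf = PMFResult(r, g_raw - g_raw.min())
    flat = jacobian_correct(pmf)
    ok = np.isfinite(flat.free_energy)
    assert np.abs(flat.free_energy[ok]).max() < 1e-9


def test_jacobian_doubling_r_arithmetic():
    r = np.array([2.0, 4.0, 20.0])
    pmf = PMFResult(r, np.zeros(3))
    out = jacobian_correct(pmf)
    # equal raw G: the correction changes G(2r) - G(r) by 2 kT ln 2
    assert np.isclose(out.free_energy[1] - out.free_energy[0],
                      2 * KT * np.log(2.0), atol=1e-12)


def test_jacobian_involution():
    rng = np.random.default_rng(4)
    r = np.linspace(2.0, 10.0, 30)
    g = rng.uniform(0, 5, size=30)
    g -= g.min()
    pmf = PMFResult(r, g)
    back = jacobian_correct(jacobian_correct(pmf), inverse=True)
    assert np.allclose(back.free_energy, g, atol=1e-10)


def test_delta_g_symmetric_ratio_is_zero():
    r = np.linspace(1.0, 9.0, 400)
    pmf = PMFResult(r, KT * np.log(4 * np.pi * r ** 2))  # cancels Jacobian
    pmf.free_energy -= pmf.free_energy.min()
    dg = delta_g(pmf, barrier=5.0, r_max=9.0)
    # p ~ const dr on both sides: ratio (9-5)/(5-1) = 1
    assert abs(dg) < 5e-3


def test_delta_g_rt_arithmetic():
    """p_unbound / p_bound = e gives -RT = -2.478 kJ/mol at 298 K."""
    r = np.linspace(1.0, 9.0, 2000)
    g = KT * np.log(4 * np.pi * r ** 2)
    g = np.where(r > 5.0, g - KT, g)   # boost outer density by factor e
    # widths equal -> ratio of integrals is exactly e
    pmf = PMFResult(r, g - g.min())
    dg = delta_g(pmf, barrier=5.0, r_max=9.0)
    assert np.isclose(dg, -2.478, atol=0.02)


def test_delta_g_invariant_to_constant_shift():
    r = np.linspace(2.0, 10.0, 300)
    g = (r - 4.0) ** 2 * 0.3
    a = delta_g(PMFResult(r, g), 6.0, 10.0)
    b = delta_g(PMFResult(r, g + 7.0), 6.0, 10.0)
    assert np.isclose(a, b, atol=1e-9)


def test_delta_g_rejects_empty_side():
    r = np.linspace(2.0, 10.0, 100)
    with pytest.raises(ValueError):
        delta_g(PMFResult(r, np.zeros(100)), barrier=0.5, r_max=1.0)


def _replicated_windows(rng, n_rep=3, n=4000):
    windows = []
    k = 10.0
    for c in (3.0, 4.5):
        w = UmbrellaWindow([Restraint("distance", (0, 1), c, k)])
        w.series = [_boltzmann_samples(
            lambda x, c=c: 0.5 * k * (x - c) ** 2, 1.0, 7.0, n, rng)
            for _ in range(n_rep)]
        windows.append(w)
    return windows


def test_bootstrap_single_resample_gives_zero_errors():
    rng = np.random.default_rng(5)
    windows = _replicated_windows(rng)
    err = bootstrap_errors(windows, n_boot=1, seed=0, bins=20,
                           coordinate_range=(2.0, 5.5))
    ok = np.isfinite(err)
    assert np.allclose(err[ok], 0.0)


def test_bootstrap_deterministic_and_positive():
    rng = np.random.default_rng(6)
    windows = _replicated_windows(rng)
    kw = dict(bins=20, coordinate_range=(2.0, 5.5))
    e1 = bootstrap_errors(windows, n_boot=20, seed=3, **kw)
    e2 = bootstrap_errors(windows, n_boot=20, seed=3, **kw)
    ok = np.isfinite(e1)
    assert np.array_equal(e1[ok], e2[ok])
    assert np.all(e1[ok] >= 0)


def test_bootstrap_error_shrinks_with_more_data():
    rng = np.random.default_rng(7)
    small = _replicated_windows(rng, n=800)
    big = _replicated_windows(rng, n=6400)
    kw = dict(bins=20, coordinate_range=(2.0, 5.5))
    e_small = bootstrap_errors(small, n_boot=25, seed=1, **kw)
    e_big = bootstrap_errors(big, n_boot=25, seed=1, **kw)
    assert np.nanmean(e_big) < np.nanmean(e_small)
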