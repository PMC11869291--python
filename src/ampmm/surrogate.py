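"""Surrogate ground-truth potential and dataset generators.

The surrogate is an analytic stand-in for the expensive reference
calculations that label training snapshots in production use.  It has the
same mathematical structure as such labels: an energy that depends on the
MM field (through an induced-dipole polarization term and direct
charge-charge electrostatics), gradients on both QM and MM atoms, and
molecular dipole/quadrupole labels.  Energies are built on the autodiff
graph, so label gradients are exact derivatives of the label energy by
construction.

Terms: harmonic bonds and angles, cosine torsions, intra-solute Coulomb
between fixed reference charges, direct Coulomb between solute reference
charges and MM charges, the induced-dipole energy -1/2 k_e alpha_i
|E_i|^2 in the MM field E_i, and Lennard-Jones coupling to the MM sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from . import autodiff as ad
from .dynamics import IntegratorConfig, dihedral_angle, integrate
from .system import CutoffSet, MMZone, QMZone, SimulationSystem
from .training import TrainingExample
from .units import KE, MASSES


@dataclass
class SurrogateSpec:
    """Parameters of the analytic label generator.

    Bonds: (i, j, k_b [kJ/mol/A^2], r0 [A]); angles: (i, j, k, k_a
    [kJ/mol/rad^2], theta0 [deg]); torsions: (i, j, k, l, k_t [kJ/mol],
    n, delta [deg]).  ``charges`` are fixed reference partial charges
    (e), ``polarizability`` per-atom scalars (A^3).
    """

    atomic_numbers: np.ndarray
    positions0: np.ndarray
    bonds: List[Tuple] = field(default_factory=list)
    angles: List[Tuple] = field(default_factory=list)
    torsions: List[Tuple] = field(default_factory=list)
    charges: np.ndarray = None
    polarizability: np.ndarray = None
    lj_epsilon: np.ndarray = None
    lj_sigma: np.ndarray = None
    total_charge: int = 0
    seed: int = 0

    def __post_init__(self):
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=int)
        n = len(self.atomic_numbers)
        self.positions0 = np.asarray(self.positions0, dtype=float).reshape(n, 3)
        if self.charges is None:
            self.charges = np.zeros(n)
        self.charges = np.asarray(self.charges, dtype=float)
        if self.polarizability is None:
            self.polarizability = np.ones(n)
        self.polarizability = np.asarray(self.polarizability, dtype=float)
        if self.lj_epsilon is None:
            self.lj_epsilon = np.full(n, 0.4)
        if self.lj_sigma is None:
            self.lj_sigma = np.full(n, 3.0)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        self.lj_sigma = np.asarray(self.lj_sigma, dtype=float)
        for terms, idx in ((self.bonds, 2), (self.angles, 3),
                           (self.torsions, 4)):
            for t in terms:
                if t[idx] < 0:
                    raise ValueError("force constants must be >= 0")
        if abs(self.charges.sum() - self.total_charge) > 1e-9:
            raise ValueError("charges must sum to the total charge")

    @property
    def masses(self) -> np.ndarray:
        return np.array([MASSES[z] for z in self.atomic_numbers])


def default_spec() -> SurrogateSpec:
    """A five-atom bent O=C-N(H2) solute with one soft torsion; energy
    fluctuations at 300-350 K span a few tens of kJ/mol."""
    return SurrogateSpec(
        atomic_numbers=[8, 6, 7, 1, 1],
        positions0=[[0.0, 1.25, 0.0], [0.0, 0.0, 0.0],
                    [1.20, -0.70, 0.0], [2.10, -0.25, 0.15],
                    [1.25, -1.70, -0.10]],
        bonds=[(0, 1, 2500.0, 1.25), (1, 2, 2000.0, 1.38),
               (2, 3, 3000.0, 1.01), (2, 4, 3000.0, 1.01)],
        angles=[(0, 1, 2, 300.0, 123.0), (1, 2, 3, 250.0, 119.0),
                (1, 2, 4, 250.0, 120.0), (3, 2, 4, 200.0, 118.0)],
        torsions=[(0, 1, 2, 3, 12.0, 2, 180.0)],
        charges=[-0.45, 0.45, -0.60, 0.30, 0.30],
        polarizability=[2.0, 1.5, 2.0, 0.5, 0.5],
        lj_epsilon=[0.65, 0.45, 0.70, 0.10, 0.10],
        lj_sigma=[3.0, 3.4, 3.3, 2.4, 2.4],
    )


# -- differentiable surrogate energy -----------------------------------

def _cross(a: ad.Var, b: ad.Var) -> ad.Var:
    """Cross product over the trailing axis (length 3)."""
    ax, ay, az = (ad.slice_last(a, k, k + 1) for k in range(3))
    bx, by, bz = (ad.slice_last(b, k, k + 1) for k in range(3))
    return ad.concat([ad.sub(ad.mul(ay, bz), ad.mul(az, by)),
                      ad.sub(ad.mul(az, bx), ad.mul(ax, bz)),
                      ad.sub(ad.mul(ax, by), ad.mul(ay, bx))], axis=-1)


def _norm(a: ad.Var) -> ad.Var:
    return ad.sqrt(ad.vsum(ad.mul(a, a), axis=-1))


def surrogate_energy_var(spec: SurrogateSpec, Rq: ad.Var,
                         Rm: Optional[ad.Var] = None, mm_charges=None):
    """Batched surrogate energy and multipole labels.

    Rq: Var (B, N, 3); Rm: Var (B, M, 3) or None.  Returns Vars
    (V (B,), dipole (B, 3), quadrupole (B, 3, 3)).
    """
    B, n = Rq.data.shape[:2]
    V = ad.Var(np.zeros(B))

    if spec.bonds:
        i, j, k, r0 = (np.array([b[c] for b in spec.bonds])
                       for c in range(4))
        d = ad.sub(ad.take(Rq, j.astype(int), 1), ad.take(Rq, i.astype(int), 1))
        r = _norm(d)
        V = ad.add(V, ad.vsum(ad.mul(ad.power(ad.sub(r, r0), 2.0), 0.5 * k),
                              axis=1))
    if spec.angles:
        i, j, k, ka, th0 = (np.array([a[c] for a in spec.angles])
                            for c in range(5))
        u = ad.sub(ad.take(Rq, i.astype(int), 1), ad.take(Rq, j.astype(int), 1))
        v = ad.sub(ad.take(Rq, k.astype(int), 1), ad.take(Rq, j.astype(int), 1))
        cosang = ad.div(ad.vsum(ad.mul(u, v), axis=-1),
                        ad.mul(_norm(u), _norm(v)))
        theta = ad.arccos(cosang)
        V = ad.add(V, ad.vsum(ad.mul(ad.power(
            ad.sub(theta, np.radians(th0)), 2.0), 0.5 * ka), axis=1))
    if spec.torsions:
        i, j, k, l, kt, nper, delta = (np.array([t[c] for t in spec.torsions])
                                       for c in range(7))
        b1 = ad.sub(ad.take(Rq, j.astype(int), 1), ad.take(Rq, i.astype(int), 1))
        b2 = ad.sub(ad.take(Rq, k.astype(int), 1), ad.take(Rq, j.astype(int), 1))
        b3 = ad.sub(ad.take(Rq, l.astype(int), 1), ad.take(Rq, k.astype(int), 1))
        n1 = _cross(b1, b2)
        n2 = _cross(b2, b3)
        y = ad.div(ad.vsum(ad.mul(_cross(n1, n2), b2), axis=-1), _norm(b2))
        x = ad.vsum(ad.mul(n1, n2), axis=-1)
        phi = ad.atan2(y, x)
        V = ad.add(V, ad.vsum(ad.mul(ad.add(ad.cos(ad.sub(
            ad.mul(phi, nper.astype(float)), np.radians(delta))), 1.0), kt),
            axis=1))

    # intra-solute Coulomb between fixed reference charges
    iu, ju = np.triu_indices(n, 1)
    if len(iu):
        d = ad.sub(ad.take(Rq, ju, 1), ad.take(Rq, iu, 1))
        qq = KE * spec.charges[iu] * spec.charges[ju]
        V = ad.add(V, ad.vsum(ad.div(ad.Var(np.broadcast_to(
            qq, (B, len(iu))).copy()), _norm(d)), axis=1))

    centroid = ad.mul(ad.vsum(Rq, axis=1, keepdims=True), 1.0 / n)
    dpos = ad.sub(Rq, centroid)
    q3 = spec.charges[None, :, None]
    dipole = ad.vsum(ad.mul(dpos, q3), axis=1)
    dd = ad.mul(ad.reshape(dpos, (B, n, 3, 1)), ad.reshape(dpos, (B, n, 1, 3)))
    quad = ad.vsum(ad.mul(dd, spec.charges[None, :, None, None]), axis=1)

    if Rm is not None and Rm.data.shape[1]:
        m = Rm.data.shape[1]
        Q = mm_charges if isinstance(mm_charges, ad.Var) else ad.Var(mm_charges)
        dqm = ad.sub(ad.reshape(Rm, (B, 1, m, 3)), ad.reshape(Rq, (B, n, 1, 3)))
        r = _norm(dqm)                              # (B, n, m)
        # direct Coulomb with the solute's reference charges
        qQ = ad.mul(ad.reshape(Q, (B, 1, m)), spec.charges[None, :, None])
        V = ad.add(V, ad.mul(ad.vsum(ad.div(qQ, r), axis=(1, 2)), KE))
        # MM field at each solute atom, E_i = sum_j Q_j (r_i - r_j) / r^3
        q_over_r3 = ad.div(ad.reshape(Q, (B, 1, m)), ad.power(r, 3.0))
        e_field = ad.vsum(ad.mul(ad.neg(dqm),
                                 ad.reshape(q_over_r3, (B, n, m, 1))), axis=2)
        esq = ad.vsum(ad.mul(e_field, e_field), axis=-1)     # (B, n)
        V = ad.add(V, ad.vsum(ad.mul(esq, -0.5 * KE * spec.polarizability),
                              axis=1))
        mu_ind = ad.mul(e_field, spec.polarizability[None, :, None])
        dipole = ad.add(dipole, ad.vsum(mu_ind, axis=1))
        mu_d = ad.add(
            ad.mul(ad.reshape(mu_ind, (B, n, 3, 1)),
                   ad.reshape(dpos, (B, n, 1, 3))),
            ad.mul(ad.reshape(dpos, (B, n, 3, 1)),
                   ad.reshape(mu_ind, (B, n, 1, 3))))
        quad = ad.add(quad, ad.vsum(mu_d, axis=1))
        # Lennard-Jones vs MM (parameters enter via the label systems too)
        eps = np.sqrt(spec.lj_epsilon[:, None] * _MM_LJ_EPS)
        sig = 0.5 * (spec.lj_sigma[:, None] + _MM_LJ_SIG)
        sr6 = ad.power(ad.div(ad.Var(np.broadcast_to(
            sig, (B, n, m)).copy()), r), 6.0)
        V = ad.add(V, ad.vsum(ad.mul(ad.sub(ad.mul(sr6, sr6), sr6),
                                     4.0 * np.broadcast_to(eps, (B, n, m))),
                              axis=(1, 2)))
    return V, dipole, quad


#: LJ parameters of the MM shell sites (kJ/mol, A)
_MM_LJ_EPS = 0.30
_MM_LJ_SIG = 3.2


def surrogate_label(sys: SimulationSystem, spec: SurrogateSpec) -> TrainingExample:
    """Label one system: energy, exact gradients, molecular multipoles."""
    if not np.array_equal(sys.qm.atomic_numbers, spec.atomic_numbers):
        raise ValueError("system topology does not match the surrogate spec")
    exs = label_batch([sys], spec)
    return exs[0]


def label_batch(systems, spec: SurrogateSpec) -> List[TrainingExample]:
    """Label many same-topology systems in one vectorized pass."""
    B = len(systems)
    Rq = ad.Var(np.stack([s.qm.positions for s in systems]))
    n_mm = systems[0].mm.n_atoms
    Rm = Qm = None
    if n_mm:
        Rm = ad.Var(np.stack([s.mm.positions for s in systems]))
        Qm = np.stack([s.mm.charges for s in systems])
    V, dip, quad = surrogate_energy_var(spec, Rq, Rm, Qm)
    wrt = [Rq] + ([Rm] if Rm is not None else [])
    grads = ad.grad(ad.vsum(V), wrt)
    g_qm = grads[0].data
    g_mm = grads[1].data if Rm is not None else np.zeros((B, 0, 3))
    return [TrainingExample(
        system=systems[b], V_ref=float(V.data[b]), grad_qm_ref=g_qm[b],
        grad_mm_ref=g_mm[b], dipole_ref=dip.data[b],
        quadrupole_ref=quad.data[b]) for b in range(B)]


# -- fast numpy twin for propagation -----------------------------------

def vacuum_energy_forces(spec: SurrogateSpec, x: np.ndarray):
    """Solute-only surrogate energy and forces (no MM shell), hand-coded
    in plain numpy for the sampling loops; agrees with the autodiff route
    (checked by the test suite)."""
    x = np.asarray(x, dtype=float)
    e = 0.0
    f = np.zeros_like(x)
    for i, j, k, r0 in spec.bonds:
        d = x[j] - x[i]
        r = np.linalg.norm(d)
        dev = r - r0
        e += 0.5 * k * dev * dev
        g = k * dev * d / r
        f[i] += g
        f[j] -= g
    for i, j, k, ka, th0 in spec.angles:
        u = x[i] - x[j]
        v = x[k] - x[j]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        cosang = np.clip(u @ v / (nu * nv), -1.0, 1.0)
        theta = np.arccos(cosang)
        sin_t = max(np.sqrt(1.0 - cosang * cosang), 1e-8)
        dev = theta - np.radians(th0)
        e += 0.5 * ka * dev * dev
        di = (cosang * u / nu - v / nv) / (nu * sin_t)
        dk = (cosang * v / nv - u / nu) / (nv * sin_t)
        f[i] -= ka * dev * di
        f[k] -= ka * dev * dk
        f[j] += ka * dev * (di + dk)
    for i, j, k, l, kt, nper, delta in spec.torsions:
        phi_deg, grad_deg = dihedral_angle(x, (i, j, k, l))
        phi = np.radians(phi_deg)
        grad = grad_deg * np.pi / 180.0
        e += kt * (1.0 + np.cos(nper * phi - np.radians(delta)))
        dE = -kt * nper * np.sin(nper * phi - np.radians(delta))
        f -= dE * grad
    n = len(x)
    iu, ju = np.triu_indices(n, 1)
    d = x[ju] - x[iu]
    r = np.linalg.norm(d, axis=1)
    qq = KE * spec.charges[iu] * spec.charges[ju]
    e += float(np.sum(qq / r))
    g = (qq / r ** 3)[:, None] * d
    np.add.at(f, ju, g)
    np.add.at(f, iu, -g)
    return e, f


# -- dataset generation -------------------------------------------------

def random_shell(rng, centroid, n_mm: int, radius=(4.5, 7.0),
                 charge: float = 0.4):
    """Random MM charge shell: balanced +/- charges on random directions."""
    u = rng.normal(size=(n_mm, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = rng.uniform(*radius, size=(n_mm, 1))
    pos = centroid + u * r
    q = charge * np.array([1.0, -1.0] * (n_mm // 2) + [0.0] * (n_mm % 2))
    rng.shuffle(q)
    return pos, q


def make_system(spec: SurrogateSpec, qm_positions, mm_positions,
                mm_charges) -> SimulationSystem:
    n_mm = len(mm_charges)
    return SimulationSystem(
        qm=QMZone(spec.atomic_numbers, qm_positions,
                  total_charge=spec.total_charge,
                  lj_epsilon=spec.lj_epsilon, lj_sigma=spec.lj_sigma),
        # the shell is one charge group: it is a field acting on the
        # solute, not a solvent with internal structure
        mm=MMZone(mm_positions, mm_charges,
                  np.full(n_mm, _MM_LJ_EPS), np.full(n_mm, _MM_LJ_SIG),
                  np.zeros(n_mm, dtype=int)),
        cutoffs=CutoffSet())


def generate_dataset(spec: SurrogateSpec, n_frames: int,
                     T_sample: float = 350.0, seed: int = 0,
                     n_mm: int = 16, shell=(4.5, 7.0),
                     steps_between: int = 40,
                     splits=(0.8, 0.1, 0.1)) -> dict:
    """Labeled snapshots from short SD runs on the surrogate.

    Solute configurations are drawn by stochastic dynamics at the
    (optionally elevated) sampling temperature; each frame receives a
    fresh random MM charge shell.  Deterministic for a fixed seed;
    returns dict with keys train/val/test (80/10/10 by default).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    cfg = IntegratorConfig(dt=0.5, temperature=T_sample, friction=20.0,
                           scheme="sd", seed=seed)
    masses = spec.masses
    x = spec.positions0.copy()
    v = None
    systems = []
    for _ in range(n_frames):
        x, v, _ = integrate(x, masses,
                            lambda y: vacuum_energy_forces(spec, y),
                            cfg, steps_between, rng=rng, velocities=v)
        pos, q = random_shell(rng, x.mean(axis=0), n_mm, shell)
        systems.append(make_system(spec, x.copy(), pos, q))
    examples = label_batch(systems, spec)
    order = rng.permutation(n_frames)
    n_train = int(round(splits[0] * n_frames))
    n_val = int(round(splits[1] * n_frames))
    idx = {"train": order[:n_train],
           "val": order[n_train:n_train + n_val],
           "test": order[n_train + n_val:]}
    return {k: [examples[i] for i in v] for k, v in idx.items()}


# -- toy dimer for end-to-end free-energy validation --------------------

@dataclass
class ToyDimer:
    """Two particles bound by a double-well radial potential.

    U(r) = wall (r^-12 core) - depth * gauss(r; r_min, w_min)
           + barrier * gauss(r; r_barrier, w_barrier)
    The standard (Jacobian-corrected) PMF of this pair equals U(r)
    exactly, so umbrella sampling + WHAM can be validated end to end
    against closed-form results.
    """

    depth: float = 15.0
    r_min: float = 3.0
    w_min: float = 0.6
    barrier: float = 2.0
    r_barrier: float = 4.6
    w_barrier: float = 0.5
    wall_scale: float = 5.0
    wall_sigma: float = 2.0
    mass: float = 14.0

    def u(self, r):
        r = np.asarray(r, dtype=float)
        return (self.wall_scale * (self.wall_sigma / r) ** 12
                - self.depth * np.exp(-(r - self.r_min) ** 2
                                      / (2 * self.w_min ** 2))
                + self.barrier * np.exp(-(r - self.r_barrier) ** 2
                                        / (2 * self.w_barrier ** 2)))

    def du(self, r):
        r = np.asarray(r, dtype=float)
        return (-12.0 * self.wall_scale * self.wall_sigma ** 12 / r ** 13
                + self.depth * (r - self.r_min) / self.w_min ** 2
                * np.exp(-(r - self.r_min) ** 2 / (2 * self.w_min ** 2))
                - self.barrier * (r - self.r_barrier) / self.w_barrier ** 2
                * np.exp(-(r - self.r_barrier) ** 2
                         / (2 * self.w_barrier ** 2)))

    @property
    def masses(self) -> np.ndarray:
        return np.array([self.mass, self.mass])

    def potential(self, x):
        """(energy, forces) for positions x of shape (2, 3)."""
        d = x[1] - x[0]
        r = np.linalg.norm(d)
        g = self.du(r) * d / r
        return float(self.u(r)), np.array([g, -g])

    def start_positions(self, r: float) -> np.ndarray:
        return np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])

    def analytic_pmf(self, r_grid, temperature: float = 298.0):
        """Exact standard PMF on a grid (a PMFResult, min-shifted)."""
        from .free_energy import PMFResult

        g = self.u(r_grid)
        return PMFResult(np.asarray(r_grid, dtype=float), g - g.min(),
                         temperature=temperature)

    def radial_free_energy(self, r_grid, temperature: float = 298.0):
        """Raw radial PMF including the 4 pi r^2 entropic term (what a
        histogram of sampled distances measures)."""
        from .units import KB

        r = np.asarray(r_grid, dtype=float)
        g = self.u(r) - KB * temperature * np.log(4.0 * np.pi * r ** 2)
        return g - g.min()

    def analytic_delta_g(self, barrier: float = None, r_max: float = 20.0,
                         r_lo: float = 2.0, temperature: float = 298.0,
                         n_grid: int = 4000) -> float:
        """Closed-form dissociation free energy by dense quadrature of the
        exact radial density over the same support the sampling uses."""
        from .free_energy import delta_g

        barrier = barrier if barrier is not None else self.r_barrier
        grid = np.linspace(r_lo, r_max, n_grid)
        return delta_g(self.analytic_pmf(grid, temperature), barrier, r_max,
                       temperature)


def toy_dimer(**kwargs) -> ToyDimer:
    return ToyDimer(**kwargs)
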