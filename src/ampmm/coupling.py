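"""Physics-motivated energy terms and their assembly into total energies
and forces.

Terms: switched intra-QM Coulomb between predicted monopoles, QM-MM
multipole electrostatics (charge-charge, charge-dipole,
charge-quadrupole), classical Lennard-Jones coupling, and the MM internal
force field.  Forces are exact negative gradients of the assembled energy
obtained by differentiating the full computational graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .model import AMPModel, _edge_geometry, _envelope_var
from .neighbors import build_qm_graph, gather_mm_pairs
from .system import SimulationSystem
from .units import KE

DOUBLE_FACTORIAL = {0: 1.0, 1: 1.0, 2: 3.0}  # (2l-1)!! with (-1)!! = 1


@dataclass
class EnergyBreakdown:
    """Per-term energies, kJ/mol; V_total is the sum of the parts."""

    V_AMP: float
    V_ES_QM: float
    V_ES_QMMM: float
    V_LJ_QMMM: float
    V_MM: float

    @property
    def V_total(self) -> float:
        return (self.V_AMP + self.V_ES_QM + self.V_ES_QMMM
                + self.V_LJ_QMMM + self.V_MM)


@dataclass
class Forces:
    """Forces (negative energy gradients), kJ/mol/A."""

    f_qm: np.ndarray
    f_mm: np.ndarray


def f_switch(r, r_c: float):
    """Electrostatic switching function: 1 at r=0, 0 at and beyond r_c,
    monotone, C^2 at both ends (unique quintic with those endpoints)."""
    if r_c <= 0:
        raise ValueError("switching cutoff must be positive")
    x = np.clip(np.asarray(r, dtype=float) / r_c, 0.0, 1.0)
    return 1.0 - x ** 3 * (10.0 - 15.0 * x + 6.0 * x * x)


def radial_T(l: int, r):
    """Multipole radial function T^(l)(r) = (2l-1)!! / r^(l+1)."""
    if l not in DOUBLE_FACTORIAL:
        raise ValueError(f"multipole order {l} not supported")
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radial_T requires r > 0")
    return DOUBLE_FACTORIAL[l] / r ** (l + 1)


def switched_coulomb_qm(q, positions, r_graph: float = 5.0, box=None) -> float:
    """V_ES,QM = k_e sum_{i<j} q_i q_j (1 - f_switch(r_ij)) / r_ij.

    Smoothly suppressed inside the graph cutoff (where the learned energy
    operates) and exactly Coulombic beyond it.
    """
    q = np.asarray(q, dtype=float)
    pos = np.asarray(positions, dtype=float)
    n = len(q)
    if n < 2:
        return 0.0
    iu, ju = np.triu_indices(n, 1)
    d = pos[ju] - pos[iu]
    if box is not None:
        d -= np.asarray(box) * np.round(d / np.asarray(box))
    r = np.linalg.norm(d, axis=1)
    return float(KE * np.sum(q[iu] * q[ju] * (1.0 - f_switch(r, r_graph)) / r))


def lj_qmmm(sys: SimulationSystem) -> float:
    """Lennard-Jones QM-MM coupling with Lorentz-Berthelot combination,
    summed over pairs within r_es (group-based gathering)."""
    pairs = gather_mm_pairs(sys)
    eps_i, sig_i = _qm_lj(sys)
    eps = np.sqrt(eps_i[pairs.es_qm] * sys.mm.lj_epsilon[pairs.es_mm])
    sig = 0.5 * (sig_i[pairs.es_qm] + sys.mm.lj_sigma[pairs.es_mm])
    sr6 = (sig / pairs.es_r) ** 6
    return float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)))


def _qm_lj(sys: SimulationSystem):
    n = sys.qm.n_atoms
    eps = sys.qm.lj_epsilon if sys.qm.lj_epsilon is not None else np.zeros(n)
    sig = sys.qm.lj_sigma if sys.qm.lj_sigma is not None else np.ones(n)
    return eps, sig


def es_qmmm(q, es_mu, es_theta, qm_positions, mm_positions, mm_charges,
            pairs=None, box=None) -> float:
    """Multipole-monopole electrostatics between QM atoms and MM charges.

    V = k_e sum_ij [ q_i Q_j / r + Q_j (mu_i . u_ij) / r^2
                     + 3 Q_j (u_ij^T Theta_i u_ij) / r^3 ]
    with u_ij pointing from QM atom i to MM site j; the monopole term is
    the plain Coulomb energy.
    """
    qp = np.asarray(qm_positions, dtype=float)
    mp = np.asarray(mm_positions, dtype=float)
    if pairs is None:
        qi, mj = [a.ravel() for a in np.meshgrid(
            np.arange(len(qp)), np.arange(len(mp)), indexing="ij")]
    else:
        qi, mj = pairs
    if len(qi) == 0:
        return 0.0
    d = mp[mj] - qp[qi]
    if box is not None:
        d -= np.asarray(box) * np.round(d / np.asarray(box))
    r = np.linalg.norm(d, axis=1)
    u = d / r[:, None]
    q = np.asarray(q, dtype=float)[qi]
    Q = np.asarray(mm_charges, dtype=float)[mj]
    mu = np.asarray(es_mu, dtype=float)[qi]
    th = np.asarray(es_theta, dtype=float)[qi]
    t0 = q * Q * radial_T(0, r)
    t1 = Q * np.einsum("pi,pi->p", mu, u) * radial_T(1, r)
    t2 = Q * np.einsum("pi,pij,pj->p", u, th, u) * radial_T(2, r)
    return float(KE * np.sum(t0 + t1 + t2))


# -- differentiable versions (shared by training and inference) --------

def switched_coulomb_var(q: ad.Var, R: ad.Var, r_graph: float,
                         box=None) -> ad.Var:
    """Batched Var version of :func:`switched_coulomb_qm`; returns (B,)."""
    B, N = q.data.shape
    if N < 2:
        return ad.Var(np.zeros(B, dtype=q.data.dtype))
    iu, ju = np.triu_indices(N, 1)
    Ri = ad.take(R, iu, 1)
    Rj = ad.take(R, ju, 1)
    _, r, _ = _edge_geometry(Ri, Rj, box)
    qq = ad.mul(ad.take(q, iu, 1), ad.take(q, ju, 1))
    P = len(iu)
    one_m_f = ad.sub(1.0, ad.reshape(
        _envelope_var(ad.reshape(r, (B, P, 1)), r_graph), (B, P)))
    return ad.mul(ad.vsum(ad.div(ad.mul(qq, one_m_f), r), axis=1), KE)


def es_qmmm_var(q, es_mu, es_theta, R, Rm, Qm, pairs, box=None) -> ad.Var:
    """Batched Var version of :func:`es_qmmm`; returns (B,)."""
    eq, em = pairs
    B = q.data.shape[0]
    if len(eq) == 0:
        return ad.Var(np.zeros(B, dtype=q.data.dtype))
    P = len(eq)
    Ri = ad.take(R, eq, 1)
    Rj = ad.take(Rm, em, 1)
    _, r, u = _edge_geometry(Ri, Rj, box)
    qi = ad.take(q, eq, 1)
    Qj = ad.take(Qm, em, 1)
    mui = ad.take(es_mu, eq, 1)                       # (B, P, 3)
    thi = ad.take(es_theta, eq, 1)                    # (B, P, 3, 3)
    mu_u = ad.vsum(ad.mul(mui, u), axis=-1)
    uthu = ad.vsum(ad.mul(ad.mul(thi, ad.reshape(u, (B, P, 3, 1))),
                          ad.reshape(u, (B, P, 1, 3))), axis=(-1, -2))
    t0 = ad.div(ad.mul(qi, Qj), r)
    t1 = ad.div(ad.mul(Qj, mu_u), ad.mul(r, r))
    t2 = ad.mul(ad.div(ad.mul(Qj, uthu), ad.mul(ad.mul(r, r), r)), 3.0)
    return ad.mul(ad.vsum(ad.add(ad.add(t0, t1), t2), axis=1), KE)


def lj_qmmm_var(R, Rm, pairs, eps_ij, sig_ij, box=None) -> ad.Var:
    """LJ over explicit QM-MM pairs with precombined parameters; (B,)."""
    eq, em = pairs
    B = R.data.shape[0]
    if len(eq) == 0 or not np.any(eps_ij):
        return ad.Var(np.zeros(B, dtype=R.data.dtype))
    Ri = ad.take(R, eq, 1)
    Rj = ad.take(Rm, em, 1)
    _, r, _ = _edge_geometry(Ri, Rj, box)
    dtype = R.data.dtype
    sr6 = ad.power(ad.div(ad.Var(np.asarray(sig_ij, dtype=dtype)), r), 6.0)
    v = ad.mul(ad.mul(ad.sub(ad.mul(sr6, sr6), sr6),
                      ad.Var(np.asarray(eps_ij, dtype=dtype))), 4.0)
    return ad.vsum(v, axis=1)


def model_energy_var(model: AMPModel, p: dict, Z, R: ad.Var, edges,
                     total_charge=0.0, mm=None, box=None, qm_lj=None):
    """Assemble the differentiable model-side energy terms.

    Returns (AMPOutput, dict of (B,) Vars with keys V_AMP, V_ES_QM,
    V_ES_QMMM, V_LJ_QMMM).  V_AMP absorbs the MM-induced polarization.
    """
    out = model.forward(p, Z, R, edges, total_charge, mm=mm, box=box)
    terms = {
        "V_AMP": out.V_amp,
        "V_ES_QM": switched_coulomb_var(out.q, R, model.config.r_graph, box),
    }
    B = R.data.shape[0]
    if mm is not None and len(mm["es_pairs"][0]):
        terms["V_ES_QMMM"] = es_qmmm_var(
            out.q, out.es_mu, out.es_theta, R, mm["R"], mm["q"],
            mm["es_pairs"], box)
        if qm_lj is not None:
            eq, em = mm["es_pairs"]
            eps_i, sig_i = qm_lj
            eps_ij = np.sqrt(eps_i[eq] * mm["lj_eps"][em])
            sig_ij = 0.5 * (sig_i[eq] + mm["lj_sig"][em])
            terms["V_LJ_QMMM"] = lj_qmmm_var(R, mm["R"], mm["es_pairs"],
                                             eps_ij, sig_ij, box)
        else:
            terms["V_LJ_QMMM"] = ad.Var(np.zeros(B, dtype=R.data.dtype))
    else:
        terms["V_ES_QMMM"] = ad.Var(np.zeros(B, dtype=R.data.dtype))
        terms["V_LJ_QMMM"] = ad.Var(np.zeros(B, dtype=R.data.dtype))
    return out, terms


def polarization_update(model: AMPModel, p: dict, M, h, R, mm, box=None):
    """MM-induced multipoles added onto the QM multipole channels (thin
    wrapper over the model's internal pathway)."""
    return model._induced(p, M, h, R, mm, box)


def mm_inputs(sys: SimulationSystem, pairs=None):
    """Build the mm dict consumed by the model/energy routines (B=1)."""
    if sys.mm.n_atoms == 0:
        return None
    if pairs is None:
        pairs = gather_mm_pairs(sys)
    return {
        "R": ad.Var(sys.mm.positions[None]),
        "q": ad.Var(sys.mm.charges[None]),
        "pol_pairs": (pairs.pol_qm, pairs.pol_mm),
        "es_pairs": (pairs.es_qm, pairs.es_mm),
        "lj_eps": sys.mm.lj_epsilon,
        "lj_sig": sys.mm.lj_sigma,
    }


def total_energy_forces(sys: SimulationSystem, model: AMPModel):
    """Total energy breakdown and exact-gradient forces for one system."""
    graph = build_qm_graph(sys)
    mm = mm_inputs(sys)
    box = sys.box_lengths
    R = ad.Var(sys.qm.positions[None])
    p = model.param_vars()
    out, terms = model_energy_var(
        model, p, sys.qm.atomic_numbers, R, (graph.src, graph.dst),
        total_charge=sys.qm.total_charge, mm=mm, box=box, qm_lj=_qm_lj(sys))
    v_model = ad.vsum(ad.add(ad.add(terms["V_AMP"], terms["V_ES_QM"]),
                             ad.add(terms["V_ES_QMMM"], terms["V_LJ_QMMM"])))
    wrt = [R] + ([mm["R"]] if mm is not None else [])
    grads = ad.grad(v_model, wrt)
    f_qm = -grads[0].data[0]
    f_mm = -grads[1].data[0] if mm is not None else np.zeros((0, 3))

    if sys.mm.n_atoms:
        from .dynamics import mm_forcefield
        v_mm, f_mm_internal = mm_forcefield(sys.mm, sys.box_lengths)
        f_mm = f_mm + f_mm_internal
    else:
        v_mm = 0.0

    breakdown = EnergyBreakdown(
        V_AMP=float(terms["V_AMP"].data[0]),
        V_ES_QM=float(terms["V_ES_QM"].data[0]),
        V_ES_QMMM=float(terms["V_ES_QMMM"].data[0]),
        V_LJ_QMMM=float(terms["V_LJ_QMMM"].data[0]),
        V_MM=float(v_mm),
    )
    return breakdown, Forces(f_qm=f_qm, f_mm=f_mm)
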