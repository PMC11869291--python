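"""Anisotropic message-passing network with per-atom multipole channels.

Each atom carries a hidden feature vector and a set of multipole channels
(scalar, vector, rank-2 tensor per channel) expanded from edge directions.
Rotation-invariant multipole-interaction coefficients g_ij couple the
orientation of neighbouring atoms' multipoles into the (scalar) message
passing, which keeps predicted energies invariant and multipoles
equivariant under rigid motions by construction.

Readout heads produce per-atom energies, conservation-projected partial
charges, a separate set of electrostatic multipoles (used for the QM-MM
multipole electrostatics), and a per-atom polarizability coupling that
scales MM-induced multipoles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from . import autodiff as ad
from .nn import MLP

_EYE3 = np.eye(3)


@dataclass
class ModelConfig:
    """Hyperparameters; defaults are the small-model configuration."""

    message_passing_steps: int = 2
    r_graph: float = 5.0
    r_pol: float = 9.0
    r_es: float = 14.0
    node_size: int = 128
    edge_size: int = 32
    n_bessel_qm: int = 8
    n_bessel_qmmm: int = 8
    n_multipole_channels: int = 32
    max_multipole_order: int = 2
    elements: tuple = (1, 6, 7, 8)
    seed: int = 0

    def __post_init__(self):
        self.elements = tuple(int(z) for z in self.elements)


@dataclass
class NodeState:
    """Per-atom state after (part of) a forward pass (numpy views)."""

    h: np.ndarray
    M0: np.ndarray
    M1: np.ndarray
    M2: np.ndarray
    q: Optional[np.ndarray] = None
    alpha: Optional[np.ndarray] = None
    es_charge: Optional[np.ndarray] = None
    es_dipole: Optional[np.ndarray] = None
    es_quadrupole: Optional[np.ndarray] = None


class AMPOutput:
    """Var container produced by :meth:`AMPModel.forward`."""

    def __init__(self, **kw):
        self.__dict__.update(kw)

    def state(self) -> NodeState:
        return NodeState(
            h=self.h.data, M0=self.M0.data, M1=self.M1.data, M2=self.M2.data,
            q=self.q.data, alpha=self.alpha.data, es_charge=self.q.data,
            es_dipole=self.es_mu.data, es_quadrupole=self.es_theta.data)


# -- reference (numpy) formulations used by tests and docs -------------

def local_basis(u: np.ndarray, k: int):
    """Rank-k basis tensor from a unit vector: 1, u, or u (x) u."""
    u = np.asarray(u, dtype=float)
    if k == 0:
        return 1.0
    if k == 1:
        return u
    if k == 2:
        return np.outer(u, u)
    raise ValueError(f"multipole order {k} > 2 not supported")


def interaction_triples(k: int):
    """All (d_i, d_j, d_c) with nonnegative parts summing to k."""
    return [(di, dj, k - di - dj)
            for di in range(k + 1) for dj in range(k + 1 - di)]


def _np_factor(M, d_u: int, d_c: int, u: np.ndarray):
    """One bracket of an interaction coefficient: the order-(d_u + d_c)
    multipole with d_u indices contracted onto the edge direction."""
    order = d_u + d_c
    m = M[order]
    if order == 0:
        return m
    if order == 1:
        return m @ u if d_u == 1 else m
    if d_u == 2:
        return np.einsum("cij,i,j->c", m, u, u)
    if d_u == 1:
        return np.einsum("cij,j->ci", m, u)
    return m


def multipole_interaction_coeffs(M_i, M_j, u, k: int) -> np.ndarray:
    """Rotation-invariant scalars coupling two atoms' multipoles.

    ``M_i``/``M_j`` are triples (M0: (C,), M1: (C,3), M2: (C,3,3)); returns
    an (n_triples, C) array, one row per (d_i, d_j, d_c) composition of k.
    Combinatorial prefactors are omitted; any fixed positive prefactor is
    absorbed by downstream network weights.
    """
    u = np.asarray(u, dtype=float)
    if k > 2:
        raise ValueError(f"multipole order {k} > 2 not supported")
    rows = []
    for di, dj, dc in interaction_triples(k):
        fi = _np_factor(M_i, di, dc, u)
        fj = _np_factor(M_j, dj, dc, u)
        prod = fi * fj
        if dc:
            prod = prod.reshape(prod.shape[0], -1).sum(axis=1)
        rows.append(prod)
    return np.stack(rows)


# -- differentiable model ----------------------------------------------

def _bessel_var(r: ad.Var, n_feats: int, r_c: float) -> ad.Var:
    """Differentiable twin of :func:`ampmm.neighbors.bessel_features`;
    input r has shape (...,), output (..., n_feats)."""
    shape = r.data.shape + (1,)
    r1 = ad.reshape(r, shape)
    n = np.arange(1, n_feats + 1, dtype=r.data.dtype)
    base = ad.mul(ad.div(ad.sin(ad.mul(r1, n * (np.pi / r_c))), r1),
                  float(np.sqrt(2.0 / r_c)))
    return ad.mul(base, _envelope_var(r1, r_c))


def _envelope_var(r: ad.Var, r_c: float) -> ad.Var:
    x = ad.mul(r, 1.0 / r_c)
    poly = 1.0 + ad.mul(ad.power(x, 3.0),
                        ad.add(ad.mul(x, ad.add(ad.mul(x, -6.0), 15.0)), -10.0))
    return ad.where(r.data < r_c, poly,
                    ad.Var(np.zeros(1, dtype=r.data.dtype)))


def _edge_geometry(R_a: ad.Var, R_b: ad.Var, box=None):
    """d, r, u for precomputed endpoint Vars of shape (B, E, 3)."""
    d = ad.sub(R_b, R_a)
    if box is not None:
        shift = np.asarray(box) * np.round(d.data / np.asarray(box))
        if np.any(shift):
            d = ad.sub(d, ad.Var(shift.astype(d.data.dtype)))
    r = ad.sqrt(ad.vsum(ad.mul(d, d), axis=-1))
    u = ad.div(d, ad.reshape(r, r.data.shape + (1,)))
    return d, r, u


class AMPModel:
    """The message-passing potential for the QM zone.

    Parameters are a flat dict of float64 arrays; ``forward`` runs on a
    batch of conformers sharing one topology (edge index lists), which
    covers both single-system inference (B=1, edges from the neighbor
    search) and batched training (edges = all pairs; the smooth envelope
    makes both routes exactly equivalent).
    """

    def __init__(self, config: ModelConfig = None, params: dict = None):
        self.config = config or ModelConfig()
        cfg = self.config
        if cfg.max_multipole_order != 2:
            raise ValueError("only multipoles up to quadrupole are supported")
        self.z_index = {z: i for i, z in enumerate(cfg.elements)}
        ne, node, edge = len(cfg.elements), cfg.node_size, cfg.edge_size
        C = cfg.n_multipole_channels
        n_g = 10 * C                       # 1 + 3 + 6 triples per channel
        e_in = 2 * node + 2 * ne + cfg.n_bessel_qm + n_g

        self.params: dict = {}
        rng = np.random.default_rng(cfg.seed)
        self.params["embed.W"] = rng.normal(0.0, np.sqrt(2.0 / ne), (ne, node))
        n_self = 4 * C                     # per-node multipole invariants
        self.phi_e, self.phi_h, self.phi_m = [], [], []
        for l in range(cfg.message_passing_steps):
            self.phi_e.append(MLP(self.params, f"e{l}", e_in,
                                  (node, node), edge, rng))
            self.phi_h.append(MLP(self.params, f"h{l}", node + edge + n_self,
                                  (node, node), node, rng))
            self.phi_m.append(MLP(self.params, f"m{l}", e_in,
                                  (edge, edge), 3 * C, rng))
        self.phi_b = MLP(self.params, "pol_b", cfg.n_bessel_qmmm + 3 * C,
                         (edge, edge), 3 * C, rng)
        self.phi_alpha = MLP(self.params, "alpha", node, (edge, edge), 1, rng)
        self.phi_V = MLP(self.params, "V", node, (node, node), 1, rng)
        self.phi_q = MLP(self.params, "q", node, (edge, edge), 1, rng)
        self.phi_es = MLP(self.params, "es", node, (edge, edge), 2 * C, rng)
        if params is not None:
            for k, v in params.items():
                if k not in self.params:
                    raise KeyError(f"unexpected parameter {k}")
                self.params[k] = np.asarray(v, dtype=float)

    # -- plumbing ------------------------------------------------------

    def param_vars(self, dtype=np.float64) -> dict:
        return {k: ad.Var(np.asarray(v, dtype=dtype))
                for k, v in self.params.items()}

    def onehot(self, Z) -> np.ndarray:
        Z = np.asarray(Z, dtype=int)
        out = np.zeros((len(Z), len(self.config.elements)))
        for i, z in enumerate(Z):
            if z not in self.z_index:
                raise ValueError(
                    f"element Z={z} outside supported set {self.config.elements}")
            out[i, self.z_index[z]] = 1.0
        return out

    def init_embeddings(self, Z) -> NodeState:
        """Initial per-atom state: learned linear map of the one-hot
        element encoding; multipoles start at zero."""
        h0 = self.onehot(Z) @ self.params["embed.W"]
        n, C = len(h0), self.config.n_multipole_channels
        return NodeState(h=h0, M0=np.zeros((n, C)), M1=np.zeros((n, C, 3)),
                         M2=np.zeros((n, C, 3, 3)))

    # -- forward pieces -------------------------------------------------

    def _g_coeffs(self, M, src, dst, u: ad.Var) -> ad.Var:
        """Interaction coefficients per edge, concatenated over orders and
        channels -> (B, E, 10 C)."""

        def gather(m):
            return ad.take(m, src, 1), ad.take(m, dst, 1)

        M0i, M0j = gather(M[0])
        M1i, M1j = gather(M[1])
        M2i, M2j = gather(M[2])
        # contracted bracket factors (edge-direction contractions)
        A1i = ad.contract("beci,bei->bec", M1i, u)
        A1j = ad.contract("beci,bei->bec", M1j, u)
        B2i = ad.contract("becij,bej->beci", M2i, u)
        B2j = ad.contract("becij,bej->beci", M2j, u)
        A2i = ad.contract("beci,bei->bec", B2i, u)
        A2j = ad.contract("beci,bei->bec", B2j, u)

        def factor(m0, m1, a1, b2, a2, d_u, d_c):
            order = d_u + d_c
            if order == 0:
                return m0
            if order == 1:
                return a1 if d_u == 1 else m1
            if d_u == 2:
                return a2
            if d_u == 1:
                return b2
            return None  # full rank-2 tensor handled below

        parts = []
        fac_i = (M0i, M1i, A1i, B2i, A2i)
        fac_j = (M0j, M1j, A1j, B2j, A2j)
        for k in range(3):
            for di, dj, dc in interaction_triples(k):
                if dc == 2:
                    parts.append(ad.contract("becij,becij->bec", M2i, M2j))
                    continue
                fi = factor(*fac_i, di, dc)
                fj = factor(*fac_j, dj, dc)
                if dc == 1:
                    parts.append(ad.contract("beci,beci->bec", fi, fj))
                else:
                    parts.append(ad.mul(fi, fj))
        return ad.concat(parts, axis=-1)

    @staticmethod
    def _node_invariants(M) -> ad.Var:
        """Rotation-invariant quadratics of each node's own multipoles:
        M0, |M1|^2, M2:M2 and tr(M2) per channel -> (B, N, 4C).

        Edge coefficients only ever couple *different* nodes' multipoles,
        so without these a node's own induced moments (e.g. the square of
        an MM-induced dipole, which carries the polarization energy)
        could not reach the scalar energy head."""
        m1sq = ad.contract("bnci,bnci->bnc", M[1], M[1])
        m2sq = ad.contract("bncij,bncij->bnc", M[2], M[2])
        tr = ad.vsum(ad.mul(M[2], _EYE3.astype(M[2].data.dtype)),
                     axis=(-1, -2))
        return ad.concat([M[0], m1sq, m2sq, tr], axis=-1)

    def _expand(self, c: ad.Var, src, u: ad.Var, n_atoms: int):
        """Scatter per-edge coefficients (B,E,3C) into per-node multipole
        channels using the local basis (1, u, u (x) u)."""
        C = self.config.n_multipole_channels
        c0 = ad.slice_last(c, 0, C)
        c1 = ad.slice_last(c, C, 2 * C)
        c2 = ad.slice_last(c, 2 * C, 3 * C)
        w1 = ad.contract("bec,bei->beci", c1, u)
        w2 = ad.contract("beci,bej->becij",
                         ad.contract("bec,bei->beci", c2, u), u)
        M0 = ad.untake(c0, src, 1, n_atoms)
        M1 = ad.untake(w1, src, 1, n_atoms)
        M2 = ad.untake(w2, src, 1, n_atoms)
        return M0, M1, M2

    def _induced(self, p, M, h, R, mm, box):
        """MM-induced multipoles: alpha_i * sum_j q_j * b_ij * basis(u, k),
        b_ij a network of QM/MM Bessel features and the coefficients
        between QM multipoles and the MM monopole."""
        cfg = self.config
        C = cfg.n_multipole_channels
        pq, pm = mm["pol_pairs"]
        if len(pq) == 0:
            return M
        B = R.data.shape[0]
        n_atoms = R.data.shape[1]
        P = len(pq)
        Rq = ad.take(R, pq, 1)
        Rm = ad.take(mm["R"], pm, 1)
        _, r, u = _edge_geometry(Rq, Rm, box)
        env = ad.reshape(_envelope_var(ad.reshape(r, (B, P, 1)), cfg.r_pol),
                         (B, P, 1))
        bes = _bessel_var(r, cfg.n_bessel_qmmm, cfg.r_pol)
        M0i = ad.take(M[0], pq, 1)
        M1i = ad.take(M[1], pq, 1)
        M2i = ad.take(M[2], pq, 1)
        a1 = ad.contract("beci,bei->bec", M1i, u)
        a2 = ad.contract("beci,bei->bec",
                         ad.contract("becij,bej->beci", M2i, u), u)
        g_pol = ad.concat([M0i, a1, a2], axis=-1)
        b = ad.mul(self.phi_b(ad.concat([bes, g_pol], axis=-1), p), env)
        alpha = self.phi_alpha(h, p)                      # (B, N, 1)
        ai = ad.take(alpha, pq, 1)                        # (B, P, 1)
        qj = ad.reshape(ad.take(mm["q"], pm, 1), (B, P, 1))
        w = ad.mul(ad.mul(ai, qj), b)
        w0 = ad.slice_last(w, 0, C)
        w1 = ad.slice_last(w, C, 2 * C)
        w2 = ad.slice_last(w, 2 * C, 3 * C)
        dM0 = ad.untake(w0, pq, 1, n_atoms)
        dM1 = ad.untake(ad.contract("bec,bei->beci", w1, u), pq, 1, n_atoms)
        dM2 = ad.untake(ad.contract(
            "beci,bej->becij", ad.contract("bec,bei->beci", w2, u), u),
            pq, 1, n_atoms)
        return (ad.add(M[0], dM0), ad.add(M[1], dM1), ad.add(M[2], dM2))

    # -- full forward ----------------------------------------------------

    def forward(self, p: dict, Z, R: ad.Var, edges, total_charge: float = 0.0,
                mm: Optional[dict] = None, box=None) -> AMPOutput:
        """Run message passing and readout.

        Parameters
        ----------
        p : dict of name -> Var (``param_vars()``)
        Z : (N,) atomic numbers
        R : Var (B, N, 3), QM positions
        edges : (src, dst) int arrays, directed QM edges
        mm : optional dict with keys ``R`` (Var (B, M, 3)), ``q`` (Var
            (B, M)), ``pol_pairs`` ((pq, pm) index arrays within r_pol)
        """
        cfg = self.config
        steps = cfg.message_passing_steps
        B, N = R.data.shape[0], R.data.shape[1]
        src, dst = edges
        E = len(src)
        C = cfg.n_multipole_channels

        dtype = R.data.dtype
        onehot = self.onehot(Z).astype(dtype)
        h = ad.broadcast_to(ad.dot(ad.Var(onehot), p["embed.W"]),
                            (B, N, cfg.node_size))
        M = (ad.Var(np.zeros((B, N, C), dtype=dtype)),
             ad.Var(np.zeros((B, N, C, 3), dtype=dtype)),
             ad.Var(np.zeros((B, N, C, 3, 3), dtype=dtype)))

        Ri = ad.take(R, src, 1)
        Rj = ad.take(R, dst, 1)
        _, r, u = _edge_geometry(Ri, Rj, box)
        env = ad.reshape(_envelope_var(ad.reshape(r, (B, E, 1)), cfg.r_graph),
                         (B, E, 1))
        bes = _bessel_var(r, cfg.n_bessel_qm, cfg.r_graph)
        oh_i = ad.Var(np.broadcast_to(onehot[src][None], (B, E, onehot.shape[1])))
        oh_j = ad.Var(np.broadcast_to(onehot[dst][None], (B, E, onehot.shape[1])))

        if mm is not None and steps == 1:
            M = self._induced(p, M, h, R, mm, box)
        for l in range(steps):
            g = self._g_coeffs(M, src, dst, u)
            hi = ad.take(h, src, 1)
            hj = ad.take(h, dst, 1)
            ein = ad.concat([hi, hj, oh_i, oh_j, bes, g], axis=-1)
            msg = ad.mul(self.phi_e[l](ein, p), env)
            agg = ad.untake(msg, src, 1, N)
            h = self.phi_h[l](ad.concat(
                [h, agg, self._node_invariants(M)], axis=-1), p)
            c = ad.mul(self.phi_m[l](ein, p), env)
            M = self._expand(c, src, u, N)
            if mm is not None and l == steps - 2:
                M = self._induced(p, M, h, R, mm, box)

        return self._readout(p, h, M, total_charge, B, N, C)

    def _readout(self, p, h, M, total_charge, B, N, C) -> AMPOutput:
        V_atoms = self.phi_V(h, p)                       # (B, N, 1)
        V_amp = ad.reshape(ad.vsum(V_atoms, axis=(1, 2)), (B,))
        q_raw = ad.reshape(self.phi_q(h, p), (B, N))
        excess = ad.mul(ad.sub(ad.vsum(q_raw, axis=1, keepdims=True),
                               float(total_charge)), 1.0 / N)
        q = ad.sub(q_raw, excess)
        gates = self.phi_es(h, p)                        # (B, N, 2C)
        g1 = ad.slice_last(gates, 0, C)
        g2 = ad.slice_last(gates, C, 2 * C)
        es_mu = ad.contract("bnc,bnci->bni", g1, M[1])   # (B, N, 3)
        th = ad.contract("bnc,bncij->bnij", g2, M[2])    # (B, N, 3, 3)
        eye = _EYE3.astype(th.data.dtype)
        tr = ad.vsum(ad.mul(th, eye), axis=(-1, -2), keepdims=True)
        es_theta = ad.sub(th, ad.mul(tr, eye / 3.0))     # detraced
        alpha = ad.reshape(self.phi_alpha(h, p), (B, N))
        return AMPOutput(V_amp=V_amp, V_atoms=V_atoms, h=h, q=q,
                         es_mu=es_mu, es_theta=es_theta, alpha=alpha,
                         M0=M[0], M1=M[1], M2=M[2])

    # -- checkpointing ---------------------------------------------------

    def save(self, path):
        cfg = asdict(self.config)
        cfg["elements"] = list(cfg["elements"])
        meta = json.dumps({"format_version": 1, "config": cfg})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "AMPModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format_version") != 1:
                raise ValueError("unsupported checkpoint format version")
            cfg = meta["config"]
            cfg["elements"] = tuple(cfg["elements"])
            params = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(ModelConfig(**cfg), params=params)
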