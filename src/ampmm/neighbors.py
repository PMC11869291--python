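"""Neighbor lists for the QM graph and QM-MM pair lists, plus radial
(zeroth-order spherical Bessel) edge features with a smooth C^2 envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system import SimulationSystem


class DegenerateGeometryError(ValueError):
    """Two atoms at (numerically) identical positions."""


@dataclass
class QMGraph:
    """Directed edge list over QM atoms within the graph cutoff."""

    src: np.ndarray   # i indices
    dst: np.ndarray   # j indices
    r: np.ndarray     # distances (A)
    u: np.ndarray     # unit vectors (R_j - R_i) / r

    @property
    def n_edges(self) -> int:
        return len(self.src)


@dataclass
class QMMMPairs:
    """QM-MM pair lists per cutoff role; polarization list is a subset of
    the electrostatics list."""

    es_qm: np.ndarray
    es_mm: np.ndarray
    es_r: np.ndarray
    pol_qm: np.ndarray
    pol_mm: np.ndarray
    pol_r: np.ndarray


def displacements(a: np.ndarray, b: np.ndarray, box=None) -> np.ndarray:
    """Pairwise displacement vectors b[j] - a[i], minimum image if periodic.

    Returns an (len(a), len(b), 3) array.
    """
    d = b[None, :, :] - a[:, None, :]
    if box is not None:
        box = np.asarray(box, dtype=float)
        d -= box * np.round(d / box)
    return d


def build_qm_graph(sys: SimulationSystem) -> QMGraph:
    """All directed QM pairs with (minimum-image) distance <= r_graph.

    Brute-force all-pairs scan; systems handled here are small (the QM
    zone of a solute), so correctness beats cell-list bookkeeping.
    """
    pos = sys.qm.positions
    d = displacements(pos, pos, sys.box_lengths)
    r = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(r, np.inf)
    mask = r <= sys.cutoffs.r_graph
    if np.any(r[mask] < 1e-8):
        raise DegenerateGeometryError(
            "two QM atoms coincide; edge unit vector undefined")
    src, dst = np.nonzero(mask)
    rr = r[src, dst]
    return QMGraph(src, dst, rr, d[src, dst] / rr[:, None])


def gather_mm_pairs(sys: SimulationSystem) -> QMMMPairs:
    """Group-based gathering of MM sites around the QM zone.

    An MM charge group enters in full if any of its members lies within
    the cutoff of any QM atom; this keeps charge groups neutral across the
    boundary.  Distances are recorded per pair.
    """
    mm = sys.mm
    if mm.n_atoms == 0:
        e = np.zeros(0, dtype=int)
        return QMMMPairs(e, e, np.zeros(0), e, e, np.zeros(0))
    d = displacements(sys.qm.positions, mm.positions, sys.box_lengths)
    r = np.linalg.norm(d, axis=-1)

    def group_select(cutoff):
        within = (r <= cutoff).any(axis=0)          # per MM atom
        groups = np.unique(mm.group_ids[within])
        sel = np.isin(mm.group_ids, groups)
        qi, mi = np.nonzero(np.broadcast_to(sel[None, :], r.shape))
        return qi, mi, r[qi, mi]

    es_qm, es_mm, es_r = group_select(sys.cutoffs.r_es)
    pol_qm, pol_mm, pol_r = group_select(sys.cutoffs.r_pol)
    return QMMMPairs(es_qm, es_mm, es_r, pol_qm, pol_mm, pol_r)


def poly_envelope(r: np.ndarray, r_c: float) -> np.ndarray:
    """Quintic smoothstep envelope: 1 at r=0, 0 with zero first and second
    derivative at r=r_c, identically 0 beyond."""
    x = np.clip(np.asarray(r, dtype=float) / r_c, 0.0, 1.0)
    return 1.0 - x ** 3 * (10.0 - 15.0 * x + 6.0 * x * x)


def bessel_features(r, n_feats: int, r_c: float) -> np.ndarray:
    """Zeroth-order spherical Bessel radial basis with smooth envelope.

    Component n (1-based) is sqrt(2/r_c) * sin(n*pi*r/r_c) / r, multiplied
    by :func:`poly_envelope` so every component vanishes smoothly at r_c.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("bessel_features requires r > 0")
    n = np.arange(1, n_feats + 1)
    base = np.sqrt(2.0 / r_c) * np.sin(
        n * np.pi * r[..., None] / r_c) / r[..., None]
    return base * poly_envelope(r, r_c)[..., None]
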