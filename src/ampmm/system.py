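"""Data model for ML/MM systems and extended-XYZ I/O.

A simulation system is split into a QM zone (the solute, treated by the
learned potential) and an MM zone (fixed point charges with Lennard-Jones
parameters, typically solvent).  Units follow :mod:`ampmm.units`:
Angstrom, elementary charges, kJ/mol.

The extended-XYZ dialect used here is self-describing: per-atom columns
are ``species x y z [q] [gx gy gz]`` (the optional trailing triple holds
per-atom gradient labels), and the frame comment line carries
whitespace-separated ``key=value`` entries.  Recognised keys:

``energy``            frame energy label (kJ/mol)
``dipole``            3 numbers, molecular dipole label (e*A)
``quadrupole``        9 numbers, row-major molecular quadrupole (e*A^2)
``qm_mask``           per-atom 0/1 flags, 1 = QM atom (default: all QM)
``total_charge``      integer total charge of the QM zone
``box``               3 numbers, periodic box edge lengths (A)
``cutoffs``           3 numbers: r_graph r_pol r_es (A)
``group_ids``         per-MM-atom integer charge-group ids
``qm_lj_eps/qm_lj_sigma``  per-QM-atom LJ parameters (kJ/mol, A)
``mm_lj_eps/mm_lj_sigma``  per-MM-atom LJ parameters (kJ/mol, A)

Vector-valued entries are double-quoted, e.g. ``dipole="0.1 0.0 -0.2"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .units import NUMBERS, SYMBOLS


@dataclass
class CutoffSet:
    """Cutoff radii (A): QM graph, QM/MM polarization, QM/MM electrostatics."""

    r_graph: float = 5.0
    r_pol: float = 9.0
    r_es: float = 14.0

    @classmethod
    def from_yaml(cls, path) -> "CutoffSet":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**{k: float(v) for k, v in data.items()})


@dataclass
class QMZone:
    atomic_numbers: np.ndarray
    positions: np.ndarray
    total_charge: int = 0
    spin_multiplicity: Optional[int] = None  # stored, unused by the model
    lj_epsilon: Optional[np.ndarray] = None
    lj_sigma: Optional[np.ndarray] = None

    def __post_init__(self):
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.lj_epsilon is not None:
            self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        if self.lj_sigma is not None:
            self.lj_sigma = np.asarray(self.lj_sigma, dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)


@dataclass
class MMZone:
    positions: np.ndarray
    charges: np.ndarray
    lj_epsilon: np.ndarray
    lj_sigma: np.ndarray
    group_ids: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        self.lj_sigma = np.asarray(self.lj_sigma, dtype=float)
        self.group_ids = np.asarray(self.group_ids, dtype=int)

    @classmethod
    def empty(cls) -> "MMZone":
        z = np.zeros(0)
        return cls(np.zeros((0, 3)), z, z, z, np.zeros(0, dtype=int))

    @classmethod
    def from_charges(cls, positions, charges, lj_epsilon=None, lj_sigma=None,
                     group_ids=None) -> "MMZone":
        positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        n = len(positions)
        return cls(
            positions,
            np.asarray(charges, dtype=float),
            np.zeros(n) if lj_epsilon is None else lj_epsilon,
            np.full(n, 1.0) if lj_sigma is None else lj_sigma,
            np.arange(n) if group_ids is None else group_ids,
        )

    @property
    def n_atoms(self) -> int:
        return len(self.charges)


@dataclass
class SimulationSystem:
    qm: QMZone
    mm: MMZone = field(default_factory=MMZone.empty)
    box_lengths: Optional[np.ndarray] = None
    cutoffs: CutoffSet = field(default_factory=CutoffSet)

    def __post_init__(self):
        if self.box_lengths is not None:
            self.box_lengths = np.asarray(self.box_lengths, dtype=float).reshape(3)


@dataclass
class Labels:
    """Reference labels attached to a frame (all optional)."""

    energy: Optional[float] = None
    grad_qm: Optional[np.ndarray] = None
    grad_mm: Optional[np.ndarray] = None
    dipole: Optional[np.ndarray] = None
    quadrupole: Optional[np.ndarray] = None


class Frame(NamedTuple):
    system: SimulationSystem
    labels: Optional[Labels]


class ExtXYZError(ValueError):
    pass


def validate_system(sys: SimulationSystem) -> list:
    """Check all type invariants; returns a list of violation strings.

    Total on well-typed input: never raises, an empty list means valid.
    """
    v = []
    qm, mm, c = sys.qm, sys.mm, sys.cutoffs
    if qm.n_atoms < 1:
        v.append("qm.atomic_numbers: QM zone must contain at least one atom")
    if np.any(qm.atomic_numbers < 1):
        v.append("qm.atomic_numbers: atomic numbers must be >= 1")
    if not np.all(np.isfinite(qm.positions)):
        v.append("qm.positions: non-finite coordinates")
    n = mm.n_atoms
    for name in ("positions", "charges", "lj_epsilon", "lj_sigma", "group_ids"):
        if len(getattr(mm, name)) != n:
            v.append(f"mm.{name}: per-atom array length mismatch")
    if n:
        if np.any(mm.lj_epsilon < 0):
            v.append("mm.lj_epsilon: must be >= 0")
        if np.any(mm.lj_sigma <= 0):
            v.append("mm.lj_sigma: must be > 0")
    if not (0 < c.r_graph <= c.r_pol <= c.r_es):
        v.append("cutoffs: require 0 < r_graph <= r_pol <= r_es")
    if sys.box_lengths is not None:
        half = float(np.min(sys.box_lengths)) / 2.0
        for name in ("r_graph", "r_pol", "r_es"):
            if getattr(c, name) >= half:
                v.append(f"cutoffs.{name}: cutoff >= half box "
                         f"({getattr(c, name)} >= {half})")
    return v


# -- extended-XYZ ------------------------------------------------------

_QUOTED = re.compile(r'(\w+)=(?:"([^"]*)"|(\S+))')


def _parse_comment(line: str) -> dict:
    out = {}
    for m in _QUOTED.finditer(line):
        key = m.group(1)
        out[key] = m.group(2) if m.group(2) is not None else m.group(3)
    return out


def _floats(s: str) -> np.ndarray:
    return np.array([float(x) for x in s.split()])


def read_extxyz(path) -> list:
    """Read frames from the extended-XYZ dialect described in the module
    docstring; returns a list of :class:`Frame`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].strip())
        except ValueError:
            raise ExtXYZError(
                f"{path}:{i + 1}: malformed header, expected atom count, "
                f"got {lines[i]!r}")
        if i + 2 + nat > len(lines):
            raise ExtXYZError(f"{path}:{i + 1}: truncated frame ({nat} atoms)")
        meta = _parse_comment(lines[i + 1])
        symbols, coords, extra = [], [], []
        for k in range(nat):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise ExtXYZError(
                    f"{path}:{i + 3 + k}: atom line needs >= 4 columns")
            if parts[0] not in NUMBERS:
                raise ExtXYZError(
                    f"{path}:{i + 3 + k}: unknown element symbol {parts[0]!r}")
            symbols.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
            extra.append([float(x) for x in parts[4:]])
        frames.append(_assemble(symbols, np.array(coords).reshape(-1, 3),
                                extra, meta))
        i += 2 + nat
    return frames


def _assemble(symbols, coords, extra, meta) -> Frame:
    nat = len(symbols)
    mask = (np.array([int(x) for x in meta["qm_mask"].split()], dtype=bool)
            if "qm_mask" in meta else np.ones(nat, dtype=bool))
    z = np.array([NUMBERS[s] for s in symbols])
    ncols = max((len(e) for e in extra), default=0)
    q = np.array([e[0] if len(e) > 0 else 0.0 for e in extra])
    grads = (np.array([e[1:4] if len(e) >= 4 else [0.0] * 3 for e in extra])
             if ncols >= 4 else None)

    qm = QMZone(z[mask], coords[mask],
                total_charge=int(meta.get("total_charge", 0)))
    if "qm_lj_eps" in meta:
        qm.lj_epsilon = _floats(meta["qm_lj_eps"])
        qm.lj_sigma = _floats(meta["qm_lj_sigma"])
    if mask.all():
        mm = MMZone.empty()
    else:
        mmi = ~mask
        mm = MMZone.from_charges(
            coords[mmi], q[mmi],
            lj_epsilon=_floats(meta["mm_lj_eps"]) if "mm_lj_eps" in meta else None,
            lj_sigma=_floats(meta["mm_lj_sigma"]) if "mm_lj_sigma" in meta else None,
            group_ids=(np.array([int(x) for x in meta["group_ids"].split()])
                       if "group_ids" in meta else None),
        )
    box = _floats(meta["box"]) if "box" in meta else None
    cut = CutoffSet(*_floats(meta["cutoffs"])) if "cutoffs" in meta else CutoffSet()
    system = SimulationSystem(qm, mm, box, cut)

    labels = None
    if any(k in meta for k in ("energy", "dipole", "quadrupole")) or grads is not None:
        labels = Labels(
            energy=float(meta["energy"]) if "energy" in meta else None,
            grad_qm=grads[mask] if grads is not None else None,
            grad_mm=grads[~mask] if grads is not None and not mask.all() else None,
            dipole=_floats(meta["dipole"]) if "dipole" in meta else None,
            quadrupole=(_floats(meta["quadrupole"]).reshape(3, 3)
                        if "quadrupole" in meta else None),
        )
    return Frame(system, labels)


def _fmt(x) -> str:
    return " ".join(f"{v:.10g}" for v in np.asarray(x).ravel())


def write_extxyz(path, frames: Sequence[Frame]):
    """Write frames in the dialect read by :func:`read_extxyz`."""
    out = []
    for frame in frames:
        sys_, labels = frame
        qm, mm = sys_.qm, sys_.mm
        nat = qm.n_atoms + mm.n_atoms
        meta = [f'qm_mask="{" ".join(["1"] * qm.n_atoms + ["0"] * mm.n_atoms)}"',
                f"total_charge={qm.total_charge}"]
        c = sys_.cutoffs
        meta.append(f'cutoffs="{_fmt([c.r_graph, c.r_pol, c.r_es])}"')
        if sys_.box_lengths is not None:
            meta.append(f'box="{_fmt(sys_.box_lengths)}"')
        if qm.lj_epsilon is not None:
            meta.append(f'qm_lj_eps="{_fmt(qm.lj_epsilon)}"')
            meta.append(f'qm_lj_sigma="{_fmt(qm.lj_sigma)}"')
        if mm.n_atoms:
            meta.append(f'mm_lj_eps="{_fmt(mm.lj_epsilon)}"')
            meta.append(f'mm_lj_sigma="{_fmt(mm.lj_sigma)}"')
            meta.append(f'group_ids="{" ".join(str(g) for g in mm.group_ids)}"')
        grads = None
        if labels is not None:
            if labels.energy is not None:
                meta.append(f"energy={labels.energy:.12g}")
            if labels.dipole is not None:
                meta.append(f'dipole="{_fmt(labels.dipole)}"')
            if labels.quadrupole is not None:
                meta.append(f'quadrupole="{_fmt(labels.quadrupole)}"')
            if labels.grad_qm is not None:
                gmm = (labels.grad_mm if labels.grad_mm is not None
                       else np.zeros((mm.n_atoms, 3)))
                grads = np.vstack([labels.grad_qm, gmm])

        out.append(str(nat))
        out.append(" ".join(meta))
        charges = np.concatenate([np.zeros(qm.n_atoms), mm.charges])
        coords = np.vstack([qm.positions, mm.positions]) if mm.n_atoms \
            else qm.positions
        zs = list(qm.atomic_numbers) + [0] * mm.n_atoms
        for k in range(nat):
            sym = SYMBOLS[zs[k]] if k < qm.n_atoms else "H"
            # MM sites are written with a placeholder species; identity is
            # carried by qm_mask and the charge column.
            row = f"{sym} {_fmt(coords[k])} {charges[k]:.10g}"
            if grads is not None:
                row += f" {_fmt(grads[k])}"
            out.append(row)
    Path(path).write_text("\n".join(out) + "\n")
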