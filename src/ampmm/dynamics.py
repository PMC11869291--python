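"""Minimal MD/SD engine with harmonic umbrella restraints.

Propagation uses the BAOAB splitting of Langevin dynamics; with zero
friction the noise vanishes and the scheme reduces to velocity Verlet
(NVE).  Potentials are callables ``positions -> (energy, forces)`` so the
engine runs identically on the learned potential or on analytic surrogate
potentials.  Units: A, fs, K, kJ/mol, g/mol; friction in 1/ps.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np

from .system import MMZone
from .units import ACC, KB, KE, KIN


class DegenerateDihedralError(ValueError):
    """Collinear geometry; dihedral angle undefined."""


@dataclass
class IntegratorConfig:
    dt: float = 0.5                # fs
    temperature: float = 298.0     # K
    friction: float = 1.0          # 1/ps (SD only)
    scheme: str = "sd"             # {"sd", "nve"}
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")


@dataclass
class Restraint:
    """Harmonic restraint U = 1/2 k (xi - xi0)^2 on a distance (A) or a
    dihedral (degrees, difference wrapped to (-180, 180])."""

    kind: str                      # {"distance", "dihedral"}
    atoms: Sequence[int]
    center: float
    force_constant: float

    def __post_init__(self):
        need = {"distance": 2, "dihedral": 4}[self.kind]
        if len(self.atoms) != need:
            raise ValueError(f"{self.kind} restraint needs {need} atom indices")
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")


@dataclass
class UmbrellaWindow:
    restraints: List[Restraint]
    equilibration_steps: int = 1000
    production_steps: int = 10000
    output_stride: int = 10
    series: List[np.ndarray] = field(default_factory=list)
    failed: bool = False

    @property
    def centers(self):
        return np.array([r.center for r in self.restraints])

    @property
    def force_constants(self):
        return np.array([r.force_constant for r in self.restraints])


def _wrap_deg(x):
    """Wrap angle difference to (-180, 180]."""
    return -((-np.asarray(x) + 180.0) % 360.0 - 180.0)


def dihedral_angle(positions, atoms):
    """Dihedral angle in degrees and its analytic gradient (deg/A) with
    respect to the four atom positions."""
    p = np.asarray(positions, dtype=float)
    i, j, k, l = atoms
    b1 = p[j] - p[i]
    b2 = p[k] - p[j]
    b3 = p[l] - p[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq, n2sq = n1 @ n1, n2 @ n2
    b2n = np.linalg.norm(b2)
    if n1sq < 1e-14 or n2sq < 1e-14 or b2n < 1e-10:
        raise DegenerateDihedralError("collinear atoms in dihedral")
    phi = np.degrees(np.arctan2(np.cross(n1, n2) @ b2 / b2n, n1 @ n2))
    # standard analytic gradient (radians), then convert to degrees
    g1 = -(b2n / n1sq) * n1
    g4 = (b2n / n2sq) * n2
    s12 = (b1 @ b2) / (b2n * b2n)
    s32 = (b3 @ b2) / (b2n * b2n)
    g2 = -(1.0 + s12) * g1 + s32 * g4
    g3 = s12 * g1 - (1.0 + s32) * g4
    grad = np.zeros_like(p)
    conv = 180.0 / np.pi
    for idx, g in zip(atoms, (g1, g2, g3, g4)):
        grad[idx] = conv * g
    return phi, grad


def reaction_coordinate(restraint: Restraint, positions) -> float:
    p = np.asarray(positions, dtype=float)
    if restraint.kind == "distance":
        i, j = restraint.atoms
        return float(np.linalg.norm(p[j] - p[i]))
    phi, _ = dihedral_angle(p, restraint.atoms)
    return float(phi)


def restraint_energy(restraint: Restraint, positions):
    """Harmonic restraint energy (kJ/mol) and forces (kJ/mol/A)."""
    p = np.asarray(positions, dtype=float)
    k = restraint.force_constant
    forces = np.zeros_like(p)
    if restraint.kind == "distance":
        i, j = restraint.atoms
        d = p[j] - p[i]
        r = np.linalg.norm(d)
        dev = r - restraint.center
        u = d / r
        forces[i] = k * dev * u
        forces[j] = -k * dev * u
        return 0.5 * k * dev * dev, forces
    phi, grad = dihedral_angle(p, restraint.atoms)
    dev = _wrap_deg(phi - restraint.center)
    forces = -k * dev * grad
    return 0.5 * k * dev * dev, forces


# -- integrator --------------------------------------------------------

def maxwell_boltzmann(masses, temperature, rng) -> np.ndarray:
    """Initial velocities (A/fs) at the given temperature."""
    m = np.asarray(masses, dtype=float)[:, None]
    sigma = np.sqrt(KB * temperature / (m * KIN))
    return rng.normal(0.0, 1.0, (len(m), 3)) * sigma


def remove_com_motion(velocities, masses):
    m = np.asarray(masses, dtype=float)[:, None]
    velocities -= (velocities * m).sum(axis=0) / m.sum()
    return velocities


def sd_step(positions, velocities, forces, masses, potential,
            cfg: IntegratorConfig, rng):
    """One BAOAB Langevin step; returns (positions, velocities, forces,
    energy).  With friction 0 (or scheme 'nve') this is velocity Verlet.
    """
    dt = cfg.dt
    m = np.asarray(masses, dtype=float)[:, None]
    v = velocities + 0.5 * dt * forces / m * ACC
    x = positions + 0.5 * dt * v
    if cfg.scheme == "sd" and cfg.friction > 0:
        gamma = cfg.friction * 1e-3            # 1/ps -> 1/fs
        c1 = np.exp(-gamma * dt)
        sigma = np.sqrt(KB * cfg.temperature / (m * KIN) * (1.0 - c1 * c1))
        v = c1 * v + sigma * rng.normal(0.0, 1.0, v.shape)
    x = x + 0.5 * dt * v
    energy, forces = potential(x)
    v = v + 0.5 * dt * forces / m * ACC
    return x, v, forces, energy


def kinetic_energy(velocities, masses) -> float:
    m = np.asarray(masses, dtype=float)[:, None]
    return float(0.5 * np.sum(m * velocities ** 2) * KIN)


def integrate(positions, masses, potential, cfg: IntegratorConfig,
              n_steps: int, rng=None, velocities=None, record=None,
              stride: int = 1, com_removal_interval: int = 1000,
              force_limit: float = 1e8):
    """Propagate for n_steps; optionally record ``record(positions)`` every
    ``stride`` steps.  Returns (positions, velocities, samples list).

    Raises FloatingPointError if forces blow past ``force_limit``.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    x = np.array(positions, dtype=float)
    v = (maxwell_boltzmann(masses, cfg.temperature, rng)
         if velocities is None else np.array(velocities, dtype=float))
    _, f = potential(x)
    samples = []
    for step in range(1, n_steps + 1):
        x, v, f, _ = sd_step(x, v, f, masses, potential, cfg, rng)
        if not np.all(np.isfinite(f)) or np.max(np.abs(f)) > force_limit:
            raise FloatingPointError(f"trajectory blow-up at step {step}")
        if com_removal_interval and step % com_removal_interval == 0:
            remove_com_motion(v, masses)
        if record is not None and step % stride == 0:
            samples.append(record(x))
    return x, v, samples


# -- MM internal force field -------------------------------------------

def mm_forcefield(mm: MMZone, box=None, cutoff: float = 14.0,
                  dielectric: float = 78.5):
    """LJ plus reaction-field Coulomb for the MM zone (V_MM).

    Barker-Watts reaction field with a single cutoff:
    V_C(r) = k_e q_i q_j (1/r + k_rf r^2 - c_rf) for r < cutoff, with
    k_rf = (eps-1)/(2 eps + 1) / R_c^3 and c_rf chosen so V_C(R_c) = 0.
    Pairs within the same charge group are excluded.
    """
    n = mm.n_atoms
    forces = np.zeros((n, 3))
    if n < 2:
        return 0.0, forces
    iu, ju = np.triu_indices(n, 1)
    keep = mm.group_ids[iu] != mm.group_ids[ju]
    iu, ju = iu[keep], ju[keep]
    d = mm.positions[ju] - mm.positions[iu]
    if box is not None:
        d -= np.asarray(box) * np.round(d / np.asarray(box))
    r = np.linalg.norm(d, axis=1)
    within = r < cutoff
    iu, ju, d, r = iu[within], ju[within], d[within], r[within]
    if len(iu) == 0:
        return 0.0, forces

    k_rf = (dielectric - 1.0) / (2.0 * dielectric + 1.0) / cutoff ** 3
    c_rf = 1.0 / cutoff + k_rf * cutoff ** 2
    qq = KE * mm.charges[iu] * mm.charges[ju]
    v_c = qq * (1.0 / r + k_rf * r * r - c_rf)
    dv_c = qq * (-1.0 / r ** 2 + 2.0 * k_rf * r)

    eps = np.sqrt(mm.lj_epsilon[iu] * mm.lj_epsilon[ju])
    sig = 0.5 * (mm.lj_sigma[iu] + mm.lj_sigma[ju])
    sr6 = (sig / r) ** 6
    v_lj = 4.0 * eps * (sr6 * sr6 - sr6)
    dv_lj = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r

    fpair = -(dv_c + dv_lj)[:, None] * (d / r[:, None])  # force on atom j
    np.add.at(forces, ju, fpair)
    np.add.at(forces, iu, -fpair)
    return float(np.sum(v_c + v_lj)), forces


# -- umbrella sampling --------------------------------------------------

def umbrella_schedule(kind: str, n: int, lo: float = 2.0, hi: float = 20.0,
                      atoms=None, atoms2=None, force_constant: float = 20.0,
                      equilibration_steps: int = 1000,
                      production_steps: int = 10000,
                      output_stride: int = 10) -> List[UmbrellaWindow]:
    """Equidistant umbrella windows.

    ``distance_1d``: n centers from lo to hi inclusive (A).
    ``dihedral_2d``: n x n centers covering (-180, 180] per angle (deg);
    ``atoms``/``atoms2`` are the two dihedral index quadruples.
    """
    if n < 2:
        raise ValueError("need at least two umbrella windows per dimension")
    common = dict(equilibration_steps=equilibration_steps,
                  production_steps=production_steps,
                  output_stride=output_stride)
    if kind == "distance_1d":
        atoms = atoms if atoms is not None else (0, 1)
        return [UmbrellaWindow([Restraint("distance", atoms, c, force_constant)],
                               **common)
                for c in np.linspace(lo, hi, n)]
    if kind == "dihedral_2d":
        atoms = atoms if atoms is not None else (0, 1, 2, 3)
        atoms2 = atoms2 if atoms2 is not None else (1, 2, 3, 4)
        centers = -180.0 + 360.0 * (np.arange(n) + 1) / n   # in (-180, 180]
        return [UmbrellaWindow(
            [Restraint("dihedral", atoms, c1, force_constant),
             Restraint("dihedral", atoms2, c2, force_constant)], **common)
            for c1 in centers for c2 in centers]
    raise ValueError(f"unknown schedule kind {kind!r}")


def cumulative_sampling_ns(n_windows: int, n_replicates: int,
                           ns_per_window: float) -> float:
    """Total sampling bookkeeping: windows x replicates x length."""
    return n_windows * n_replicates * ns_per_window


def run_umbrella(positions, masses, potential, windows,
                 cfg: IntegratorConfig, replicates: int = 3,
                 initialize: Optional[Callable] = None) -> List[UmbrellaWindow]:
    """Run biased sampling for every window and replicate.

    Replicates differ only in their velocity seeds, derived
    deterministically from ``cfg.seed``; reaction-coordinate samples are
    stored per replicate on the returned windows.  A window whose
    trajectory blows up is marked failed and the rest continue.
    """
    out = []
    for wi, window in enumerate(windows):
        if window.production_steps <= 0:
            raise ValueError("production steps must be positive")
        window = copy.deepcopy(window)
        rests = window.restraints

        def biased(x, rests=rests):
            e, f = potential(x)
            for rest in rests:
                er, fr = restraint_energy(rest, x)
                e, f = e + er, f + fr
            return e, f

        def record(x, rests=rests):
            vals = [reaction_coordinate(r, x) for r in rests]
            return vals[0] if len(vals) == 1 else vals

        x0 = (initialize(window) if initialize is not None
              else np.array(positions, dtype=float))
        for rep in range(replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, wi, rep]))
            try:
                x, v, _ = integrate(x0, masses, biased, cfg,
                                    window.equilibration_steps, rng=rng)
                _, _, samples = integrate(
                    x, masses, biased, cfg, window.production_steps, rng=rng,
                    velocities=v, record=record, stride=window.output_stride)
            except FloatingPointError:
                window.failed = True
                window.series = []
                break
            window.series.append(np.asarray(samples))
        out.append(window)
    return out
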