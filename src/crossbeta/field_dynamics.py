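"""Charged elastic-network model under an oscillating field.

One bead per residue at the Calpha position, formal charge from the
sequence, harmonic springs within a cutoff, and an overdamped
(Brownian) integrator::

    r <- r + (dt/gamma) (F_spring + F_field) + sqrt(2 kB T dt / gamma) eta

Units: kJ/mol, nm, ps, elementary charge, K.  The field is
``E(t) = E0 cos(2 pi nu t)`` along a fixed axis; a charge of +1 e in a
1 V/nm field feels 96.485 kJ mol^-1 nm^-1 (Faraday constant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .fibril_model import AssemblyMap, charge_of
from .structure_io import Structure, Trajectory

__all__ = [
    "FieldSpec",
    "ENMSystem",
    "field_at",
    "field_force",
    "build_enm",
    "simulate",
    "response_amplitude",
    "KB_KJ_PER_MOL_K",
    "E_FIELD_FORCE_FACTOR",
]

KB_KJ_PER_MOL_K = 0.00831446261815324
#: force on +1 e in a 1 V/nm field, kJ mol^-1 nm^-1 (Faraday constant / 1000)
E_FIELD_FORCE_FACTOR = 96.485


@dataclass(frozen=True)
class FieldSpec:
    """Oscillating external field: strength (mV/nm), frequency (GHz)."""

    e0_mv_per_nm: float = 0.0
    frequency_ghz: float = 0.0
    axis: Tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.e0_mv_per_nm < 0:
            raise ValueError("field strength must be >= 0")
        if self.frequency_ghz < 0:
            raise ValueError("frequency must be >= 0")
        norm = math.sqrt(sum(c * c for c in self.axis))
        if norm < 1e-12:
            raise ValueError("field axis must be a nonzero vector")
        object.__setattr__(
            self, "axis", tuple(c / norm for c in self.axis)
        )

    @property
    def period_ns(self) -> float:
        """Oscillation period 1/nu in ns (inf for a static field)."""
        if self.frequency_ghz == 0:
            return math.inf
        return 1.0 / self.frequency_ghz

    @property
    def omega_per_ps(self) -> float:
        """Angular frequency 2 pi nu in rad/ps."""
        return 2.0 * math.pi * self.frequency_ghz * 1e-3


def field_at(t_ps: float, spec: FieldSpec) -> np.ndarray:
    """Field vector (mV/nm) at time t (ps): E0 cos(2 pi nu t) * axis."""
    if t_ps < 0:
        raise ValueError("time must be >= 0")
    return (
        spec.e0_mv_per_nm
        * math.cos(spec.omega_per_ps * t_ps)
        * np.asarray(spec.axis)
    )


def field_force(charge_e: float, field_mv_per_nm: np.ndarray) -> np.ndarray:
    """Force (kJ mol^-1 nm^-1) on a charge (e) in a field (mV/nm)."""
    return charge_e * np.asarray(field_mv_per_nm) * 1e-3 * E_FIELD_FORCE_FACTOR


@dataclass
class ENMSystem:
    """Bead/spring network with per-bead charges."""

    positions_nm: np.ndarray            # (n, 3)
    charges_e: np.ndarray               # (n,)
    springs: np.ndarray                 # (m, 2) bead index pairs
    stiffness: np.ndarray               # (m,) kJ mol^-1 nm^-2
    rest_lengths_nm: np.ndarray         # (m,)
    gamma: float = 50.0                 # kJ mol^-1 ps nm^-2
    temperature_k: float = 300.0
    tether_k: Optional[np.ndarray] = None   # per-bead restraint to start, kJ mol^-1 nm^-2
    chain_of_bead: Optional[np.ndarray] = None
    residue_of_bead: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions_nm = np.asarray(self.positions_nm, dtype=float)
        self.charges_e = np.asarray(self.charges_e, dtype=float)
        self.springs = np.asarray(self.springs, dtype=int).reshape(-1, 2)
        self.stiffness = np.asarray(self.stiffness, dtype=float)
        self.rest_lengths_nm = np.asarray(self.rest_lengths_nm, dtype=float)
        if self.tether_k is not None:
            self.tether_k = np.asarray(self.tether_k, dtype=float)
        if self.gamma <= 0:
            raise ValueError("friction gamma must be positive")
        if len(self.stiffness) and self.stiffness.min() <= 0:
            raise ValueError("spring stiffness must be positive")

    @property
    def n_beads(self) -> int:
        return len(self.positions_nm)

    def spring_forces(self, positions: np.ndarray) -> np.ndarray:
        forces = np.zeros_like(positions)
        if self.tether_k is not None:
            forces -= self.tether_k[:, None] * (positions - self.positions_nm)
        if len(self.springs) == 0:
            return forces
        i, j = self.springs[:, 0], self.springs[:, 1]
        delta = positions[j] - positions[i]
        dist = np.linalg.norm(delta, axis=1)
        dist = np.maximum(dist, 1e-12)
        mag = self.stiffness * (dist - self.rest_lengths_nm)
        fvec = (mag / dist)[:, None] * delta
        np.add.at(forces, i, fvec)
        np.add.at(forces, j, -fvec)
        return forces


def build_enm(
    structure: Structure,
    assembly: Optional[AssemblyMap] = None,
    cutoff_nm: float = 1.2,
    k: float = 500.0,
    k_interprotofilament: Optional[float] = None,
    gamma: float = 50.0,
    temperature_k: float = 300.0,
) -> ENMSystem:
    """One bead per residue at the Calpha with its formal charge.

    Springs connect beads within ``cutoff_nm`` at their starting
    separation.  Springs crossing the protofilament interface may take
    a separate (typically weaker) stiffness so that field-driven
    separation is reachable.
    """
    from .fibril_model import tau_core_spec

    _THREE_TO_ONE = {
        "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
        "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
        "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
        "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
    }
    ca_idx = structure.select(atom_name="CA")
    positions = structure.coords_nm[ca_idx]
    charges = np.array([
        charge_of(_THREE_TO_ONE.get(str(structure.res_names[i]).upper(), "G"))
        for i in ca_idx
    ], dtype=float)
    chain_ids = np.array(
        [structure.chain_ids_per_atom[i] for i in ca_idx], dtype=object
    )
    residues = np.array([int(structure.res_numbers[i]) for i in ca_idx])

    tree = cKDTree(positions)
    pairs = tree.query_pairs(cutoff_nm, output_type="ndarray")
    if len(pairs) == 0:
        springs = np.zeros((0, 2), dtype=int)
        stiff = np.zeros(0)
        rest = np.zeros(0)
    else:
        springs = pairs
        rest = np.linalg.norm(
            positions[pairs[:, 0]] - positions[pairs[:, 1]], axis=1
        )
        stiff = np.full(len(pairs), float(k))
        if k_interprotofilament is not None and assembly is not None:
            pf = np.array([
                assembly.protofilament_of.get(c, "?") for c in chain_ids
            ], dtype=object)
            cross = pf[pairs[:, 0]] != pf[pairs[:, 1]]
            stiff[cross] = float(k_interprotofilament)
    return ENMSystem(
        positions_nm=positions,
        charges_e=charges,
        springs=springs,
        stiffness=stiff,
        rest_lengths_nm=rest,
        gamma=gamma,
        temperature_k=temperature_k,
        chain_of_bead=chain_ids,
        residue_of_bead=residues,
    )


def simulate(
    system: ENMSystem,
    fieldspec: FieldSpec,
    dt_ps: float = 0.05,
    n_steps: int = 10000,
    stride: int = 100,
    seed: int = 0,
    topology: Optional[Structure] = None,
) -> Trajectory:
    """Overdamped Langevin dynamics under the oscillating field.

    Bit-reproducible from the seed.  Raises ``ValueError`` when the
    timestep violates the stability bound ``dt k / gamma < 0.1`` or any
    per-step displacement exceeds 0.5 nm.

    The returned trajectory carries a minimal bead topology (one CA per
    bead) unless an explicit ``topology`` matching the bead count is
    given.
    """
    k_max = 0.0
    if len(system.stiffness):
        k_max = float(system.stiffness.max())
    if system.tether_k is not None and len(system.tether_k):
        k_max = max(k_max, float(system.tether_k.max()))
    if k_max > 0:
        ratio = dt_ps * k_max / system.gamma
        if ratio >= 0.1:
            raise ValueError(
                f"unstable timestep: dt*k/gamma = {ratio:.3f} >= 0.1"
            )
    rng = np.random.default_rng(seed)
    pos = system.positions_nm.copy()
    mobility = dt_ps / system.gamma
    noise_scale = math.sqrt(
        2.0 * KB_KJ_PER_MOL_K * system.temperature_k * dt_ps / system.gamma
    )
    frames = [pos.copy()]
    times = [0.0]
    for step in range(1, n_steps + 1):
        t = (step - 1) * dt_ps
        e_vec = field_at(t, fieldspec)
        f = system.spring_forces(pos)
        if system.charges_e.any():
            f = f + field_force(1.0, e_vec)[None, :] * system.charges_e[:, None]
        disp = mobility * f + noise_scale * rng.standard_normal(pos.shape)
        max_disp = float(np.abs(disp).max())
        if max_disp > 0.5:
            raise ValueError(
                f"integration unstable at step {step}: displacement "
                f"{max_disp:.3f} nm > 0.5 nm"
            )
        pos = pos + disp
        if step % stride == 0:
            frames.append(pos.copy())
            times.append(step * dt_ps * 1e-3)  # ps -> ns
    if topology is None:
        topology = _bead_topology(system)
    return Trajectory(
        topology=topology,
        frames_nm=np.array(frames),
        times_ns=np.array(times),
    )


def _bead_topology(system: ENMSystem) -> Structure:
    n = system.n_beads
    chains = (
        system.chain_of_bead
        if system.chain_of_bead is not None
        else np.array(["A"] * n, dtype=object)
    )
    residues = (
        system.residue_of_bead
        if system.residue_of_bead is not None
        else np.arange(1, n + 1)
    )
    return Structure(
        atom_names=np.array(["CA"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        res_numbers=np.asarray(residues, dtype=int),
        res_names=np.array(["GLY"] * n, dtype=object),
        chain_ids_per_atom=np.asarray(chains, dtype=object),
        coords_nm=system.positions_nm.copy(),
        title="ENM bead model",
    )


def trajectory_energies(
    system: ENMSystem, traj: Trajectory, fieldspec: FieldSpec
) -> Dict[str, np.ndarray]:
    """Per-frame spring and field potential energies (kJ/mol).

    Spring energy is relative to the starting (rest) geometry; field
    energy is ``-sum(q_i F(t) . r_i)`` with the conversion of
    :func:`field_force`.
    """
    spring = np.zeros(traj.n_frames)
    fieldE = np.zeros(traj.n_frames)
    for f in range(traj.n_frames):
        pos = traj.frames_nm[f]
        if len(system.springs):
            i, j = system.springs[:, 0], system.springs[:, 1]
            dist = np.linalg.norm(pos[j] - pos[i], axis=1)
            spring[f] = float(
                0.5 * (system.stiffness * (dist - system.rest_lengths_nm) ** 2).sum()
            )
        if system.tether_k is not None:
            spring[f] += float(0.5 * (
                system.tether_k
                * ((pos - system.positions_nm) ** 2).sum(axis=1)
            ).sum())
        e_vec = field_at(traj.times_ns[f] * 1000.0, fieldspec)
        force_per_e = field_force(1.0, e_vec)
        fieldE[f] = float(-(system.charges_e * (pos @ force_per_e)).sum())
    return {"spring_kj_mol": spring, "field_kj_mol": fieldE}


def response_amplitude(
    charge_e: float,
    k: float,
    gamma: float,
    fieldspec: FieldSpec,
) -> float:
    """Steady-state oscillation amplitude (nm) of a driven harmonic bead.

    Closed form for the overdamped oscillator driven at frequency nu:
    ``q E0 / sqrt(k^2 + (2 pi nu gamma)^2)``.
    """
    f0 = abs(float(field_force(charge_e, fieldspec.e0_mv_per_nm * np.ones(1))[0]))
    omega = fieldspec.omega_per_ps
    return f0 / math.sqrt(k * k + (omega * gamma) ** 2)


def fit_response_amplitude(
    times_ps: np.ndarray,
    displacement_nm: np.ndarray,
    fieldspec: FieldSpec,
    discard_fraction: float = 0.25,
) -> float:
    """Amplitude of the sinusoid at the drive frequency in a 1D signal.

    Least-squares projection onto cos/sin at the drive frequency after
    discarding the initial transient.
    """
    times_ps = np.asarray(times_ps, dtype=float)
    y = np.asarray(displacement_nm, dtype=float)
    start = int(len(y) * discard_fraction)
    t, y = times_ps[start:], y[start:]
    omega = fieldspec.omega_per_ps
    basis = np.column_stack(
        (np.cos(omega * t), np.sin(omega * t), np.ones_like(t))
    )
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    return float(math.hypot(coef[0], coef[1]))
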