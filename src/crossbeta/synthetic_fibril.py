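"""Idealized cross-beta decamer builder and synthetic degradation data.

The builder produces backbone-only (N, CA, C, O, H) decamers of two
pentameric protofilaments.  Each chain is a C-shaped 77-residue peptide
traced in the layer plane: two beta-strand arms joined by a tight turn
at residues 340-350, stacked in-register along z.  The strand geometry
is derived once from an ideal parallel-beta backbone built from
internal coordinates and oriented so that stacking at the cross-beta
rise produces Kabsch-Sander hydrogen-bond ladders between layers.

Protofilament b placement differs by topology: a C2 rotation about the
fibril axis at the 332-336 face (symmetric, phf) or an oblique contact
of the 321-324 face against the 313-317 face (asymmetric, sf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .fibril_model import TAU_FIRST_RESIDUE, tau_core_spec
from .structure_io import Structure, Trajectory

__all__ = [
    "BuilderParams",
    "DecayGeneratorParams",
    "build_fibril",
    "generate_decay_traces",
    "perturb_trajectory",
    "designed_strand_residues",
]

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
_CHAIN_IDS = "ABCDEFGHIJ"
_MIN_CONTACT_NM = 0.15

# ideal backbone internal coordinates (nm / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 0.1458, 0.1525, 0.1329, 0.1231, 0.101
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.0, 116.6, 121.7
_PHI_BETA, _PSI_BETA = -119.0, 113.0


def default_role_table() -> Dict[int, str]:
    """strand / turn / terminus role per tau residue number."""
    spec = tau_core_spec()
    roles = {n: "strand" for n in spec.residue_numbers}
    for n in spec.segment_residues("turn"):
        roles[n] = "turn"
    for n in (304, 305, 379, 380):
        roles[n] = "terminus"
    return roles


@dataclass(frozen=True)
class BuilderParams:
    """Geometry of an idealized cross-beta decamer."""

    topology: str = "phf"              # phf | sf
    chains_per_protofilament: int = 5
    rise_nm: float = 0.475
    twist_deg: float = 0.0
    gap_nm: Optional[float] = None     # Calpha face-to-face gap; per-topology default
    turn_span: int = 5                 # residues carrying the 180 deg heading change
    single_protofilament: bool = False
    role_table: Dict[int, str] = field(default_factory=default_role_table)

    def __post_init__(self) -> None:
        if self.topology not in ("phf", "sf"):
            raise ValueError(f"topology must be phf or sf, got {self.topology!r}")
        if self.rise_nm <= 0:
            raise ValueError("rise must be positive")
        if self.chains_per_protofilament < 2:
            raise ValueError("need at least 2 chains per protofilament")

    @property
    def effective_gap_nm(self) -> float:
        # defaults tuned so the symmetric (phf) interface buries more
        # area than the offset (sf) one while staying collision-free
        if self.gap_nm is not None:
            return self.gap_nm
        return 0.60 if self.topology == "phf" else 0.72


@dataclass(frozen=True)
class DecayGeneratorParams:
    """Ground truth and noise for synthetic beta-content decay traces."""

    model: str = "m3"
    A: float = 0.6
    B: float = 0.5
    C: float = 0.4
    D: float = 5.0
    noise_sigma: float = 0.02
    n_runs: int = 3
    n_points: int = 100
    t_max: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.B <= 0 or self.D <= 0:
            raise ValueError("time constants must be positive")


# ---------------------------------------------------------------------------
# ideal strand template


def _nerf(a, b, c, bond, angle_deg, dihedral_deg):
    angle = math.radians(angle_deg)
    dihed = math.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(angle),
        bond * math.cos(dihed) * math.sin(angle),
        bond * math.sin(dihed) * math.sin(angle),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _ks_energy(o, c, n, h) -> float:
    f = 0.084 * 332.0
    r = np.linalg.norm
    # factor 10: distances nm -> Angstrom
    return f * (
        1 / (10 * r(o - n)) + 1 / (10 * r(c - h))
        - 1 / (10 * r(o - h)) - 1 / (10 * r(c - n))
    )


@lru_cache(maxsize=None)
def _beta_template(rise_nm: float = 0.475) -> Tuple[float, Tuple]:
    """Per-parity backbone offsets of an ideal stacked parallel strand.

    Builds a 12-residue beta backbone from internal coordinates, aligns
    its repeat axis with x, then picks the rotation about x that
    maximises interlayer hydrogen-bond strength when copies are stacked
    at ``rise_nm`` along z.  Returns the per-residue advance ``a`` (nm)
    and offsets of N, CA, C, O, H for even/odd residues relative to the
    point (i*a, 0, 0).
    """
    n_res = 12
    N = [np.zeros(3)]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = math.radians(180.0 - _A_N_CA_C)
    C = [CA[0] + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])]
    for _ in range(1, n_res):
        n_next = _nerf(N[-1], CA[-1], C[-1], _B_C_N, _A_CA_C_N, _PSI_BETA)
        ca_next = _nerf(CA[-1], C[-1], n_next, _B_N_CA, _A_C_N_CA, 180.0)
        c_next = _nerf(C[-1], n_next, ca_next, _B_CA_C, _A_N_CA_C, _PHI_BETA)
        N.append(n_next)
        CA.append(ca_next)
        C.append(c_next)
    N, CA, C = np.array(N), np.array(CA), np.array(C)
    O = np.zeros_like(C)
    for i in range(n_res):
        d1 = C[i] - CA[i]
        d1 /= np.linalg.norm(d1)
        if i + 1 < n_res:
            d2 = C[i] - N[i + 1]
            d2 /= np.linalg.norm(d2)
            d = d1 + d2
            d /= np.linalg.norm(d)
        else:
            d = d1
        O[i] = C[i] + _B_C_O * d

    axis = CA[10] - CA[2]
    advance = float(np.linalg.norm(axis) / 8.0)
    axis /= np.linalg.norm(axis)
    # rotate repeat axis onto x
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(axis, x)
    s = np.linalg.norm(v)
    if s > 1e-12:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - axis @ x) / s**2)
    else:
        rot = np.eye(3)
    N, CA, C, O = (arr @ rot.T for arr in (N, CA, C, O))

    def _h_positions(Na, CAa, Ca):
        H = np.full_like(Na, np.nan)
        for i in range(1, len(Na)):
            d1 = Na[i] - Ca[i - 1]
            d1 /= np.linalg.norm(d1)
            d2 = Na[i] - CAa[i]
            d2 /= np.linalg.norm(d2)
            d = d1 + d2
            d /= np.linalg.norm(d)
            H[i] = Na[i] + _B_N_H * d
        return H

    z = np.array([0.0, 0.0, rise_nm])
    best_score, best_deg = math.inf, 0
    for deg in range(0, 360):
        th = math.radians(deg)
        rx = np.array([
            [1, 0, 0],
            [0, math.cos(th), -math.sin(th)],
            [0, math.sin(th), math.cos(th)],
        ])
        n2, ca2, c2, o2 = (arr @ rx.T for arr in (N, CA, C, O))
        h2 = _h_positions(n2, ca2, c2)
        score = 0.0
        for i in range(4, 8):
            j = i - 1
            score += min(0.0, _ks_energy(o2[j], c2[j], n2[i] + z, h2[i] + z))
            score += min(0.0, _ks_energy(o2[j] + z, c2[j] + z, n2[i], h2[i]))
        if score < best_score:
            best_score, best_deg = score, deg
    th = math.radians(best_deg)
    rx = np.array([
        [1, 0, 0],
        [0, math.cos(th), -math.sin(th)],
        [0, math.sin(th), math.cos(th)],
    ])
    N, CA, C, O = (arr @ rx.T for arr in (N, CA, C, O))
    H = _h_positions(N, CA, C)

    offsets = []
    for parity, i in ((0, 4), (1, 5)):
        ref = np.array([i * advance, 0.0, 0.0])
        offsets.append({
            "N": tuple(N[i] - ref),
            "CA": tuple(CA[i] - ref),
            "C": tuple(C[i] - ref),
            "O": tuple(O[i] - ref),
            "H": tuple(H[i] - ref),
        })
    return advance, (offsets[0], offsets[1])


# ---------------------------------------------------------------------------
# chain path and assembly


def _chain_path(params: BuilderParams) -> Tuple[np.ndarray, np.ndarray]:
    """Per-residue 2D path points and heading angles of the C-shape."""
    advance, _ = _beta_template(params.rise_nm)
    spec = tau_core_spec()
    n = len(spec.sequence)
    turn_lo, turn_hi = spec.named_segments["turn"]
    centre = (turn_lo + turn_hi) / 2.0 - TAU_FIRST_RESIDUE  # index of turn apex
    half = params.turn_span / 2.0
    heading = np.empty(n)
    for i in range(n):
        u = (i - (centre - half)) / params.turn_span
        u = min(1.0, max(0.0, u))
        heading[i] = math.pi * u  # 0 -> 180 deg across the turn span
    # curl the N-terminal tail away from the interface side (negative
    # heading decaying to zero), so the free end does not graze the
    # obliquely placed partner protofilament
    n_curl, curl = 9, math.radians(-25.0)
    for i in range(min(n_curl, n)):
        heading[i] += curl * (1.0 - i / n_curl) ** 2
    points = np.zeros((n, 2))
    for i in range(1, n):
        mid = 0.5 * (heading[i - 1] + heading[i])
        points[i] = points[i - 1] + advance * np.array(
            [math.cos(mid), math.sin(mid)]
        )
    return points, heading


def _template_chain(params: BuilderParams) -> Dict[str, np.ndarray]:
    """Backbone atoms of one C-shaped chain in the z=0 layer plane."""
    advance, offsets = _beta_template(params.rise_nm)
    points, heading = _chain_path(params)
    n = len(points)
    spec = tau_core_spec()
    turn_lo, turn_hi = spec.named_segments["turn"]
    atoms = {k: np.zeros((n, 3)) for k in ("N", "CA", "C", "O", "H")}
    for i in range(n):
        t = np.array([math.cos(heading[i]), math.sin(heading[i]), 0.0])
        m = np.array([-math.sin(heading[i]), math.cos(heading[i]), 0.0])
        zhat = np.array([0.0, 0.0, 1.0])
        base = np.array([points[i, 0], points[i, 1], 0.0])
        off = offsets[i % 2]
        # roll the backbone about the path tangent inside the turn so
        # the carbonyls leave the stacking axis and the turn residues
        # stop forming interlayer ladders (turn backbone is not beta)
        resnum = TAU_FIRST_RESIDUE + i
        if turn_lo <= resnum <= turn_hi:
            chi = math.radians(70.0)
            cos_c, sin_c = math.cos(chi), math.sin(chi)
            m_loc, z_loc = cos_c * m + sin_c * zhat, -sin_c * m + cos_c * zhat
        else:
            m_loc, z_loc = m, zhat
        for name in atoms:
            o = np.asarray(off[name])
            atoms[name][i] = base + o[0] * t + o[1] * m_loc + o[2] * z_loc
    return atoms


def _ca_centroid(atoms: Dict[str, np.ndarray], residues: Sequence[int]) -> np.ndarray:
    idx = [r - TAU_FIRST_RESIDUE for r in residues]
    return atoms["CA"][idx].mean(axis=0)


def _rot_z(deg: float) -> np.ndarray:
    th = math.radians(deg)
    return np.array([
        [math.cos(th), -math.sin(th), 0.0],
        [math.sin(th), math.cos(th), 0.0],
        [0.0, 0.0, 1.0],
    ])


def _transform(atoms: Dict[str, np.ndarray], rot: np.ndarray, trans: np.ndarray):
    return {k: v @ rot.T + trans for k, v in atoms.items()}


def _side_normal(chain_a: Dict[str, np.ndarray]) -> np.ndarray:
    """In-plane unit normal of arm 1, pointing away from the molecule."""
    centre = _ca_centroid(chain_a, range(304, 381))
    face = _ca_centroid(chain_a, range(332, 337))
    n = np.array([0.0, 1.0])  # arm 1 runs along +x, normal is +/- y
    if (centre[:2] - face[:2]) @ n > 0:
        n = -n
    return n


def _place_protofilament_b(
    chain_a: Dict[str, np.ndarray], params: BuilderParams
) -> Dict[str, np.ndarray]:
    gap = params.effective_gap_nm
    out = _side_normal(chain_a)
    if params.topology == "phf":
        # C2 rotation about z at the 332-336 face: symmetric interface,
        # PGGGQ of both chains facing each other across the gap
        face = _ca_centroid(chain_a, range(332, 337))
        pivot = face[:2] + 0.5 * gap * out
        rot = _rot_z(180.0)
        trans = np.array([2 * pivot[0], 2 * pivot[1], 0.0])
        return _transform(chain_a, rot, trans)
    # sf: antiparallel offset contact, 321-324 of b against the 313-317
    # face of a.  The sequence offset makes the interface asymmetric;
    # the curled N-terminal tails of both chains bend away from the
    # partner, which confines the contact zone to the 313-324 stretch.
    face_a = _ca_centroid(chain_a, range(313, 318))
    target = face_a[:2] + gap * out
    b = _transform(chain_a, _rot_z(180.0), np.zeros(3))
    face_b = _ca_centroid(b, range(321, 325))
    shift = np.array([target[0] - face_b[0], target[1] - face_b[1], 0.0])
    return _transform(b, np.eye(3), shift)


def build_fibril(params: Optional[BuilderParams] = None, **kwargs) -> Structure:
    """Build an idealized cross-beta assembly as a backbone Structure.

    Ten chains (A..E protofilament a, F..J protofilament b) of 77
    residues each, atoms N/CA/C/O/H, stacked in-register along z at the
    given rise and per-layer twist about the assembly axis.  With
    ``single_protofilament=True`` only chains A..E are built.

    Raises ``ValueError`` when the parameters produce a steric
    collision (non-bonded interatomic distance below 0.15 nm).
    """
    if params is None:
        params = BuilderParams(**kwargs)
    elif kwargs:
        params = replace(params, **kwargs)
    chain_a = _template_chain(params)
    layers: List[Dict[str, np.ndarray]] = []
    protos = [chain_a]
    if not params.single_protofilament:
        protos.append(_place_protofilament_b(chain_a, params))
    centre_xy = np.zeros(3)
    if len(protos) == 2:
        centre_xy = 0.5 * (
            _ca_centroid(protos[0], range(304, 381))
            + _ca_centroid(protos[1], range(304, 381))
        )
    else:
        centre_xy = _ca_centroid(protos[0], range(304, 381))
    centre_xy[2] = 0.0

    spec = tau_core_spec()
    n_res = len(spec.sequence)
    names, elements, resnums, resnames, chains, coords = [], [], [], [], [], []
    n_layers = params.chains_per_protofilament
    for p_idx, proto in enumerate(protos):
        for layer in range(n_layers):
            rot = _rot_z(layer * params.twist_deg)
            shift = np.array([0.0, 0.0, layer * params.rise_nm])
            placed = {
                k: (v - centre_xy) @ rot.T + centre_xy + shift
                for k, v in proto.items()
            }
            chain_id = _CHAIN_IDS[p_idx * n_layers + layer]
            for i in range(n_res):
                resnum = TAU_FIRST_RESIDUE + i
                three = _ONE_TO_THREE[spec.sequence[i]]
                for atom, el in (
                    ("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("H", "H")
                ):
                    names.append(atom)
                    elements.append(el)
                    resnums.append(resnum)
                    resnames.append(three)
                    chains.append(chain_id)
                    coords.append(placed[atom][i])
    structure = Structure(
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        res_numbers=np.array(resnums, dtype=int),
        res_names=np.array(resnames, dtype=object),
        chain_ids_per_atom=np.array(chains, dtype=object),
        coords_nm=np.array(coords),
        title=f"idealized {params.topology} cross-beta assembly",
    )
    _check_sterics(structure)
    return structure


def _check_sterics(structure: Structure) -> None:
    coords = structure.coords_nm
    tree = cKDTree(coords)
    pairs = tree.query_pairs(_MIN_CONTACT_NM, output_type="ndarray")
    for i, j in pairs:
        same_chain = (
            structure.chain_ids_per_atom[i] == structure.chain_ids_per_atom[j]
        )
        near_seq = abs(
            int(structure.res_numbers[i]) - int(structure.res_numbers[j])
        ) <= 1
        if same_chain and near_seq:
            continue  # covalently bonded neighbourhood
        raise ValueError(
            "steric collision between atoms "
            f"{structure.chain_ids_per_atom[i]}/{structure.res_numbers[i]}/"
            f"{structure.atom_names[i]} and "
            f"{structure.chain_ids_per_atom[j]}/{structure.res_numbers[j]}/"
            f"{structure.atom_names[j]}"
        )


def designed_strand_residues(params: Optional[BuilderParams] = None) -> List[int]:
    """Residue numbers the builder lays out with ideal strand geometry."""
    params = params or BuilderParams()
    return sorted(n for n, role in params.role_table.items() if role == "strand")


# ---------------------------------------------------------------------------
# synthetic observables


def _decay_curve(p: DecayGeneratorParams, t: np.ndarray) -> np.ndarray:
    if p.model == "m1":
        return np.exp(-t / p.B)
    if p.model == "m2":
        return p.A * np.exp(-t / p.B)
    if p.model == "m3":
        return p.A * np.exp(-t / p.B) + (1.0 - p.A) * np.exp(-t / p.D)
    if p.model == "m4":
        return p.A * np.exp(-t / p.B) + p.C * np.exp(-t / p.D)
    raise ValueError(f"unknown decay model {p.model!r}")


def generate_decay_traces(
    params: DecayGeneratorParams,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Noisy decay series emulating beta-content traces.

    ``y = model(t) + N(0, sigma)`` clipped to [0, 1]; bit-reproducible
    from the seed.
    """
    rng = np.random.default_rng(params.seed)
    t = np.linspace(0.0, params.t_max, params.n_points)
    clean = _decay_curve(params, t)
    out = []
    for _ in range(params.n_runs):
        noise = rng.normal(0.0, params.noise_sigma, size=t.shape) \
            if params.noise_sigma > 0 else np.zeros_like(t)
        out.append((t.copy(), np.clip(clean + noise, 0.0, 1.0)))
    return out


def load_schedule(path) -> List["ScheduleEvent"]:
    """Read a perturbation schedule from a YAML file.

    Format: a top-level ``events`` list, each entry with a ``kind`` and
    the keyword fields of :class:`ScheduleEvent`.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    events = []
    for entry in data.get("events", []):
        entry = dict(entry)
        if "residues" in entry and entry["residues"] is not None:
            entry["residues"] = tuple(int(r) for r in entry["residues"])
        events.append(ScheduleEvent(**entry))
    return events


@dataclass(frozen=True)
class ScheduleEvent:
    """One kinematic perturbation applied while generating frames."""

    kind: str                       # terminus_jitter | turn_jitter | separation
    sigma_nm: float = 0.0
    residues: Optional[Tuple[int, ...]] = None
    start_frame: int = 0
    velocity_nm_per_frame: float = 0.0
    protofilament: str = "b"


def perturb_trajectory(
    structure: Structure,
    schedule: Sequence[ScheduleEvent],
    n_frames: int = 50,
    frame_interval_ns: float = 1.0,
    seed: int = 0,
    assembly=None,
) -> Trajectory:
    """Kinematic emulation of degradation events on a static structure.

    Events: Gaussian jitter on terminus or turn residue sets, and rigid
    separation of one protofilament from a given frame onward.  With an
    empty schedule every frame equals the input.  Deterministic from
    the seed.
    """
    rng = np.random.default_rng(seed)
    frames = np.repeat(structure.coords_nm[None, :, :], n_frames, axis=0)
    spec = tau_core_spec()
    for event in schedule:
        if event.kind in ("terminus_jitter", "turn_jitter"):
            if event.residues is not None:
                residues = list(event.residues)
            elif event.kind == "turn_jitter":
                residues = spec.segment_residues("turn")
            else:
                residues = [304, 305, 306, 307, 308, 376, 377, 378, 379, 380]
            idx = structure.select(res_numbers=residues)
            jitter = rng.normal(
                0.0, event.sigma_nm, size=(n_frames, len(idx), 3)
            )
            frames[:, idx, :] += jitter
        elif event.kind == "separation":
            if assembly is None:
                from .fibril_model import build_assembly_map
                assembly = build_assembly_map(structure)
            chains = assembly.chains_of(event.protofilament)
            idx = structure.select(chain_id=chains)
            direction = _separation_direction(structure, assembly, event)
            for f in range(event.start_frame, n_frames):
                step = (f - event.start_frame + 1) * event.velocity_nm_per_frame
                frames[f, idx, :] += step * direction
        else:
            raise ValueError(f"unknown schedule event kind {event.kind!r}")
    times = np.arange(n_frames) * float(frame_interval_ns)
    return Trajectory(topology=structure, frames_nm=frames, times_ns=times)


def _separation_direction(structure, assembly, event) -> np.ndarray:
    moving = assembly.chains_of(event.protofilament)
    staying = [
        c for c in structure.chain_ids() if c not in moving
    ]
    com_m = structure.coords(chain_id=moving).mean(axis=0)
    com_s = structure.coords(chain_id=staying).mean(axis=0)
    d = com_m - com_s
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        return np.array([0.0, 1.0, 0.0])
    return d / norm
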