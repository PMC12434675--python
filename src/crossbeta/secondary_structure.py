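"""Kabsch-Sander secondary-structure assignment and beta-content series.

Three-state reduction: E (ladder-forming beta strand), H (alpha helix),
C (everything else, including isolated bridges and turns).  The
hydrogen-bond energy form and the -0.5 kcal/mol cutoff define the
method and are not configurable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Structure, Trajectory

__all__ = [
    "hbond_energy",
    "assign_ss",
    "beta_fraction",
    "SSAssignment",
]

logger = logging.getLogger(__name__)

# Kabsch-Sander electrostatic model: q1*q2*332 with q1*q2 = 0.42*0.20 = 0.084
_KS_FACTOR = 0.084 * 332.0  # kcal/mol * Angstrom
HBOND_CUTOFF_KCAL = -0.5
_MIN_DIST_NM = 0.05
_CA_NEIGHBOUR_CUTOFF_NM = 0.9  # CA-CA prefilter for bond candidates
_NH_BOND_NM = 0.101


def hbond_energy(
    o_nm: np.ndarray, c_nm: np.ndarray, n_nm: np.ndarray, h_nm: np.ndarray
) -> float:
    """Backbone hydrogen-bond electrostatic energy (kcal/mol).

    ``E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)`` with
    distances in Angstrom; the bond criterion is ``E < -0.5``.
    Inputs are points in nm.
    """
    o, c, n, h = (np.asarray(p, dtype=float) for p in (o_nm, c_nm, n_nm, h_nm))
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    r_oc = np.linalg.norm(o - c)
    r_nh = np.linalg.norm(n - h)
    if min(r_on, r_ch, r_oh, r_cn, r_oc, r_nh) < _MIN_DIST_NM:
        raise ValueError(
            "degenerate hydrogen-bond geometry: interatomic distance below "
            f"{_MIN_DIST_NM} nm"
        )
    # distances to Angstrom
    return float(
        _KS_FACTOR
        * (1.0 / (10 * r_on) + 1.0 / (10 * r_ch) - 1.0 / (10 * r_oh) - 1.0 / (10 * r_cn))
    )


@dataclass
class _Residue:
    chain: str
    number: int
    name: str
    n: Optional[np.ndarray]
    ca: Optional[np.ndarray]
    c: Optional[np.ndarray]
    o: Optional[np.ndarray]
    h: Optional[np.ndarray]

    @property
    def complete(self) -> bool:
        return all(p is not None for p in (self.n, self.ca, self.c, self.o))


def _collect_residues(structure: Structure) -> List[_Residue]:
    table: Dict[Tuple[str, int], Dict[str, np.ndarray]] = {}
    order: List[Tuple[str, int]] = []
    resname: Dict[Tuple[str, int], str] = {}
    for i in range(structure.n_atoms):
        key = (structure.chain_ids_per_atom[i], int(structure.res_numbers[i]))
        if key not in table:
            table[key] = {}
            order.append(key)
            resname[key] = structure.res_names[i]
        table[key][structure.atom_names[i]] = structure.coords_nm[i]
    out = []
    for key in order:
        atoms = table[key]
        out.append(
            _Residue(
                chain=key[0],
                number=key[1],
                name=resname[key],
                n=atoms.get("N"),
                ca=atoms.get("CA"),
                c=atoms.get("C"),
                o=atoms.get("O"),
                h=atoms.get("H", atoms.get("HN")),
            )
        )
    return out


def _reconstruct_h(residues: List[_Residue]) -> None:
    """Place missing amide H 1.01 A from N opposite the C(i-1)/CA bisector.

    First residue of a chain cannot donate; prolines have no amide H.
    """
    for i, res in enumerate(residues):
        if res.h is not None or res.n is None or res.ca is None:
            continue
        if res.name.upper() == "PRO":
            continue
        if i == 0 or residues[i - 1].chain != res.chain:
            continue
        prev = residues[i - 1]
        if prev.c is None:
            continue
        d1 = res.n - prev.c
        d2 = res.n - res.ca
        n1, n2 = np.linalg.norm(d1), np.linalg.norm(d2)
        if n1 < 1e-9 or n2 < 1e-9:
            continue
        direction = d1 / n1 + d2 / n2
        norm = np.linalg.norm(direction)
        if norm < 1e-9:
            continue
        res.h = res.n + _NH_BOND_NM * direction / norm


def _hbond_matrix(residues: List[_Residue]) -> np.ndarray:
    """hb[d, a] True when NH of residue d donates to CO of residue a."""
    n = len(residues)
    hb = np.zeros((n, n), dtype=bool)
    cas = np.array(
        [r.ca if r.ca is not None else np.full(3, 1e6) for r in residues]
    )
    tree = cKDTree(cas)
    pairs = tree.query_pairs(_CA_NEIGHBOUR_CUTOFF_NM, output_type="ndarray")
    for d, a in np.vstack([pairs, pairs[:, ::-1]]) if len(pairs) else []:
        don, acc = residues[d], residues[a]
        if don.h is None or don.n is None or acc.o is None or acc.c is None:
            continue
        if don.chain == acc.chain and abs(d - a) <= 1:
            continue
        try:
            e = hbond_energy(acc.o, acc.c, don.n, don.h)
        except ValueError:
            continue
        if e < HBOND_CUTOFF_KCAL:
            hb[d, a] = True
    return hb


def _same_chain(residues, i, j) -> bool:
    return (
        0 <= i < len(residues)
        and 0 <= j < len(residues)
        and residues[i].chain == residues[j].chain
    )


def _helix_mask(residues: List[_Residue], hb: np.ndarray) -> np.ndarray:
    n = len(residues)
    turn4 = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        if _same_chain(residues, i, i + 4) and hb[i + 4, i]:
            turn4[i] = True
    helix = np.zeros(n, dtype=bool)
    for i in range(1, n - 4):
        if turn4[i - 1] and turn4[i]:
            helix[i : i + 4] = True
    return helix


def _bridges(residues: List[_Residue], hb: np.ndarray) -> List[Tuple[int, int, str]]:
    n = len(residues)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if residues[i].chain == residues[j].chain and j - i < 3:
                continue
            im, ip = i - 1, i + 1
            jm, jp = j - 1, j + 1
            ok_i = _same_chain(residues, im, i) and _same_chain(residues, i, ip)
            ok_j = _same_chain(residues, jm, j) and _same_chain(residues, j, jp)
            if ok_i and ok_j:
                para = (hb[j, im] and hb[ip, j]) or (hb[i, jm] and hb[jp, i])
                anti_wide = hb[jp, im] and hb[ip, jm]
            else:
                para = False
                anti_wide = False
            anti = (hb[j, i] and hb[i, j]) or anti_wide
            if para:
                out.append((i, j, "P"))
            if anti:
                out.append((i, j, "A"))
    return out


def _strand_mask(residues: List[_Residue], hb: np.ndarray) -> np.ndarray:
    bridges = _bridges(residues, hb)
    bset = set(bridges)
    strand = np.zeros(len(residues), dtype=bool)
    for (i, j, kind) in bridges:
        if kind == "P":
            ladder = (
                (i + 1, j + 1, "P") in bset
                or (i - 1, j - 1, "P") in bset
            )
        else:
            ladder = (
                (i + 1, j - 1, "A") in bset
                or (i - 1, j + 1, "A") in bset
            )
        if ladder:
            strand[i] = True
            strand[j] = True
    return strand


@dataclass
class SSAssignment:
    """Per-residue codes over {E, H, C} for one or more frames."""

    residue_keys: List[Tuple[str, int]]  # (chain, residue number)
    codes: np.ndarray                    # (n_frames, n_residues) of 'E'/'H'/'C'

    @property
    def n_frames(self) -> int:
        return self.codes.shape[0]


def assign_ss(structure: Structure) -> List[str]:
    """Assign {E, H, C} per residue of one frame.

    Backbone N/CA/C/O are required per residue; amide H is taken from
    the file when present, else reconstructed.  Residues with missing
    backbone atoms are coded C with a warning.
    """
    residues = _collect_residues(structure)
    incomplete = [r for r in residues if not r.complete]
    if incomplete:
        logger.warning(
            "%d residue(s) missing backbone atoms assigned C: %s",
            len(incomplete),
            [(r.chain, r.number) for r in incomplete[:5]],
        )
    _reconstruct_h(residues)
    hb = _hbond_matrix(residues)
    helix = _helix_mask(residues, hb)
    strand = _strand_mask(residues, hb)
    codes = []
    for i, r in enumerate(residues):
        if not r.complete:
            codes.append("C")
        elif helix[i]:
            codes.append("H")
        elif strand[i]:
            codes.append("E")
        else:
            codes.append("C")
    return codes


def assign_ss_trajectory(traj: Trajectory) -> SSAssignment:
    """Run :func:`assign_ss` on every frame."""
    keys = [
        (r.chain, r.number) for r in _collect_residues(traj.topology)
    ]
    codes = np.empty((traj.n_frames, len(keys)), dtype="U1")
    for f in range(traj.n_frames):
        codes[f] = assign_ss(traj.frame(f))
    return SSAssignment(residue_keys=keys, codes=codes)


def beta_fraction(
    traj: Trajectory,
    selection: Optional[Sequence[Tuple[str, int]]] = None,
    assignment: Optional[SSAssignment] = None,
) -> np.ndarray:
    """Fraction of residues coded E per frame, over an optional selection.

    ``selection`` is a list of (chain id, residue number) keys; default
    is every residue.  Returns an array of shape (n_frames,) in [0, 1].
    """
    if assignment is None:
        assignment = assign_ss_trajectory(traj)
    if selection is None:
        mask = np.ones(len(assignment.residue_keys), dtype=bool)
    else:
        wanted = set(selection)
        mask = np.array(
            [k in wanted for k in assignment.residue_keys], dtype=bool
        )
    if not mask.any():
        raise ValueError("empty residue selection for beta_fraction")
    return (assignment.codes[:, mask] == "E").mean(axis=1)


def aggregate_runs(series: Sequence[np.ndarray]) -> Tuple[np.ndarray, np.ndarray]:
    """Mean and standard deviation across runs, per time point."""
    stacked = np.vstack(series)
    return stacked.mean(axis=0), stacked.std(axis=0, ddof=0)
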