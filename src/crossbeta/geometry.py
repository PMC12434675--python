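"""Sheet-twist dihedral, Shrake-Rupley SASA and protofilament interface area.

Lengths are nm internally; areas are reported in Angstrom^2, matching
the convention of the structural literature.  The interface area is the
sum of the two separate protofilament surface areas minus the assembly
surface area (twice the conventional per-side buried area — kept
deliberately, see the package docs).
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .fibril_model import AssemblyMap
from .structure_io import Structure

__all__ = [
    "dihedral",
    "sheet_twist",
    "sasa",
    "interface_area",
    "VDW_RADII_NM",
    "PROBE_RADIUS_NM",
]

#: Heavy-atom van der Waals radii (nm), standard Bondi-type set.
VDW_RADII_NM: Dict[str, float] = {
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
    "H": 0.120,
    "SE": 0.190,
}
PROBE_RADIUS_NM = 0.14
DEFAULT_SPHERE_POINTS = 960


def dihedral(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> float:
    """Signed four-point dihedral in degrees, IUPAC convention.

    Right-handed sign, trans = 180 deg; range (-180, 180].
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ (b2 / np.linalg.norm(b2)))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def sheet_twist(
    structure: Structure,
    assembly: AssemblyMap,
    residue_pair: Tuple[int, int] = (306, 310),
) -> float:
    """Beta-sheet twist between the two lowest layers of protofilament a.

    The dihedral over the Calpha atoms (res_i of chain 1a, res_j of
    chain 1a, res_j of chain 2a, res_i of chain 2a) with the default
    residue pair (306, 310).  Degrees, signed.
    """
    c1 = assembly.chain_by_label("1a")
    c2 = assembly.chain_by_label("2a")
    ri, rj = residue_pair
    pts = []
    for chain, res in ((c1, ri), (c1, rj), (c2, rj), (c2, ri)):
        idx = structure.select(
            atom_name="CA", chain_id=chain, res_numbers=[res]
        )
        if len(idx) == 0:
            raise ValueError(
                f"missing Calpha of residue {res} in chain {chain!r} "
                "for twist dihedral"
            )
        pts.append(structure.coords_nm[idx[0]])
    return dihedral(*pts)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def _radii(structure: Structure, include_hydrogens: bool) -> Tuple[np.ndarray, np.ndarray]:
    elements = [str(e).upper() for e in structure.elements]
    keep = np.array(
        [include_hydrogens or e != "H" for e in elements], dtype=bool
    )
    unknown = sorted(
        {e for e, k in zip(elements, keep) if k and e not in VDW_RADII_NM}
    )
    if unknown:
        raise ValueError(
            f"no van der Waals radius for element(s) {unknown}; "
            "extend VDW_RADII_NM or strip those atoms"
        )
    idx = np.flatnonzero(keep)
    radii = np.array([VDW_RADII_NM[elements[i]] for i in idx])
    return idx, radii


def sasa(
    structure: Structure,
    probe_nm: float = PROBE_RADIUS_NM,
    n_points: int = DEFAULT_SPHERE_POINTS,
    include_hydrogens: bool = False,
) -> Tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom's extended sphere (vdW radius + probe) is sampled with a
    deterministic quasi-uniform point set; points inside any neighbour's
    extended sphere are buried.  Hydrogens are excluded by default (the
    deposited models are heavy-atom).

    Returns ``(per_atom_area, total_area)`` in Angstrom^2; the per-atom
    array is aligned with the full atom table (zeros for excluded
    atoms).
    """
    idx, radii = _radii(structure, include_hydrogens)
    coords = structure.coords_nm[idx]
    ext = radii + probe_nm
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * ext.max()
    per_atom = np.zeros(structure.n_atoms)
    for a in range(len(idx)):
        pts = coords[a] + ext[a] * unit
        neighbours = [
            b for b in tree.query_ball_point(coords[a], ext[a] + ext.max())
            if b != a
            and np.linalg.norm(coords[b] - coords[a]) < ext[a] + ext[b]
        ]
        if neighbours:
            nb_coords = coords[neighbours]
            nb_ext = ext[neighbours]
            d2 = (
                (pts[:, None, :] - nb_coords[None, :, :]) ** 2
            ).sum(axis=2)
            buried = (d2 < (nb_ext**2)[None, :]).any(axis=1)
            accessible = np.count_nonzero(~buried)
        else:
            accessible = n_points
        # area of the extended sphere in A^2 (1 nm^2 = 100 A^2)
        area_nm2 = 4.0 * np.pi * ext[a] ** 2 * accessible / n_points
        per_atom[idx[a]] = area_nm2 * 100.0
    return per_atom, float(per_atom.sum())


def interface_area(
    structure: Structure,
    assembly: AssemblyMap,
    probe_nm: float = PROBE_RADIUS_NM,
    n_points: int = DEFAULT_SPHERE_POINTS,
) -> Dict[str, float]:
    """Protofilament interface area by SASA subtraction (Angstrom^2).

    ``interface = sasa(pentamer a) + sasa(pentamer b) - sasa(assembly)``.
    Returns all four numbers.
    """
    pfs = assembly.protofilaments
    if len(pfs) != 2:
        raise ValueError("interface area needs two protofilaments")
    chains_a = assembly.chains_of(pfs[0])
    chains_b = assembly.chains_of(pfs[1])
    _, total = sasa(structure, probe_nm, n_points)
    _, area_a = sasa(structure.subset_chains(chains_a), probe_nm, n_points)
    _, area_b = sasa(structure.subset_chains(chains_b), probe_nm, n_points)
    return {
        "sasa_decamer": total,
        "sasa_pentamer_a": area_a,
        "sasa_pentamer_b": area_b,
        "interface_area": area_a + area_b - total,
    }
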