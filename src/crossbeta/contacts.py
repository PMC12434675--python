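"""Calpha contact classes and native-contact-fraction time series.

Contact classes, with cutoffs in nm:

* intrapeptide: same chain, sequence separation > 3, Calpha within 1.25
* interpeptide: different chains, Calpha within 0.8
* interprotofilament: different protofilaments, Calpha within 1.0

Distances strictly below the cutoff count as in contact; the same rule
is applied when building the reference set and when tracking it.  A
pair on different protofilaments may appear in both the interpeptide
and interprotofilament classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .fibril_model import AssemblyMap
from .structure_io import Structure, Trajectory

__all__ = [
    "CUTOFFS_NM",
    "ContactRecord",
    "ContactSet",
    "reference_contacts",
    "contact_fraction",
    "per_residue_fraction",
]

CUTOFFS_NM: Dict[str, float] = {
    "intrapeptide": 1.25,
    "interpeptide": 0.8,
    "interprotofilament": 1.0,
}
MIN_SEQ_SEPARATION = 3  # intrapeptide pairs must be more than this apart

ResidueKey = Tuple[str, int]  # (chain id, residue number)


@dataclass(frozen=True)
class ContactRecord:
    a: ResidueKey
    b: ResidueKey
    contact_class: str
    cutoff_nm: float


@dataclass
class ContactSet:
    """Reference contacts plus the Calpha indexing used to track them."""

    records: List[ContactRecord]
    residue_keys: List[ResidueKey]       # order of the Calpha table
    ca_indices: np.ndarray               # atom indices of the Calphas

    def by_class(self, contact_class: str) -> List[ContactRecord]:
        return [r for r in self.records if r.contact_class == contact_class]

    def classes(self) -> List[str]:
        return [c for c in CUTOFFS_NM if any(
            r.contact_class == c for r in self.records
        )]

    def __len__(self) -> int:
        return len(self.records)


def _ca_table(structure: Structure) -> Tuple[List[ResidueKey], np.ndarray]:
    keys: List[ResidueKey] = []
    indices: List[int] = []
    seen = set()
    for i in range(structure.n_atoms):
        key = (structure.chain_ids_per_atom[i], int(structure.res_numbers[i]))
        if key in seen:
            continue
        if structure.atom_names[i] == "CA":
            keys.append(key)
            indices.append(i)
            seen.add(key)
    # verify every residue has a Calpha
    all_keys = set()
    for i in range(structure.n_atoms):
        all_keys.add(
            (structure.chain_ids_per_atom[i], int(structure.res_numbers[i]))
        )
    missing = sorted(all_keys - seen)
    if missing:
        raise ValueError(f"residues missing a Calpha atom: {missing[:5]}")
    return keys, np.array(indices, dtype=int)


def reference_contacts(
    structure: Structure, assembly: AssemblyMap
) -> ContactSet:
    """All class-qualified Calpha pairs of the given (starting) structure.

    Unordered pairs are stored once per class; a pair can belong to both
    the interpeptide and interprotofilament classes when it satisfies
    both definitions.
    """
    keys, ca_idx = _ca_table(structure)
    coords = structure.coords_nm[ca_idx]
    seq_pos: Dict[ResidueKey, int] = {}
    for chain in structure.chain_ids():
        for pos, num in enumerate(structure.residue_numbers(chain)):
            seq_pos[(chain, num)] = pos

    max_cutoff = max(CUTOFFS_NM.values())
    tree = cKDTree(coords)
    pairs = tree.query_pairs(max_cutoff, output_type="ndarray")
    records: List[ContactRecord] = []
    for ii, jj in pairs:
        ka, kb = keys[ii], keys[jj]
        d = float(np.linalg.norm(coords[ii] - coords[jj]))
        same_chain = ka[0] == kb[0]
        if same_chain:
            if (
                abs(seq_pos[ka] - seq_pos[kb]) > MIN_SEQ_SEPARATION
                and d < CUTOFFS_NM["intrapeptide"]
            ):
                records.append(
                    ContactRecord(ka, kb, "intrapeptide", CUTOFFS_NM["intrapeptide"])
                )
        else:
            if d < CUTOFFS_NM["interpeptide"]:
                records.append(
                    ContactRecord(ka, kb, "interpeptide", CUTOFFS_NM["interpeptide"])
                )
            pf_a = assembly.protofilament_of.get(ka[0])
            pf_b = assembly.protofilament_of.get(kb[0])
            if (
                pf_a is not None
                and pf_b is not None
                and pf_a != pf_b
                and d < CUTOFFS_NM["interprotofilament"]
            ):
                records.append(
                    ContactRecord(
                        ka, kb, "interprotofilament",
                        CUTOFFS_NM["interprotofilament"],
                    )
                )
    return ContactSet(records=records, residue_keys=keys, ca_indices=ca_idx)


def _pair_indices(refset: ContactSet) -> Dict[str, np.ndarray]:
    pos = {k: i for i, k in enumerate(refset.residue_keys)}
    out: Dict[str, np.ndarray] = {}
    for cls in CUTOFFS_NM:
        recs = refset.by_class(cls)
        if recs:
            out[cls] = np.array(
                [(pos[r.a], pos[r.b]) for r in recs], dtype=int
            )
    return out


def contact_fraction(
    traj: Trajectory,
    refset: ContactSet,
    classes: Optional[Sequence[str]] = None,
) -> Dict[str, np.ndarray]:
    """Per-class fraction of reference contacts surviving in each frame.

    A class with no reference pairs is reported as missing (absent key),
    never as zero.  Returns ``{class: array of shape (n_frames,)}``.
    """
    pair_idx = _pair_indices(refset)
    if classes is None:
        classes = list(pair_idx)
    else:
        for c in classes:
            if c not in CUTOFFS_NM:
                raise ValueError(f"unknown contact class {c!r}")
        classes = [c for c in classes if c in pair_idx]
    ca = traj.frames_nm[:, refset.ca_indices, :]  # (F, R, 3)
    out: Dict[str, np.ndarray] = {}
    for cls in classes:
        idx = pair_idx[cls]
        delta = ca[:, idx[:, 0], :] - ca[:, idx[:, 1], :]
        dist = np.linalg.norm(delta, axis=2)  # (F, P)
        out[cls] = (dist < CUTOFFS_NM[cls]).mean(axis=1)
    return out


def per_residue_fraction(
    traj: Trajectory,
    refset: ContactSet,
    contact_class: str,
    mode: str = "pair_average",
) -> Tuple[List[ResidueKey], np.ndarray]:
    """Per-residue contact survival for one class.

    ``mode='pair_average'`` (default) averages the survival indicator
    over all reference pairs involving the residue;
    ``mode='any_contact'`` reports whether at least one such pair
    survives.  Returns the residue keys that have reference pairs and a
    (n_frames, n_residues) matrix.
    """
    if mode not in ("pair_average", "any_contact"):
        raise ValueError(f"unknown mode {mode!r}")
    recs = refset.by_class(contact_class)
    if not recs:
        raise ValueError(f"no reference pairs in class {contact_class!r}")
    pos = {k: i for i, k in enumerate(refset.residue_keys)}
    involved: Dict[ResidueKey, List[int]] = {}
    pairs = np.array([(pos[r.a], pos[r.b]) for r in recs], dtype=int)
    for pi, r in enumerate(recs):
        involved.setdefault(r.a, []).append(pi)
        involved.setdefault(r.b, []).append(pi)
    ca = traj.frames_nm[:, refset.ca_indices, :]
    dist = np.linalg.norm(
        ca[:, pairs[:, 0], :] - ca[:, pairs[:, 1], :], axis=2
    )
    alive = dist < CUTOFFS_NM[contact_class]  # (F, P)
    res_keys = sorted(involved)
    out = np.empty((traj.n_frames, len(res_keys)))
    for ri, key in enumerate(res_keys):
        cols = involved[key]
        if mode == "pair_average":
            out[:, ri] = alive[:, cols].mean(axis=1)
        else:
            out[:, ri] = alive[:, cols].any(axis=1)
    return res_keys, out
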