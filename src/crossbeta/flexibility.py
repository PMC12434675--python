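"""Rigid-body superposition and central-chain-anchored RMSF.

Every frame is superposed onto the first frame using the Calpha atoms
of the anchor chain (the stack-index-3 chain of each protofilament);
fluctuations are then measured for each chain about the per-atom mean
position after alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .fibril_model import AssemblyMap
from .structure_io import Trajectory

__all__ = ["superpose", "apply_transform", "rmsf", "RMSFProfile"]


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Kabsch algorithm via SVD; reflections are excluded (proper rotation
    only).  Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``.

    Raises ``ValueError`` for fewer than 3 points or a degenerate
    (collinear) selection.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"selection shapes differ: {mobile.shape} vs {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    x = mobile - mu_m
    y = reference - mu_r
    # collinearity check: rank of the centred cloud
    if np.linalg.matrix_rank(x, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) selection for superposition")
    cov = x.T @ y
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = mu_r - rot @ mu_m
    fitted = mobile @ rot.T + trans
    rmsd = float(np.sqrt(((fitted - reference) ** 2).sum(axis=1).mean()))
    return rot, trans, rmsd


def apply_transform(
    coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray
) -> np.ndarray:
    return np.asarray(coords) @ rotation.T + translation


@dataclass
class RMSFProfile:
    """Per-chain, per-residue Calpha RMSF (nm) with its alignment anchor."""

    anchor_chain: str
    residue_numbers: Dict[str, List[int]]
    rmsf_nm: Dict[str, np.ndarray]

    def chain(self, chain_id: str) -> Tuple[List[int], np.ndarray]:
        return self.residue_numbers[chain_id], self.rmsf_nm[chain_id]


def rmsf(traj: Trajectory, assembly: AssemblyMap) -> Dict[str, RMSFProfile]:
    """Central-chain-anchored RMSF profiles, one per protofilament.

    For each protofilament, every frame is aligned to frame 0 on the
    Calphas of the central (stack-index-3) chain, then per-residue
    fluctuations about the aligned mean are computed for each of its
    five chains.  Returns ``{protofilament label: RMSFProfile}``.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    top = traj.topology
    out: Dict[str, RMSFProfile] = {}
    for pf in assembly.protofilaments:
        chains = assembly.chains_of(pf)
        anchor = chains[2]
        anchor_idx = top.select(atom_name="CA", chain_id=anchor)
        ref = traj.frames_nm[0][anchor_idx]
        chain_idx = {c: top.select(atom_name="CA", chain_id=c) for c in chains}
        aligned = {
            c: np.empty((traj.n_frames, len(idx), 3))
            for c, idx in chain_idx.items()
        }
        for f in range(traj.n_frames):
            rot, trans, _ = superpose(traj.frames_nm[f][anchor_idx], ref)
            for c, idx in chain_idx.items():
                aligned[c][f] = apply_transform(
                    traj.frames_nm[f][idx], rot, trans
                )
        numbers = {c: top.residue_numbers(c) for c in chains}
        values: Dict[str, np.ndarray] = {}
        for c in chains:
            mean = aligned[c].mean(axis=0)
            dev2 = ((aligned[c] - mean) ** 2).sum(axis=2)
            values[c] = np.sqrt(dev2.mean(axis=0))
        out[pf] = RMSFProfile(
            anchor_chain=anchor, residue_numbers=numbers, rmsf_nm=values
        )
    return out
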