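"""Independent reference implementations used to check the package.

These deliberately use different algorithms/libraries than the code
under test: an external DSSP implementation, a quaternion-based
superposition, an O(n^2) contact enumeration, and closed-form sphere
areas.
"""

from __future__ import annotations

import warnings

import numpy as np


def reference_dssp(structure, tmp_path):
    """Three-state codes from the MDAnalysis (pydssp-derived) DSSP."""
    warnings.filterwarnings("ignore")
    import MDAnalysis as mda
    from MDAnalysis.analysis.dssp import DSSP

    from crossbeta.structure_io import write_structure

    path = tmp_path / "ref_dssp_input.pdb"
    write_structure(structure, path)
    u = mda.Universe(str(path))
    codes = np.array(DSSP(u).run().results.dssp[0])
    return np.where(codes == "-", "C", codes)


def quaternion_superpose(mobile, reference):
    """Horn's closed-form quaternion absolute orientation."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mu_m, mu_r = mobile.mean(axis=0), reference.mean(axis=0)
    x, y = mobile - mu_m, reference - mu_r
    s = x.T @ y
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    w, v = np.linalg.eigh(k)
    q = v[:, np.argmax(w)]
    q0, q1, q2, q3 = q
    rot = np.array([
        [q0*q0 + q1*q1 - q2*q2 - q3*q3, 2*(q1*q2 - q0*q3), 2*(q1*q3 + q0*q2)],
        [2*(q1*q2 + q0*q3), q0*q0 - q1*q1 + q2*q2 - q3*q3, 2*(q2*q3 - q0*q1)],
        [2*(q1*q3 - q0*q2), 2*(q2*q3 + q0*q1), q0*q0 - q1*q1 - q2*q2 + q3*q3],
    ])
    trans = mu_r - rot @ mu_m
    fitted = mobile @ rot.T + trans
    rmsd = float(np.sqrt(((fitted - reference) ** 2).sum(axis=1).mean()))
    return rot, trans, rmsd


def brute_force_contact_fraction(structure_coords, keys, refset, cls):
    """Exhaustive per-frame survival fraction for one contact class."""
    from crossbeta.contacts import CUTOFFS_NM

    pos = {k: i for i, k in enumerate(keys)}
    records = [r for r in refset.records if r.contact_class == cls]
    alive = 0
    for r in records:
        d = np.linalg.norm(
            structure_coords[pos[r.a]] - structure_coords[pos[r.b]]
        )
        if d < CUTOFFS_NM[cls]:
            alive += 1
    return alive / len(records)


def brute_force_reference_records(coords, keys, protofilament_of, seq_pos):
    """Exhaustive O(n^2) enumeration of class-qualified contact pairs."""
    from crossbeta.contacts import CUTOFFS_NM, MIN_SEQ_SEPARATION

    found = set()
    n = len(keys)
    for i in range(n):
        for j in range(i + 1, n):
            ka, kb = keys[i], keys[j]
            d = np.linalg.norm(coords[i] - coords[j])
            if ka[0] == kb[0]:
                if (
                    abs(seq_pos[ka] - seq_pos[kb]) > MIN_SEQ_SEPARATION
                    and d < CUTOFFS_NM["intrapeptide"]
                ):
                    found.add((ka, kb, "intrapeptide"))
            else:
                if d < CUTOFFS_NM["interpeptide"]:
                    found.add((ka, kb, "interpeptide"))
                if (
                    protofilament_of.get(ka[0]) != protofilament_of.get(kb[0])
                    and d < CUTOFFS_NM["interprotofilament"]
                ):
                    found.add((ka, kb, "interprotofilament"))
    return found


def two_sphere_area(r_ext_a, d):
    """Total accessible area of two equal fused spheres (closed form)."""
    if d >= 2 * r_ext_a:
        return 2 * 4 * np.pi * r_ext_a**2
    cap_h = r_ext_a - d / 2.0
    buried_per_sphere = 2 * np.pi * r_ext_a * cap_h
    return 2 * (4 * np.pi * r_ext_a**2 - buried_per_sphere)
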