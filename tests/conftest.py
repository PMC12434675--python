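"""Shared fixtures: built assemblies and small geometric test structures."""

from __future__ import annotations

import math
from types import SimpleNamespace

import numpy as np
import pytest

from crossbeta.fibril_model import build_assembly_map
from crossbeta.structure_io import Structure
from crossbeta.synthetic_fibril import BuilderParams, build_fibril


@pytest.fixture(scope="session")
def phf_structure():
    return build_fibril(BuilderParams(topology="phf"))


@pytest.fixture(scope="session")
def sf_structure():
    return build_fibril(BuilderParams(topology="sf"))


@pytest.fixture(scope="session")
def phf_assembly(phf_structure):
    return build_assembly_map(phf_structure)


@pytest.fixture(scope="session")
def sf_assembly(sf_structure):
    return build_assembly_map(sf_structure)


def make_structure(records, coords):
    """Structure from (name, element, resnum, resname, chain) records."""
    return Structure(
        atom_names=np.array([r[0] for r in records], dtype=object),
        elements=np.array([r[1] for r in records], dtype=object),
        res_numbers=np.array([r[2] for r in records], dtype=int),
        res_names=np.array([r[3] for r in records], dtype=object),
        chain_ids_per_atom=np.array([r[4] for r in records], dtype=object),
        coords_nm=np.asarray(coords, dtype=float),
    )


def ca_only_structure(chain_coords):
    """Calpha-only structure from {chain: (n_res, 3) array} (nm)."""
    records, coords = [], []
    for chain, arr in chain_coords.items():
        for i, xyz in enumerate(arr):
            records.append(("CA", "C", 304 + i, "GLY", chain))
            coords.append(xyz)
    return make_structure(records, coords)


def toy_assembly_map(protofilament_of):
    """Duck-typed stand-in for AssemblyMap in contact tests."""
    return SimpleNamespace(protofilament_of=dict(protofilament_of))


def build_dihedral_chain(phi, psi, n_res, omega=180.0):
    """Ideal backbone (N, CA, C, O arrays, nm) at fixed phi/psi."""
    from crossbeta.synthetic_fibril import (
        _A_C_N_CA, _A_CA_C_N, _A_N_CA_C, _B_C_N, _B_C_O, _B_CA_C, _B_N_CA,
        _nerf,
    )

    n_atoms = [np.zeros(3)]
    ca_atoms = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = math.radians(180.0 - _A_N_CA_C)
    c_atoms = [ca_atoms[0] + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])]
    for _ in range(1, n_res):
        n_i = _nerf(n_atoms[-1], ca_atoms[-1], c_atoms[-1], _B_C_N, _A_CA_C_N, psi)
        ca_i = _nerf(ca_atoms[-1], c_atoms[-1], n_i, _B_N_CA, _A_C_N_CA, omega)
        c_i = _nerf(c_atoms[-1], n_i, ca_i, _B_CA_C, _A_N_CA_C, phi)
        n_atoms.append(n_i)
        ca_atoms.append(ca_i)
        c_atoms.append(c_i)
    n_arr, ca_arr, c_arr = map(np.array, (n_atoms, ca_atoms, c_atoms))
    o_arr = np.zeros_like(c_arr)
    for i in range(n_res):
        d1 = c_arr[i] - ca_arr[i]
        d1 /= np.linalg.norm(d1)
        if i + 1 < n_res:
            d2 = c_arr[i] - n_arr[i + 1]
            d2 /= np.linalg.norm(d2)
            d = d1 + d2
            d /= np.linalg.norm(d)
        else:
            d = d1
        o_arr[i] = c_arr[i] + _B_C_O * d
    return n_arr, ca_arr, c_arr, o_arr


def backbone_structure(n_arr, ca_arr, c_arr, o_arr, chain="A", resname="ALA"):
    records, coords = [], []
    for i in range(len(n_arr)):
        for name, el, arr in (
            ("N", "N", n_arr), ("CA", "C", ca_arr),
            ("C", "C", c_arr), ("O", "O", o_arr),
        ):
            records.append((name, el, i + 1, resname, chain))
            coords.append(arr[i])
    return make_structure(records, coords)
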