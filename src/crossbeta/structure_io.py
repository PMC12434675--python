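"""PDB structure/trajectory I/O with nm unit convention.

Coordinates are Angstrom in PDB files and nanometre everywhere inside
the package; conversion happens only here.  Multi-model PDB is the
trajectory interchange format (frame times come from the caller, the
format itself carries none).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Structure",
    "Trajectory",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "PDBParseError",
]

NM_PER_ANGSTROM = 0.1
ANGSTROM_PER_NM = 10.0

_WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP3"}


class PDBParseError(ValueError):
    """Raised when a PDB file violates the subset of the format we read."""


@dataclass
class Structure:
    """One frame of an assembly as parallel per-atom arrays (nm)."""

    atom_names: np.ndarray          # str
    elements: np.ndarray            # str
    res_numbers: np.ndarray         # int
    res_names: np.ndarray           # str (3-letter)
    chain_ids_per_atom: np.ndarray  # str
    coords_nm: np.ndarray           # (n_atoms, 3) float
    title: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        self.coords_nm = np.asarray(self.coords_nm, dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(self.coords_nm)):
            raise ValueError("non-finite coordinates in structure")
        keys = list(
            zip(self.chain_ids_per_atom, self.res_numbers, self.atom_names)
        )
        if len(set(keys)) != n:
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise ValueError(
                        f"duplicate atom record (chain, residue, atom) = {k}"
                    )
                seen.add(k)

    def __len__(self) -> int:
        return len(self.atom_names)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def chain_ids(self) -> List[str]:
        """Unique chain ids in file order."""
        seen: Dict[str, None] = {}
        for c in self.chain_ids_per_atom:
            seen.setdefault(c, None)
        return list(seen)

    def residue_numbers(self, chain_id: str) -> List[int]:
        mask = self.chain_ids_per_atom == chain_id
        seen: Dict[int, None] = {}
        for r in self.res_numbers[mask]:
            seen.setdefault(int(r), None)
        return list(seen)

    def residue_count(self, chain_id: str) -> int:
        return len(self.residue_numbers(chain_id))

    def select(
        self,
        atom_name: Optional[str] = None,
        chain_id: Optional[str | Sequence[str]] = None,
        res_numbers: Optional[Iterable[int]] = None,
    ) -> np.ndarray:
        """Indices of atoms matching all given criteria, in file order."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if atom_name is not None:
            mask &= self.atom_names == atom_name
        if chain_id is not None:
            if isinstance(chain_id, str):
                mask &= self.chain_ids_per_atom == chain_id
            else:
                mask &= np.isin(self.chain_ids_per_atom, list(chain_id))
        if res_numbers is not None:
            mask &= np.isin(self.res_numbers, list(res_numbers))
        return np.flatnonzero(mask)

    def coords(self, **kwargs) -> np.ndarray:
        """Coordinates (nm) of the atoms selected by :meth:`select`."""
        return self.coords_nm[self.select(**kwargs)]

    def atom_index(self, chain_id: str, res_number: int, atom_name: str) -> int:
        idx = self.select(
            atom_name=atom_name, chain_id=chain_id, res_numbers=[res_number]
        )
        if len(idx) == 0:
            raise KeyError(
                f"no atom {atom_name!r} in chain {chain_id!r} residue {res_number}"
            )
        return int(idx[0])

    def subset(self, indices: np.ndarray) -> "Structure":
        indices = np.asarray(indices)
        return Structure(
            atom_names=self.atom_names[indices],
            elements=self.elements[indices],
            res_numbers=self.res_numbers[indices],
            res_names=self.res_names[indices],
            chain_ids_per_atom=self.chain_ids_per_atom[indices],
            coords_nm=self.coords_nm[indices],
            title=self.title,
            source=self.source,
        )

    def subset_chains(self, chains: Sequence[str]) -> "Structure":
        return self.subset(self.select(chain_id=list(chains)))

    def with_coords(self, coords_nm: np.ndarray) -> "Structure":
        return Structure(
            atom_names=self.atom_names,
            elements=self.elements,
            res_numbers=self.res_numbers,
            res_names=self.res_names,
            chain_ids_per_atom=self.chain_ids_per_atom,
            coords_nm=np.asarray(coords_nm, dtype=float),
            title=self.title,
            source=self.source,
        )


@dataclass
class Trajectory:
    """Frames sharing one topology; coordinates nm, times ns."""

    topology: Structure
    frames_nm: np.ndarray  # (n_frames, n_atoms, 3)
    times_ns: np.ndarray   # (n_frames,)

    def __post_init__(self) -> None:
        self.frames_nm = np.asarray(self.frames_nm, dtype=float)
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        if self.frames_nm.ndim != 3 or self.frames_nm.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames_nm.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames carry {self.frames_nm.shape[1]} atoms, topology "
                f"{self.topology.n_atoms}"
            )
        if len(self.times_ns) != len(self.frames_nm):
            raise ValueError("times and frames length mismatch")
        if len(self.times_ns) > 1 and not np.all(np.diff(self.times_ns) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames_nm)

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames_nm[i])


def _parse_atom_line(line: str, lineno: int) -> Tuple:
    try:
        name = line[12:16].strip()
        altloc = line[16].strip()
        res_name = line[17:20].strip()
        chain = line[21].strip() or "A"
        res_number = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_str = line[54:60].strip()
        occupancy = float(occ_str) if occ_str else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(
            f"malformed ATOM/HETATM record at line {lineno}: {exc}"
        ) from exc
    if not element:
        element = _guess_element(name)
    return name, altloc, res_name, chain, res_number, (x, y, z), occupancy, element


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    if not stripped:
        return ""
    if stripped[0].isdigit():  # e.g. 1HB
        stripped = stripped.lstrip("0123456789")
    return stripped[0].upper()


def _records_to_structure(
    records: List[Tuple], title: str, source: str
) -> Structure:
    # resolve altlocs: keep highest occupancy per (chain, resnum, name)
    best: Dict[Tuple[str, int, str], Tuple[float, int]] = {}
    for i, rec in enumerate(records):
        name, _altloc, _resn, chain, resnum, _xyz, occ, _el = rec
        key = (chain, resnum, name)
        if key not in best or occ > best[key][0]:
            best[key] = (occ, i)
    keep = sorted(i for _occ, i in best.values())
    recs = [records[i] for i in keep]
    return Structure(
        atom_names=np.array([r[0] for r in recs], dtype=object),
        elements=np.array([r[7] for r in recs], dtype=object),
        res_numbers=np.array([r[4] for r in recs], dtype=int),
        res_names=np.array([r[2] for r in recs], dtype=object),
        chain_ids_per_atom=np.array([r[3] for r in recs], dtype=object),
        coords_nm=np.array([r[5] for r in recs], dtype=float) * NM_PER_ANGSTROM,
        title=title,
        source=source,
    )


def read_structure(
    path: str | os.PathLike,
    keep_waters: bool = False,
    keep_hetero: bool = False,
) -> Structure:
    """Read the first model of a PDB file as a :class:`Structure`.

    Altloc is resolved to highest occupancy; waters and HETATM records
    are stripped unless requested.  Coordinates are converted to nm.
    """
    models = _read_models(path, keep_waters, keep_hetero, first_only=True)
    title, model_records = models[0]
    if not model_records:
        raise PDBParseError(f"no ATOM records found in {path}")
    return _records_to_structure(model_records, title, str(path))


def _read_models(
    path, keep_waters: bool, keep_hetero: bool, first_only: bool = False
) -> List[Tuple[str, List[Tuple]]]:
    title = ""
    models: List[List[Tuple]] = []
    current: List[Tuple] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "TITLE ":
                title = (title + " " + line[10:].strip()).strip()
            elif rec == "MODEL ":
                if in_model and current:
                    models.append(current)
                    current = []
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
                if first_only and models:
                    break
            elif rec in ("ATOM  ", "HETATM"):
                parsed = _parse_atom_line(line, lineno)
                res_name = parsed[2]
                if res_name in _WATER_RESNAMES and not keep_waters:
                    continue
                if rec == "HETATM" and not keep_hetero and res_name not in _WATER_RESNAMES:
                    continue
                current.append(parsed)
    if current:
        models.append(current)
    if not models:
        models = [[]]
    return [(title, m) for m in models]


def read_trajectory(
    path: str | os.PathLike,
    frame_interval_ns: float = 1.0,
    times_ns: Optional[Sequence[float]] = None,
) -> Trajectory:
    """Read a multi-model PDB file as a trajectory.

    MODEL/ENDMDL blocks must share one atom table.  PDB carries no time
    axis, so frame times come from ``times_ns`` or a uniform
    ``frame_interval_ns`` stride starting at 0.
    """
    models = _read_models(path, keep_waters=False, keep_hetero=False)
    models = [(t, m) for t, m in models if m]
    if not models:
        raise PDBParseError(f"no ATOM records found in {path}")
    title = models[0][0]
    first = _records_to_structure(models[0][1], title, str(path))
    n = first.n_atoms
    frames = np.empty((len(models), n, 3))
    frames[0] = first.coords_nm
    for mi, (_t, recs) in enumerate(models[1:], start=1):
        s = _records_to_structure(recs, title, str(path))
        if s.n_atoms != n:
            raise PDBParseError(
                f"model {mi + 1} has {s.n_atoms} atoms, model 1 has {n}"
            )
        frames[mi] = s.coords_nm
    if times_ns is None:
        times = np.arange(len(models)) * float(frame_interval_ns)
    else:
        times = np.asarray(times_ns, dtype=float)
    return Trajectory(topology=first, frames_nm=frames, times_ns=times)


def _format_atom_line(
    serial: int,
    name: str,
    res_name: str,
    chain: str,
    res_number: int,
    xyz_ang: np.ndarray,
    element: str,
) -> str:
    # PDB convention: 1/2-char element names start in column 14
    if len(name) < 4 and len(element) == 1:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    return (
        f"ATOM  {serial:>5d} {name_field} {res_name:>3s} {chain:1s}"
        f"{res_number:>4d}    "
        f"{xyz_ang[0]:8.3f}{xyz_ang[1]:8.3f}{xyz_ang[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def _write_model(fh, structure: Structure, coords_nm: np.ndarray) -> None:
    xyz = np.asarray(coords_nm) * ANGSTROM_PER_NM
    serial = 0
    prev_chain = None
    for i in range(structure.n_atoms):
        chain = structure.chain_ids_per_atom[i]
        if prev_chain is not None and chain != prev_chain:
            fh.write("TER\n")
        prev_chain = chain
        serial += 1
        fh.write(
            _format_atom_line(
                min(serial, 99999),
                structure.atom_names[i],
                structure.res_names[i],
                chain,
                int(structure.res_numbers[i]),
                xyz[i],
                structure.elements[i],
            )
            + "\n"
        )
    fh.write("TER\n")


def write_structure(structure: Structure, path: str | os.PathLike) -> None:
    """Write a structure as a single-model PDB file (Angstrom)."""
    with open(path, "w") as fh:
        if structure.title:
            fh.write(f"TITLE     {structure.title}\n")
        _write_model(fh, structure, structure.coords_nm)
        fh.write("END\n")


def write_trajectory(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write a trajectory as a multi-model PDB file."""
    with open(path, "w") as fh:
        if traj.topology.title:
            fh.write(f"TITLE     {traj.topology.title}\n")
        for i in range(traj.n_frames):
            fh.write(f"MODEL     {i + 1:>4d}\n")
            _write_model(fh, traj.topology, traj.frames_nm[i])
            fh.write("ENDMDL\n")
        fh.write("END\n")


def structure_to_pdb_string(structure: Structure) -> str:
    buf = io.StringIO()
    if structure.title:
        buf.write(f"TITLE     {structure.title}\n")
    _write_model(buf, structure, structure.coords_nm)
    buf.write("END\n")
    return buf.getvalue()
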