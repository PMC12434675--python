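import numpy as np
import pytest

from crossbeta.contacts import (
    CUTOFFS_NM,
    contact_fraction,
    per_residue_fraction,
    reference_contacts,
)
from crossbeta.structure_io import Trajectory

from .conftest import ca_only_structure, toy_assembly_map
from .oracles import brute_force_reference_records


def _two_chain(d_nm):
    """Two 5-residue chains along x, chain B offset by d_nm in y."""
    a = np.column_stack([np.arange(5) * 0.4, np.zeros(5), np.zeros(5)])
    b = a + np.array([0.0, d_nm, 0.0])
    return ca_only_structure({"A": a, "B": b})


class TestReferenceContacts:
    def test_far_chains_no_cross_contacts(self):
        s = _two_chain(5.0)
        amap = toy_assembly_map({"A": "a", "B": "b"})
        refs = reference_contacts(s, amap)
        assert not refs.by_class("interpeptide")
        assert not refs.by_class("interprotofilament")

    def test_sequence_separation_three_excluded(self):
        # residues 304 and 307 are 3 apart: never intrapeptide
        coords = np.zeros((5, 3))
        coords[:, 0] = [0.0, 0.30, 0.60, 0.20, 1.8]
        s = ca_only_structure({"A": coords})
        refs = reference_contacts(s, toy_assembly_map({"A": "a"}))
        pairs = {(r.a[1], r.b[1]) for r in refs.by_class("intrapeptide")}
        assert (304, 307) not in pairs
        assert (304, 308) not in pairs  # 1.8 nm apart anyway

    def test_interpeptide_cutoff_boundary(self):
        amap = toy_assembly_map({"A": "a", "B": "a"})
        near = reference_contacts(_two_chain(0.79), amap)
        far = reference_contacts(_two_chain(0.81), amap)
        assert len(near.by_class("interpeptide")) == 5
        assert len(far.by_class("interpeptide")) == 0

    def test_cross_protofilament_pair_in_both_classes(self):
        s = _two_chain(0.79)
        refs = reference_contacts(s, toy_assembly_map({"A": "a", "B": "b"}))
        inter = {(r.a, r.b) for r in refs.by_class("interpeptide")}
        cross = {(r.a, r.b) for r in refs.by_class("interprotofilament")}
        assert inter <= cross  # within 0.8 implies within 1.0

    def test_missing_calpha_rejected(self, phf_structure):
        no_ca = phf_structure.subset(
            np.flatnonzero(
                ~(
                    (phf_structure.atom_names == "CA")
                    & (phf_structure.res_numbers == 310)
                    & (phf_structure.chain_ids_per_atom == "A")
                )
            )
        )
        amap = toy_assembly_map({c: "a" for c in "ABCDE"} | {c: "b" for c in "FGHIJ"})
        with pytest.raises(ValueError, match="missing a Calpha"):
            reference_contacts(no_ca, amap)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        # random 20-residue toy assembly: 4 chains x 5 residues
        chains = {
            c: rng.uniform(0, 1.6, size=(5, 3)) for c in "ABCD"
        }
        s = ca_only_structure(chains)
        pf = {"A": "a", "B": "a", "C": "b", "D": "b"}
        refs = reference_contacts(s, toy_assembly_map(pf))
        keys, coords = [], []
        for c in "ABCD":
            for i in range(5):
                keys.append((c, 304 + i))
                coords.append(chains[c][i])
        seq_pos = {(c, 304 + i): i for c in "ABCD" for i in range(5)}
        expected = brute_force_reference_records(
            np.array(coords), keys, pf, seq_pos
        )
        got = {
            (r.a, r.b, r.contact_class) for r in refs.records
        }
        norm = lambda s: {(min(a, b), max(a, b), c) for a, b, c in s}
        assert norm(got) == norm(expected)

    def test_rotation_invariant_counts(self, phf_structure, phf_assembly):
        refs = reference_contacts(phf_structure, phf_assembly)
        theta = 1.0
        rot = np.array([
            [np.cos(theta), 0, np.sin(theta)],
            [0, 1, 0],
            [-np.sin(theta), 0, np.cos(theta)],
        ])
        moved = phf_structure.with_coords(
            phf_structure.coords_nm @ rot.T + 2.0
        )
        refs2 = reference_contacts(moved, phf_assembly)
        for cls in CUTOFFS_NM:
            assert len(refs.by_class(cls)) == len(refs2.by_class(cls))


class TestContactFraction:
    def _traj(self, structure, frames):
        return Trajectory(
            structure, np.array(frames), np.arange(len(frames), dtype=float)
        )

    def test_reference_frame_is_one(self, phf_structure, phf_assembly):
        refs = reference_contacts(phf_structure, phf_assembly)
        traj = self._traj(phf_structure, [phf_structure.coords_nm])
        out = contact_fraction(traj, refs)
        for cls, series in out.items():
            assert series[0] == pytest.approx(1.0)

    def test_separation_event(self, phf_structure, phf_assembly):
        refs = reference_contacts(phf_structure, phf_assembly)
        b_idx = phf_structure.select(chain_id=phf_assembly.chains_of("b"))
        frames = [phf_structure.coords_nm.copy() for _ in range(4)]
        for f in (2, 3):
            frames[f][b_idx] += np.array([0.0, -5.0, 0.0])
        out = contact_fraction(self._traj(phf_structure, frames), refs)
        np.testing.assert_allclose(
            out["interprotofilament"], [1.0, 1.0, 0.0, 0.0]
        )

    def test_monotone_under_rigid_separation(self, phf_structure, phf_assembly):
        refs = reference_contacts(phf_structure, phf_assembly)
        b_idx = phf_structure.select(chain_id=phf_assembly.chains_of("b"))
        frames = []
        for step in np.linspace(0, 1.2, 6):
            f = phf_structure.coords_nm.copy()
            f[b_idx] += np.array([0.0, -step, 0.0])
            frames.append(f)
        out = contact_fraction(self._traj(phf_structure, frames), refs)
        series = out["interprotofilament"]
        assert np.all(np.diff(series) <= 1e-12)

    def test_matches_brute_force_per_frame(self):
        rng = np.random.default_rng(3)
        chains = {c: rng.uniform(0, 1.5, size=(5, 3)) for c in "ABCD"}
        s = ca_only_structure(chains)
        pf = {"A": "a", "B": "a", "C": "b", "D": "b"}
        refs = reference_contacts(s, toy_assembly_map(pf))
        frames = [
            s.coords_nm + rng.normal(scale=0.15, size=s.coords_nm.shape)
            for _ in range(5)
        ]
        out = contact_fraction(self._traj(s, frames), refs)
        from .oracles import brute_force_contact_fraction

        for cls, series in out.items():
            for fi, frame in enumerate(frames):
                expected = brute_force_contact_fraction(
                    frame[refs.ca_indices], refs.residue_keys, refs, cls
                )
                assert series[fi] == expected  # exact, same arithmetic class

    def test_missing_class_reported_absent(self):
        s = _two_chain(5.0)
        refs = reference_contacts(s, toy_assembly_map({"A": "a", "B": "b"}))
        traj = self._traj(s, [s.coords_nm])
        out = contact_fraction(traj, refs)
        assert "interprotofilament" not in out
        assert "interpeptide" not in out

    def test_unknown_class_rejected(self, phf_structure, phf_assembly):
        refs = reference_contacts(phf_structure, phf_assembly)
        traj = self._traj(phf_structure, [phf_structure.coords_nm])
        with pytest.raises(ValueError, match="unknown contact class"):
            contact_fraction(traj, refs, classes=["sidechain"])


class TestPerResidueFraction:
    def test_reference_frame_all_ones(self, phf_structure, phf_assembly):
        refs = reference_contacts(phf_structure, phf_assembly)
        traj = Trajectory(
            phf_structure, phf_structure.coords_nm[None], np.zeros(1)
        )
        keys, matrix = per_residue_fraction(traj, refs, "interpeptide")
        np.testing.assert_allclose(matrix[0], np.ones(len(keys)))

    def test_any_contact_mode_upper_bounds_average(
        self, phf_structure, phf_assembly
    ):
        refs = reference_contacts(phf_structure, phf_assembly)
        rng = np.random.default_rng(0)
        frames = [
            phf_structure.coords_nm
            + rng.normal(scale=0.1, size=phf_structure.coords_nm.shape)
            for _ in range(3)
        ]
        traj = Trajectory(phf_structure, np.array(frames), np.arange(3.0))
        _, avg = per_residue_fraction(traj, refs, "interpeptide")
        _, any_ = per_residue_fraction(
            traj, refs, "interpeptide", mode="any_contact"
        )
        assert np.all(any_ + 1e-12 >= avg)
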