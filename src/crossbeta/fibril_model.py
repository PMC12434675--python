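"""Domain model for the tau fibril decamer.

Chain/protofilament bookkeeping, the 77-residue core peptide with its
named segments, and per-residue formal-charge assignment.  Residue
numbers use the tau (304-based) convention throughout; chain-local
indices are never exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "TAU_CORE_SEQUENCE",
    "TAU_FIRST_RESIDUE",
    "TAU_SEGMENTS",
    "AssemblyMap",
    "PeptideSpec",
    "assign_charges",
    "charge_of",
    "build_assembly_map",
    "tau_core_spec",
]

#: 77-residue fibrillar core of tau (residues 304-380, tau numbering).
TAU_CORE_SEQUENCE = (
    "GSVQIVYKPVDLSKVTSKCGSLGNIHHKPGGGQVEVKSEKLDFKDRVQSKIGSLDNITHVPGGGNKKIETHKLTFRE"
)
TAU_FIRST_RESIDUE = 304

#: Named segments as inclusive residue-number ranges (tau numbering).
TAU_SEGMENTS: Dict[str, Tuple[int, int]] = {
    "PHF6": (306, 311),   # VQIVYK
    "PAM4": (350, 362),   # VQSKIGSLDNITH
    "turn": (340, 350),   # KSEKLDFKDRV, apex of the C-shape
}

_AA_CODES = set("ACDEFGHIKLMNPQRSTVWY")
_POSITIVE = {"K", "R"}
_NEGATIVE = {"D", "E"}


def charge_of(residue: str) -> int:
    """Formal side-chain charge of a one-letter residue code at neutral pH.

    K/R -> +1, D/E -> -1, everything else (including H) -> 0.
    """
    if residue in _POSITIVE:
        return 1
    if residue in _NEGATIVE:
        return -1
    return 0


def assign_charges(sequence: str) -> List[int]:
    """Per-residue formal charges for an amino-acid sequence.

    Parameters
    ----------
    sequence : str
        One-letter codes; only the 20 standard residues are accepted.

    Returns
    -------
    list of int
        Same length as ``sequence``, values in {-1, 0, +1}.

    Raises
    ------
    ValueError
        If the sequence contains a non-standard code; the message names
        the offending position (0-based).
    """
    for i, aa in enumerate(sequence):
        if aa not in _AA_CODES:
            raise ValueError(
                f"unknown residue code {aa!r} at position {i} of sequence"
            )
    return [charge_of(aa) for aa in sequence]


@dataclass(frozen=True)
class PeptideSpec:
    """Sequence and segment bookkeeping for one peptide chain."""

    sequence: str
    first_residue_number: int
    named_segments: Mapping[str, Tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assign_charges(self.sequence)  # validates residue codes
        last = self.last_residue_number
        for name, (lo, hi) in self.named_segments.items():
            if not (self.first_residue_number <= lo <= hi <= last):
                raise ValueError(
                    f"segment {name!r} range {lo}-{hi} outside peptide "
                    f"{self.first_residue_number}-{last}"
                )

    @property
    def last_residue_number(self) -> int:
        return self.first_residue_number + len(self.sequence) - 1

    @property
    def residue_numbers(self) -> List[int]:
        return list(
            range(self.first_residue_number, self.last_residue_number + 1)
        )

    def residue_name(self, number: int) -> str:
        """One-letter code at a residue number."""
        idx = number - self.first_residue_number
        if not 0 <= idx < len(self.sequence):
            raise KeyError(f"residue number {number} outside peptide range")
        return self.sequence[idx]

    def segment_residues(self, name: str) -> List[int]:
        """Inclusive residue-number list of a registered named segment."""
        if name not in self.named_segments:
            raise KeyError(
                f"unknown segment {name!r}; registered: "
                f"{sorted(self.named_segments)}"
            )
        lo, hi = self.named_segments[name]
        return list(range(lo, hi + 1))

    def segment_sequence(self, name: str) -> str:
        lo, hi = self.named_segments[name]
        i = lo - self.first_residue_number
        return self.sequence[i : i + (hi - lo + 1)]

    def charges(self) -> List[int]:
        return assign_charges(self.sequence)


def tau_core_spec() -> PeptideSpec:
    """The packaged tau fibrillar-core peptide (G304-E380)."""
    return PeptideSpec(
        sequence=TAU_CORE_SEQUENCE,
        first_residue_number=TAU_FIRST_RESIDUE,
        named_segments=dict(TAU_SEGMENTS),
    )


@dataclass(frozen=True)
class AssemblyMap:
    """Chain -> (protofilament, stack index) bookkeeping for the decamer.

    Two protofilaments labelled ``a`` and ``b``, five chains each,
    stack indices 1..5 along the fibril axis.  The central chains are
    the stack-index-3 members (``3a``/``3b``).  A single-protofilament
    (pentamer) map contains only protofilament ``a``.
    """

    chain_ids: Tuple[str, ...]
    protofilament_of: Mapping[str, str]
    stack_index_of: Mapping[str, int]

    def __post_init__(self) -> None:
        pf_chains: Dict[str, List[str]] = {}
        for cid in self.chain_ids:
            pf = self.protofilament_of[cid]
            if pf not in ("a", "b"):
                raise ValueError(f"protofilament label {pf!r} not in {{a, b}}")
            pf_chains.setdefault(pf, []).append(cid)
        if set(pf_chains) not in ({"a"}, {"a", "b"}):
            raise ValueError("protofilaments must be 'a' or 'a'+'b'")
        for pf, chains in pf_chains.items():
            if len(chains) != 5:
                raise ValueError(
                    f"protofilament {pf!r} has {len(chains)} chains, need 5"
                )
            idx = sorted(self.stack_index_of[c] for c in chains)
            if idx != [1, 2, 3, 4, 5]:
                raise ValueError(
                    f"protofilament {pf!r} stack indices {idx} != [1..5]"
                )

    @property
    def protofilaments(self) -> Tuple[str, ...]:
        return tuple(sorted({self.protofilament_of[c] for c in self.chain_ids}))

    def chains_of(self, protofilament: str) -> List[str]:
        """Chain ids of one protofilament ordered by stack index."""
        chains = [
            c for c in self.chain_ids if self.protofilament_of[c] == protofilament
        ]
        return sorted(chains, key=lambda c: self.stack_index_of[c])

    @property
    def central_chains(self) -> Tuple[str, ...]:
        """Stack-index-3 chain of each protofilament (``3a``, ``3b``)."""
        return tuple(
            self.chains_of(pf)[2] for pf in self.protofilaments
        )

    def central_chain_of(self, chain_id: str) -> str:
        """Alignment anchor for a chain: centre of its own protofilament."""
        return self.chains_of(self.protofilament_of[chain_id])[2]

    def label(self, chain_id: str) -> str:
        """Conventional ``<stack><pf>`` label, e.g. ``3a``."""
        return f"{self.stack_index_of[chain_id]}{self.protofilament_of[chain_id]}"

    def chain_by_label(self, label: str) -> str:
        """Inverse of :meth:`label` (e.g. ``'1a'`` -> chain id)."""
        for cid in self.chain_ids:
            if self.label(cid) == label:
                return cid
        raise KeyError(f"no chain labelled {label!r}")


def build_assembly_map(
    structure,
    chain_order: Sequence[str] | None = None,
    single_protofilament: bool = False,
) -> AssemblyMap:
    """Derive the protofilament/stack bookkeeping from a structure.

    The first five chains (in ``chain_order``, defaulting to file order)
    form protofilament ``a``, the remaining five protofilament ``b``.
    Stack indices 1..5 are assigned by position along the mean fibril
    axis (dominant principal axis of the Calpha cloud), so the ordering
    is deterministic for any rigid placement of the assembly.

    Parameters
    ----------
    structure : Structure
        Parsed assembly with 10 chains (or 5 with
        ``single_protofilament=True``) of equal residue count.
    chain_order : sequence of str, optional
        Explicit chain ordering overriding file order (the deposited
        entries do not document the 1a..5a/1b..5b convention).
    single_protofilament : bool
        Accept a 5-chain pentamer as protofilament ``a`` alone.
    """
    file_chains = structure.chain_ids()
    if chain_order is None:
        chain_order = file_chains
    else:
        chain_order = list(chain_order)
        if sorted(chain_order) != sorted(file_chains):
            raise ValueError(
                f"chain_order {chain_order} does not match structure chains "
                f"{file_chains}"
            )
    expected = 5 if single_protofilament else 10
    if len(chain_order) != expected:
        raise ValueError(
            f"expected {expected} chains, found {len(chain_order)} "
            "(pass single_protofilament=True for a pentamer)"
        )
    counts = {c: structure.residue_count(c) for c in chain_order}
    if len(set(counts.values())) != 1:
        raise ValueError(f"chains differ in residue count: {counts}")

    groups = {"a": list(chain_order[:5])}
    if not single_protofilament:
        groups["b"] = list(chain_order[5:])

    # fibril axis = principal axis of the chain centroids within each
    # protofilament (the stacked chains are collinear along it), averaged
    # across protofilaments with consistent sign
    group_centroids = {
        pf: np.array([
            structure.coords(atom_name="CA", chain_id=c).mean(axis=0)
            for c in chains
        ])
        for pf, chains in groups.items()
    }
    axes = []
    for cent in group_centroids.values():
        ax = _principal_axis(cent)
        if axes and ax @ axes[0] < 0:
            ax = -ax
        axes.append(ax)
    axis = np.mean(axes, axis=0)
    axis /= np.linalg.norm(axis)

    proto: Dict[str, str] = {}
    stack: Dict[str, int] = {}
    ordered: List[str] = []
    for pf, chains in groups.items():
        centroids = {
            c: structure.coords(atom_name="CA", chain_id=c).mean(axis=0)
            for c in chains
        }
        ranked = sorted(chains, key=lambda c: float(centroids[c] @ axis))
        for i, c in enumerate(ranked, start=1):
            proto[c] = pf
            stack[c] = i
        ordered.extend(ranked)
    return AssemblyMap(
        chain_ids=tuple(ordered), protofilament_of=proto, stack_index_of=stack
    )


def load_assembly_config(path: str | None = None) -> Dict:
    """Assembly config (chain order, segments) from YAML.

    Without a path the packaged tau-decamer defaults are returned.  The
    deposited entries do not document the 1a..5a/1b..5b chain
    convention, so the chain order is always overridable here.
    """
    import yaml

    if path is None:
        from importlib import resources

        text = (
            resources.files("crossbeta") / "data" / "tau_decamer.yaml"
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    config = yaml.safe_load(text)
    if "chain_order" in config:
        config["chain_order"] = [str(c) for c in config["chain_order"]]
    if "segments" in config:
        config["segments"] = {
            str(k): (int(v[0]), int(v[1]))
            for k, v in config["segments"].items()
        }
    return config


def _principal_axis(points: np.ndarray) -> np.ndarray:
    centred = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    # fix sign for determinism: largest-magnitude component positive
    i = int(np.argmax(np.abs(axis)))
    return axis if axis[i] >= 0 else -axis
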