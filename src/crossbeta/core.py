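"""Core data model for cross-beta fibril assemblies.

A fibril is represented as a collection of :class:`Chain` objects grouped
into protofilaments, each chain carrying an integer *rung* index giving its
level along the fibril axis (the convention i, i±1, i±2 used to describe
staggered contacts between layers). Author residue numbering is preserved
throughout; nothing in the package renumbers sequentially.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .config import vdw_radius

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

#: 3-letter -> 1-letter code for the 20 standard residues
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class StructureError(ValueError):
    """Malformed or unusable structural input."""


class TopologyError(ValueError):
    """Chains cannot be partitioned into stacked protofilaments."""


class GeometryError(ValueError):
    """Geometric quantity is undefined for this input."""


@dataclass
class Atom:
    """One heavy atom. Coordinates in Å, PDB atom-name conventions."""

    serial: int
    name: str
    element: str
    coord: np.ndarray  # shape (3,)
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.name}: empty element symbol")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES

    @property
    def vdw_radius(self) -> float:
        return vdw_radius(self.element)


@dataclass
class Residue:
    """One residue, author (precursor) numbering, ordered heavy atoms."""

    seq_id: int
    name: str  # 3-letter code
    atoms: List[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> Optional[np.ndarray]:
        a = self.atom(name)
        return None if a is None else a.coord

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C"))


@dataclass
class Chain:
    chain_id: str
    residues: List[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.seq_id for r in self.residues]
        if ids and any(b <= a for a, b in zip(ids, ids[1:])):
            raise StructureError(f"chain {self.chain_id}: residue numbering not strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, seq_id: int) -> Optional[Residue]:
        for r in self.residues:
            if r.seq_id == seq_id:
                return r
        return None

    @property
    def seq_ids(self) -> List[int]:
        return [r.seq_id for r in self.residues]

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def atoms(self) -> Iterator[Atom]:
        for r in self.residues:
            yield from r.atoms

    def ca_coords(self, seq_ids: Optional[Sequence[int]] = None) -> np.ndarray:
        """Cα coordinates, optionally restricted to given residue numbers."""
        if seq_ids is None:
            pts = [r.coord("CA") for r in self.residues]
        else:
            wanted = set(seq_ids)
            pts = [r.coord("CA") for r in self.residues if r.seq_id in wanted]
        pts = [p for p in pts if p is not None]
        if not pts:
            return np.zeros((0, 3))
        return np.vstack(pts)

    def centroid(self) -> np.ndarray:
        ca = self.ca_coords()
        if len(ca) == 0:
            raise StructureError(f"chain {self.chain_id}: no CA atoms")
        return ca.mean(axis=0)


@dataclass
class FibrilAssembly:
    """Multi-chain fibril model with (optional) protofilament/rung topology.

    ``protofilament_of`` and ``rung_of`` are filled by
    :func:`crossbeta.topology.assign_topology`; ``axis_dir``/``axis_point``
    describe the fibril axis estimated alongside.
    """

    chains: List[Chain]
    protofilament_of: Dict[str, int] = field(default_factory=dict)
    rung_of: Dict[str, int] = field(default_factory=dict)
    symmetry: Optional[str] = None  # "C1" | "C2"
    axis_dir: Optional[np.ndarray] = None
    axis_point: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chains:
            raise StructureError("empty model: no polymer chains")
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise StructureError("duplicate chain identifiers")

    @property
    def chain_ids(self) -> List[str]:
        return [c.chain_id for c in self.chains]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    @property
    def has_topology(self) -> bool:
        return bool(self.protofilament_of) and bool(self.rung_of)

    def require_topology(self) -> None:
        if not self.has_topology:
            raise TopologyError("topology not assigned; run assign_topology first")

    @property
    def n_protofilaments(self) -> int:
        self.require_topology()
        return len(set(self.protofilament_of.values()))

    def protofilament_chains(self, index: int) -> List[Chain]:
        self.require_topology()
        return [c for c in self.chains if self.protofilament_of[c.chain_id] == index]

    def rungs_of_protofilament(self, index: int) -> Dict[int, Chain]:
        return {self.rung_of[c.chain_id]: c for c in self.protofilament_chains(index)}

    def interior_chain_ids(self) -> List[str]:
        """Chains with both axial neighbours present in their protofilament."""
        self.require_topology()
        out = []
        for p in sorted(set(self.protofilament_of.values())):
            rungs = self.rungs_of_protofilament(p)
            for r, c in sorted(rungs.items()):
                if (r - 1) in rungs and (r + 1) in rungs:
                    out.append(c.chain_id)
        return out

    def terminal_chain_id(self, protofilament: int = 0) -> str:
        """Chain at the highest rung of the given protofilament (fibril end)."""
        rungs = self.rungs_of_protofilament(protofilament)
        return rungs[max(rungs)].chain_id

    def subset(self, chain_ids: Sequence[str], keep_topology: bool = True) -> "FibrilAssembly":
        wanted = set(chain_ids)
        chains = [c for c in self.chains if c.chain_id in wanted]
        sub = FibrilAssembly(chains=chains, label=self.label)
        if keep_topology and self.has_topology:
            sub.protofilament_of = {k: v for k, v in self.protofilament_of.items() if k in wanted}
            sub.rung_of = {k: v for k, v in self.rung_of.items() if k in wanted}
            sub.axis_dir = None if self.axis_dir is None else self.axis_dir.copy()
            sub.axis_point = None if self.axis_point is None else self.axis_point.copy()
            sub.symmetry = self.symmetry
        return sub

    def all_atom_coords(self) -> np.ndarray:
        return np.vstack([a.coord for c in self.chains for a in c.atoms()])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "FibrilAssembly":
        """Rigidly transformed copy (x -> R x + t); topology maps copied as-is."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        chains = []
        for c in self.chains:
            residues = []
            for r in c.residues:
                atoms = [Atom(a.serial, a.name, a.element, R @ a.coord + t,
                              a.occupancy, a.bfactor) for a in r.atoms]
                residues.append(Residue(r.seq_id, r.name, atoms))
            chains.append(Chain(c.chain_id, residues))
        out = FibrilAssembly(chains=chains, label=self.label)
        out.protofilament_of = dict(self.protofilament_of)
        out.rung_of = dict(self.rung_of)
        out.symmetry = self.symmetry
        if self.axis_dir is not None:
            out.axis_dir = R @ self.axis_dir
        if self.axis_point is not None:
            out.axis_point = R @ self.axis_point + t
        return out


@dataclass
class SequenceRecord:
    """A named amino-acid sequence (1-letter codes, 20 standard + X)."""

    id: str
    sequence: str

    _ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        for i, ch in enumerate(self.sequence):
            if ch not in self._ALPHABET:
                raise ValueError(f"record {self.id!r}: illegal character {ch!r} at position {i + 1}")

    def __len__(self) -> int:
        return len(self.sequence)

    def region(self, start: int, end: int, numbering_offset: int = 0) -> "SequenceRecord":
        """Sub-record for positions start..end inclusive in (offset) numbering."""
        i0 = start - 1 - numbering_offset
        i1 = end - numbering_offset
        return SequenceRecord(f"{self.id}:{start}-{end}", self.sequence[max(i0, 0):i1])
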