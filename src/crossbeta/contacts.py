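"""Stabilizing contacts at fibril interfaces.

Three heavy-atom contact classes are detected — hydrogen bonds, ionic locks
(buried salt bridges) and hydrophobic contacts — and attributed to an
interface: ``intra_chain`` (within one chain, sequence separation > 2),
``intra_protomer`` (between chains of the same protofilament) or
``inter_protomer`` (between protofilaments). Each contact carries the rung
offset Δ = rung(partner) − rung(reference), the stagger bookkeeping used to
describe how one layer grips the layers above and below it.

Cutoffs are configuration keys with common heavy-atom defaults (H-bond
donor–acceptor 3.5 Å with a ≥90° donor-antecedent angle, ionic 4.0 Å,
hydrophobic carbon–carbon 4.5 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from ._geom import angle_deg
from .config import merged
from .core import FibrilAssembly, Residue, TopologyError
from .sasa import compute_sasa

AtomRef = Tuple[str, int, str]

# --- chemistry tables (heavy-atom, hydrogen-free models) -------------------

_CATION_ATOMS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
_ANION_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
_HYDROPHOBIC_RES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}
_TYR_RING = {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}

# side-chain donors with their antecedent heavy atom
_SC_DONORS = {
    ("SER", "OG"): "CB", ("THR", "OG1"): "CB", ("TYR", "OH"): "CZ",
    ("CYS", "SG"): "CB", ("TRP", "NE1"): "CD1",
    ("HIS", "ND1"): "CG", ("HIS", "NE2"): "CD2",
    ("ASN", "ND2"): "CG", ("GLN", "NE2"): "CD",
    ("LYS", "NZ"): "CE",
    ("ARG", "NE"): "CD", ("ARG", "NH1"): "CZ", ("ARG", "NH2"): "CZ",
}
_SC_ACCEPTORS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"), ("THR", "OG1"),
    ("TYR", "OH"), ("HIS", "ND1"), ("HIS", "NE2"),
}


@dataclass
class ContactRecord:
    kind: str                     # hbond | ionic_lock | hydrophobic
    atom_a: AtomRef               # reference-chain side
    atom_b: AtomRef               # partner side
    distance_A: float
    interface: str                # intra_chain | intra_protomer | inter_protomer
    rung_offset: int

    @property
    def residue_pair(self) -> Tuple[Tuple[str, int], Tuple[str, int]]:
        return ((self.atom_a[0], self.atom_a[1]), (self.atom_b[0], self.atom_b[1]))


@dataclass
class HydrophobicCluster:
    members: FrozenSet[Tuple[str, int]]
    edges: List[Tuple[Tuple[str, int], Tuple[str, int]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


def _is_donor(res: Residue, atom_name: str) -> Optional[str]:
    """Antecedent atom name if (residue, atom) can donate an implicit H."""
    if atom_name == "N" and res.name != "PRO":
        return "CA"
    return _SC_DONORS.get((res.name, atom_name))


def _is_acceptor(res: Residue, atom_name: str) -> bool:
    if atom_name in ("O", "OXT"):
        return True
    return (res.name, atom_name) in _SC_ACCEPTORS


def _is_hydrophobic_atom(res: Residue, atom_name: str) -> bool:
    if res.name == "TYR":
        return atom_name in _TYR_RING
    if res.name in _HYDROPHOBIC_RES:
        return atom_name.startswith("C") and atom_name not in ("C", "CA")
    return False


def _is_cation(res: Residue, atom_name: str) -> bool:
    return atom_name in _CATION_ATOMS.get(res.name, ())


def _is_anion(res: Residue, atom_name: str) -> bool:
    return atom_name == "OXT" or atom_name in _ANION_ATOMS.get(res.name, ())


def detect_contacts(assembly: FibrilAssembly, reference_chain: str,
                    config: Optional[dict] = None,
                    require_interior: bool = True) -> List[ContactRecord]:
    """All contacts between the reference chain and the rest of the assembly
    (plus long-range contacts within the reference chain itself).

    The reference chain should be an interior (rung 0) chain so that both
    axial neighbours are present; pass ``require_interior=False`` for small
    constructed fixtures. Same-chain pairs with sequence separation ≤ 2 are
    never interface contacts.
    """
    cfg = merged(config)["contacts"]
    assembly.require_topology()
    ref_pf = assembly.protofilament_of[reference_chain]
    ref_rung = assembly.rung_of[reference_chain]
    pf_rungs = {assembly.rung_of[c.chain_id]
                for c in assembly.protofilament_chains(ref_pf)}
    if require_interior and len(pf_rungs) > 1:
        if not {ref_rung - 1, ref_rung + 1} <= pf_rungs:
            raise TopologyError(
                f"chain {reference_chain} is terminal; use an interior (rung 0) chain")

    # flat atom table
    refs: List[AtomRef] = []
    coords: List[np.ndarray] = []
    residues: Dict[Tuple[str, int], Residue] = {}
    for c in assembly.chains:
        for r in c.residues:
            residues[(c.chain_id, r.seq_id)] = r
            for a in r.atoms:
                refs.append((c.chain_id, r.seq_id, a.name))
                coords.append(a.coord)
    coords = np.vstack(coords)
    tree = cKDTree(coords)
    max_cut = max(cfg["hbond_max_A"], cfg["ionic_max_A"], cfg["hydrophobic_max_A"])
    ref_idx = [i for i, k in enumerate(refs) if k[0] == reference_chain]

    out: List[ContactRecord] = []
    seen: Set[Tuple[str, AtomRef, AtomRef]] = set()
    for i in ref_idx:
        ca_id, ca_seq, ca_name = refs[i]
        res_a = residues[(ca_id, ca_seq)]
        for j in tree.query_ball_point(coords[i], max_cut):
            if j == i:
                continue
            cb_id, cb_seq, cb_name = refs[j]
            if cb_id == ca_id and abs(cb_seq - ca_seq) <= cfg["exclude_seq_sep"]:
                continue
            res_b = residues[(cb_id, cb_seq)]
            d = float(np.linalg.norm(coords[j] - coords[i]))
            if cb_id == ca_id:
                interface = "intra_chain"
            elif assembly.protofilament_of[cb_id] == ref_pf:
                interface = "intra_protomer"
            else:
                interface = "inter_protomer"
            rung_offset = assembly.rung_of[cb_id] - ref_rung

            def emit(kind: str) -> None:
                key_fwd = (kind, refs[i], refs[j])
                key_rev = (kind, refs[j], refs[i])
                if key_fwd in seen or (cb_id == ca_id and key_rev in seen):
                    return
                seen.add(key_fwd)
                out.append(ContactRecord(kind, refs[i], refs[j], d, interface, rung_offset))

            # ionic locks
            if d <= cfg["ionic_max_A"] and (
                    (_is_cation(res_a, ca_name) and _is_anion(res_b, cb_name))
                    or (_is_anion(res_a, ca_name) and _is_cation(res_b, cb_name))):
                emit("ionic_lock")
            # hydrophobic
            if d <= cfg["hydrophobic_max_A"] and _is_hydrophobic_atom(res_a, ca_name) \
                    and _is_hydrophobic_atom(res_b, cb_name):
                emit("hydrophobic")
            # hydrogen bonds (either direction), salt-bridge pairs not re-counted
            if d <= cfg["hbond_max_A"]:
                ionic_pair = ((_is_cation(res_a, ca_name) and _is_anion(res_b, cb_name))
                              or (_is_anion(res_a, ca_name) and _is_cation(res_b, cb_name)))
                if not ionic_pair:
                    for don_res, don_name, don_key, acc_res, acc_name, acc_coord in (
                            (res_a, ca_name, i, res_b, cb_name, coords[j]),
                            (res_b, cb_name, j, res_a, ca_name, coords[i])):
                        ante = _is_donor(don_res, don_name)
                        if ante is None:
                            continue
                        if not _is_acceptor(acc_res, acc_name):
                            continue
                        ante_coord = don_res.coord(ante)
                        if ante_coord is None:
                            continue
                        don_coord = coords[don_key]
                        if angle_deg(ante_coord, don_coord, acc_coord) >= cfg["donor_angle_min_deg"]:
                            emit("hbond")
                            break
    return out


def cluster_hydrophobics(contacts: Sequence[ContactRecord],
                         interface: Optional[str] = None,
                         config: Optional[dict] = None) -> List[HydrophobicCluster]:
    """Connected components of the residue-level hydrophobic contact graph.

    ``interface`` restricts edges to one class ("inter_protomer",
    "intra_protomer", "intra_chain") or the union "intra" (same-protofilament
    plus within-chain). Components smaller than ``contacts.min_cluster_size``
    residues are discarded.
    """
    cfg = merged(config)["contacts"]
    if interface == "intra":
        allowed = {"intra_protomer", "intra_chain"}
    elif interface is None:
        allowed = {"intra_protomer", "intra_chain", "inter_protomer"}
    else:
        allowed = {interface}
    edges: Set[Tuple[Tuple[str, int], Tuple[str, int]]] = set()
    nodes: Set[Tuple[str, int]] = set()
    for rec in contacts:
        if rec.kind != "hydrophobic" or rec.interface not in allowed:
            continue
        a, b = rec.residue_pair
        edges.add((a, b))
        nodes.update((a, b))
    adj: Dict[Tuple[str, int], Set[Tuple[str, int]]] = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    clusters: List[HydrophobicCluster] = []
    unvisited = set(nodes)
    while unvisited:
        start = min(unvisited)
        comp = {start}
        stack = [start]
        unvisited.discard(start)
        while stack:
            cur = stack.pop()
            for nxt in adj[cur]:
                if nxt in unvisited:
                    unvisited.discard(nxt)
                    comp.add(nxt)
                    stack.append(nxt)
        if len(comp) >= cfg["min_cluster_size"]:
            comp_edges = [(a, b) for a, b in edges if a in comp and b in comp]
            clusters.append(HydrophobicCluster(members=frozenset(comp), edges=comp_edges))
    clusters.sort(key=lambda c: sorted(c.members)[0])
    return clusters


def stagger_footprint(contacts: Sequence[ContactRecord]
                      ) -> Dict[str, Dict[int, int]]:
    """Contact counts by rung offset Δ for each interface class."""
    hist: Dict[str, Dict[int, int]] = {}
    for rec in contacts:
        hist.setdefault(rec.interface, {})
        hist[rec.interface][rec.rung_offset] = hist[rec.interface].get(rec.rung_offset, 0) + 1
    return hist


def interface_area(assembly: FibrilAssembly, interface: str = "inter_protomer",
                   config: Optional[dict] = None) -> float:
    """Buried interface area: half the SASA lost when the two sides separate.

    ``inter_protomer``: protofilament 0 vs protofilament 1.
    ``intra_protomer``: the rung-0 chain of protofilament 0 vs the other
    chains of the same protofilament.
    """
    assembly.require_topology()
    if interface == "inter_protomer":
        if assembly.n_protofilaments < 2:
            raise ValueError("inter-protomer interface needs two protofilaments")
        side_a = [c.chain_id for c in assembly.protofilament_chains(0)]
        side_b = [c.chain_id for c in assembly.protofilament_chains(1)]
    elif interface == "intra_protomer":
        rungs = assembly.rungs_of_protofilament(0)
        ref = rungs[min(rungs, key=abs)].chain_id
        side_a = [ref]
        side_b = [c.chain_id for c in assembly.protofilament_chains(0) if c.chain_id != ref]
        if not side_b:
            raise ValueError("intra-protomer interface needs >= 2 chains in protofilament 0")
    else:
        raise ValueError(f"undefined interface {interface!r}")
    both = assembly.subset(side_a + side_b)
    a_only = assembly.subset(side_a)
    b_only = assembly.subset(side_b)
    s_both = compute_sasa(both, "assembly", config=config).total
    s_a = compute_sasa(a_only, "assembly", config=config).total
    s_b = compute_sasa(b_only, "assembly", config=config).total
    return (s_a + s_b - s_both) / 2.0
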