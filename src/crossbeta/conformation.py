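"""Secondary structure, peptide-bond isomers and rigid superposition.

β-structure is assigned with the Kabsch–Sander electrostatic H-bond model:
amide hydrogens (absent from fibril models) are reconstructed geometrically,
the partial-charge interaction energy of each NH→CO pair is evaluated, and
pairs below the −0.5 kcal/mol cutoff define H-bonds from which β-bridges and
ladders are assembled. In a cross-β fibril these H-bonds run between rungs,
so the assignment needs the neighbouring chains present, not just the chain
being labelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from ._geom import dihedral_deg, kabsch
from .config import merged
from .core import FibrilAssembly, GeometryError, Residue

_KS_Q1Q2_F = 0.084 * 332.0  # kcal/mol·Å, Kabsch–Sander coupling constant


@dataclass
class SecondaryStructure:
    labels: Dict[int, str]                    # seq_id -> strand|turn|coil
    strands: List[Tuple[int, int]]            # inclusive residue ranges
    warnings: List[str] = field(default_factory=list)

    @property
    def n_strands(self) -> int:
        return len(self.strands)


@dataclass
class OmegaRecord:
    residue: int          # seq_id of the residue following the peptide bond
    residue_name: str
    omega_deg: float
    isomer: str           # cis | trans | twisted


@dataclass
class _BackboneUnit:
    chain_id: str
    seq_id: int
    index: int            # position within chain
    name: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: Optional[np.ndarray]
    h: Optional[np.ndarray]  # reconstructed amide H (None for Pro / chain start)


def _collect_backbone(assembly: FibrilAssembly) -> List[_BackboneUnit]:
    units: List[_BackboneUnit] = []
    for chain in assembly.chains:
        prev_c: Optional[np.ndarray] = None
        prev_seq: Optional[int] = None
        for idx, res in enumerate(chain.residues):
            n, ca, c = res.coord("N"), res.coord("CA"), res.coord("C")
            if n is None or ca is None or c is None:
                prev_c, prev_seq = None, None
                continue
            o = res.coord("O")
            h: Optional[np.ndarray] = None
            if (res.name != "PRO" and prev_c is not None
                    and prev_seq is not None and res.seq_id == prev_seq + 1):
                # H 1.0 Å from N, opposing the bisector of C(i-1)-N-CA
                d1 = n - prev_c
                d2 = n - ca
                d1 /= np.linalg.norm(d1)
                d2 /= np.linalg.norm(d2)
                bis = d1 + d2
                nb = np.linalg.norm(bis)
                if nb > 1e-6:
                    h = n + bis / nb
            units.append(_BackboneUnit(chain.chain_id, res.seq_id, idx, res.name,
                                       n, ca, c, o, h))
            prev_c, prev_seq = c, res.seq_id
    return units


def _ks_hbonds(units: List[_BackboneUnit], energy_cutoff: float) -> Set[Tuple[int, int]]:
    """Set of (acceptor_index, donor_index) pairs with E < cutoff.

    Indices refer to positions in ``units``; acceptor contributes CO, donor NH.
    """
    cas = np.vstack([u.ca for u in units])
    tree = cKDTree(cas)
    pairs = tree.query_pairs(9.0)
    bonds: Set[Tuple[int, int]] = set()

    def energy(acc: _BackboneUnit, don: _BackboneUnit) -> float:
        if acc.o is None or don.h is None:
            return 0.0
        r_on = np.linalg.norm(acc.o - don.n)
        r_ch = np.linalg.norm(acc.c - don.h)
        r_oh = np.linalg.norm(acc.o - don.h)
        r_cn = np.linalg.norm(acc.c - don.n)
        if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clashing/malformed
            return 0.0
        return _KS_Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)

    for i, j in pairs:
        a, b = units[i], units[j]
        if a.chain_id == b.chain_id and abs(a.index - b.index) <= 1:
            continue  # covalently adjacent: the peptide bond itself
        if energy(a, b) < energy_cutoff:
            bonds.add((i, j))
        if energy(b, a) < energy_cutoff:
            bonds.add((j, i))
    return bonds


def assign_beta(assembly: FibrilAssembly, chain_id: str,
                config: Optional[dict] = None) -> SecondaryStructure:
    """β-strand assignment for one chain within its assembly context.

    Bridges follow the Kabsch–Sander definitions (parallel and antiparallel,
    partner residues in any chain, |Δseq| ≥ 3 within the same chain); ladders
    of at least two consecutive bridges mark residues as strand. Residues
    with an i→i+3..5 turn H-bond and no strand label are ``turn``; everything
    else is ``coil``. Residues missing backbone atoms fall back to coil with
    a warning.
    """
    cfg = merged(config)["conformation"]
    units = _collect_backbone(assembly)
    bonds = _ks_hbonds(units, cfg["hbond_energy_cutoff"])

    # lookup: (chain, index-in-chain) -> unit index
    pos: Dict[Tuple[str, int], int] = {(u.chain_id, u.index): k for k, u in enumerate(units)}

    def hb(a: Optional[int], b: Optional[int]) -> bool:
        return a is not None and b is not None and (a, b) in bonds

    def nb(k: Optional[int], step: int) -> Optional[int]:
        if k is None:
            return None
        u = units[k]
        return pos.get((u.chain_id, u.index + step))

    chain = assembly.chain(chain_id)
    warnings = [f"residue {r.seq_id}: incomplete backbone, labelled coil"
                for r in chain.residues if not r.has_backbone()]

    bridge_partner: Dict[int, List[int]] = {}
    n_units = len(units)
    my_units = [k for k, u in enumerate(units) if u.chain_id == chain_id]
    for i in my_units:
        for j in range(n_units):
            ui, uj = units[i], units[j]
            if ui.chain_id == uj.chain_id and abs(ui.index - uj.index) < 3:
                continue
            im1, ip1 = nb(i, -1), nb(i, +1)
            jm1, jp1 = nb(j, -1), nb(j, +1)
            parallel = (hb(im1, j) and hb(j, ip1)) or (hb(jm1, i) and hb(i, jp1))
            anti = (hb(i, j) and hb(j, i)) or (hb(im1, jp1) and hb(jm1, ip1))
            if parallel or anti:
                bridge_partner.setdefault(i, []).append(j)

    # ladders: bridge at i and at i+1 (with partners that are sequence
    # neighbours of each other) -> strand; lone bridges are left out
    strand_units: Set[int] = set()
    for i in bridge_partner:
        ip1 = nb(i, +1)
        if ip1 in bridge_partner:
            for j in bridge_partner[i]:
                jn = {nb(j, +1), nb(j, -1)}
                if jn & set(bridge_partner.get(ip1, [])):
                    strand_units.add(i)
                    strand_units.add(ip1)

    labels: Dict[int, str] = {}
    strand_seq: Set[int] = {units[k].seq_id for k in strand_units}
    for res in chain.residues:
        labels[res.seq_id] = "strand" if res.seq_id in strand_seq else "coil"
    # turns: i -> i+3..5 H-bond within the chain
    for i in my_units:
        for step in (3, 4, 5):
            j = pos.get((chain_id, units[i].index + step))
            if j is not None and (i, j) in bonds:
                for k in range(units[i].index + 1, units[i].index + step):
                    kk = pos.get((chain_id, k))
                    if kk is not None and labels.get(units[kk].seq_id) == "coil":
                        labels[units[kk].seq_id] = "turn"

    strands: List[Tuple[int, int]] = []
    run: List[int] = []
    for res in chain.residues:
        if labels.get(res.seq_id) == "strand" and (not run or res.seq_id == run[-1] + 1):
            run.append(res.seq_id)
        else:
            if len(run) >= 2:
                strands.append((run[0], run[-1]))
            run = [res.seq_id] if labels.get(res.seq_id) == "strand" else []
    if len(run) >= 2:
        strands.append((run[0], run[-1]))
    return SecondaryStructure(labels=labels, strands=strands, warnings=warnings)


def classify_omega(assembly: FibrilAssembly, chain_id: str,
                   config: Optional[dict] = None) -> List[OmegaRecord]:
    """ω dihedral (CA–C–N–CA) and cis/trans/twisted class per peptide bond.

    cis: |ω| ≤ 30°; trans: |ω| ≥ 150°; twisted otherwise. Bonds across chain
    breaks (consecutive Cα further than the configured limit) are skipped.
    """
    cfg = merged(config)["conformation"]
    chain = assembly.chain(chain_id)
    records: List[OmegaRecord] = []
    for prev, res in zip(chain.residues, chain.residues[1:]):
        needed = (prev.coord("CA"), prev.coord("C"), res.coord("N"), res.coord("CA"))
        if any(x is None for x in needed):
            continue
        if np.linalg.norm(needed[3] - needed[0]) > cfg["chain_break_ca_dist"]:
            continue
        omega = dihedral_deg(*needed)
        if abs(omega) <= cfg["cis_max_abs_omega"]:
            isomer = "cis"
        elif abs(omega) >= cfg["trans_min_abs_omega"]:
            isomer = "trans"
        else:
            isomer = "twisted"
        records.append(OmegaRecord(residue=res.seq_id, residue_name=res.name,
                                   omega_deg=omega, isomer=isomer))
    return records


def superpose(mobile: np.ndarray, target: np.ndarray
              ) -> Tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition (proper rotation) of paired Cα sets.

    Returns (R, t, rmsd) with R @ mobile + t best matching target.
    """
    return kabsch(mobile, target)


def superpose_chains(assembly_a: FibrilAssembly, chain_a: str,
                     assembly_b: FibrilAssembly, chain_b: str,
                     residue_range: Optional[Tuple[int, int]] = None,
                     pairing: Optional[Sequence[Tuple[int, int]]] = None) -> float:
    """Cα superposition RMSD between two chains.

    Residues are paired by an explicit ``pairing`` of (seq_id_a, seq_id_b)
    tuples — e.g. derived from a sequence alignment for cross-species
    comparisons — or, when omitted, by shared author numbering, optionally
    restricted to ``residue_range`` (inclusive, numbering of chain a).
    """
    ca_chain = assembly_a.chain(chain_a)
    cb_chain = assembly_b.chain(chain_b)
    if pairing is None:
        ids_b = set(cb_chain.seq_ids)
        pairing = [(s, s) for s in ca_chain.seq_ids if s in ids_b]
    if residue_range is not None:
        lo, hi = residue_range
        pairing = [(sa, sb) for sa, sb in pairing if lo <= sa <= hi]
    P, Q = [], []
    for sa, sb in pairing:
        pa = ca_chain.residue(sa)
        pb = cb_chain.residue(sb)
        if pa is None or pb is None:
            continue
        ca, cb = pa.coord("CA"), pb.coord("CA")
        if ca is None or cb is None:
            continue
        P.append(ca)
        Q.append(cb)
    if len(P) < 3:
        raise GeometryError("fewer than 3 paired CA atoms for superposition")
    _, _, rmsd = kabsch(np.asarray(P), np.asarray(Q))
    return rmsd
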