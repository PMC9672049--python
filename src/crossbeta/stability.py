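"""Solvation-free-energy estimates of fibril stability.

ΔG_sol of a chain is the atomic-solvation-parameter (ASP) energy of burying
surface on fibril formation:

    ΔG_sol = Σ_atoms σ(class) · [ASA_assembly − ASA_reference]
             + E_HB · n_buried_backbone_hbonds

with the five-class Eisenberg–McLachlan parameters (σ_C > 0: transferring
carbon surface out of water is favourable, so burying it gives a negative,
stabilizing contribution; burying charged N⁺/O⁻ surface costs energy). The
reference state is the same chain conformation extracted alone. Backbone
H-bonds detected by the Kabsch–Sander machinery whose partner residues are
both buried contribute E_HB each (default −0.6 kcal/mol, configurable).
Negative ΔG_sol = stabilizing; disease-associated amyloids typically fall
between −25 and −62 kcal/mol per molecule.

ΔG_diss is the energetic cost of removing the terminal (highest-rung) chain
from the fibril end: the same ASP + H-bond sum evaluated for the terminal
chain, sign-flipped so that a stable fibril has ΔG_diss > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import ASP_EISENBERG_MCLACHLAN, merged
from .core import FibrilAssembly, Residue, StructureError, TopologyError
from .sasa import AtomKey, compute_sasa
from .conformation import _collect_backbone, _ks_hbonds

_CHARGED_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_CHARGED_N = {("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"), ("LYS", "NZ")}


def asp_class(res_name: str, atom_name: str, element: str) -> str:
    """Five-class ASP assignment: C, N/O, O-, N+, S."""
    el = element.upper()
    if el == "S":
        return "S"
    if atom_name == "OXT" or (res_name, atom_name) in _CHARGED_O:
        return "O-"
    if (res_name, atom_name) in _CHARGED_N:
        return "N+"
    if el == "C":
        return "C"
    if el in ("N", "O"):
        return "N/O"
    raise KeyError(f"no ASP class for element {element!r} ({res_name} {atom_name})")


@dataclass
class EnergyReport:
    chain_id: str
    per_atom_dG: Dict[AtomKey, float]
    per_residue_dG: Dict[int, float]
    dG_sol_chain: float                 # kcal/mol, negative = stabilizing
    hbond_term: float                   # kcal/mol (E_HB x n_hbonds_buried)
    n_hbonds_buried: int
    asp_set_id: str
    dG_diss_terminal: Optional[float] = None
    warnings: List[str] = field(default_factory=list)


def _chain_solvation_terms(assembly: FibrilAssembly, chain_id: str,
                           cfg: dict) -> Tuple[Dict[AtomKey, float], Dict[int, float]]:
    """Per-atom ASP x ΔASA terms (assembly minus isolated-chain reference)."""
    iso = compute_sasa(assembly, "isolated_chain", chain_id, config=cfg)
    asm = compute_sasa(assembly, "assembly", config=cfg)
    chain = assembly.chain(chain_id)
    asp = ASP_EISENBERG_MCLACHLAN
    per_atom: Dict[AtomKey, float] = {}
    per_res: Dict[int, float] = {}
    for r in chain.residues:
        acc = 0.0
        for a in r.atoms:
            key = (chain_id, r.seq_id, a.name)
            sigma = asp[asp_class(r.name, a.name, a.element)]
            d = sigma * (asm.asa_of(key) - iso.asa_of(key))
            per_atom[key] = d
            acc += d
        per_res[r.seq_id] = acc
    return per_atom, per_res


def _buried_backbone_hbonds(assembly: FibrilAssembly, chain_id: str,
                            cfg: dict) -> int:
    """Backbone H-bonds of the chain whose partner residues are both buried.

    Burial here means relative residue SASA in the assembly below
    ``stability.buried_rel_asa``.
    """
    from .config import MAX_ASA_TIEN_2013
    conf_cfg = cfg["conformation"]
    stab = cfg["stability"]
    units = _collect_backbone(assembly)
    bonds = _ks_hbonds(units, conf_cfg["hbond_energy_cutoff"])
    asm = compute_sasa(assembly, "assembly", config=cfg)
    res_name: Dict[Tuple[str, int], str] = {}
    for c in assembly.chains:
        for r in c.residues:
            res_name[(c.chain_id, r.seq_id)] = r.name

    def is_buried(cid: str, seq: int) -> bool:
        mx = MAX_ASA_TIEN_2013.get(res_name.get((cid, seq), "ALA"),
                                   MAX_ASA_TIEN_2013["ALA"])
        return asm.per_residue.get((cid, seq), 0.0) / mx < stab["buried_rel_asa"]

    n = 0
    counted = set()
    for acc_i, don_i in bonds:
        a, b = units[acc_i], units[don_i]
        if chain_id not in (a.chain_id, b.chain_id):
            continue
        pair = frozenset([(a.chain_id, a.seq_id), (b.chain_id, b.seq_id)])
        if pair in counted:
            continue
        if is_buried(a.chain_id, a.seq_id) and is_buried(b.chain_id, b.seq_id):
            counted.add(pair)
            n += 1
    return n


def dG_sol(assembly: FibrilAssembly, chain_id: Optional[str] = None,
           config: Optional[dict] = None) -> EnergyReport:
    """Solvation free energy of one (by default interior, rung-0) chain.

    Raises when the assembly has no interior chain and none is named
    explicitly.
    """
    cfg = merged(config)
    if chain_id is None:
        assembly.require_topology()
        interior = [c for c in assembly.interior_chain_ids()
                    if assembly.rung_of[c] == 0]
        if not interior:
            interior = assembly.interior_chain_ids()
        if not interior:
            raise TopologyError("no interior chain (need >= 3 rungs); pass chain_id explicitly")
        chain_id = interior[0]
    per_atom, per_res = _chain_solvation_terms(assembly, chain_id, cfg)
    n_hb = _buried_backbone_hbonds(assembly, chain_id, cfg)
    e_hb = cfg["stability"]["e_hb"]
    hb_term = e_hb * n_hb
    total = float(sum(per_res.values()) + hb_term)
    return EnergyReport(
        chain_id=chain_id,
        per_atom_dG=per_atom,
        per_residue_dG=per_res,
        dG_sol_chain=total,
        hbond_term=hb_term,
        n_hbonds_buried=n_hb,
        asp_set_id=cfg["stability"]["asp_set"],
    )


def dG_diss(assembly: FibrilAssembly, protofilament: int = 0,
            config: Optional[dict] = None) -> float:
    """Dissociation cost of the terminal (highest-rung) chain, kcal/mol.

    Positive = costly to remove. A single isolated chain dissociates for
    free (returns 0). Requires at least 3 rungs so the terminal chain sees a
    fibril-like environment; fewer rungs raise unless the assembly is a
    designed dimer/single chain, in which case the interaction energy is
    still well-defined and returned.
    """
    cfg = merged(config)
    if len(assembly.chains) == 1:
        return 0.0
    assembly.require_topology()
    rungs = assembly.rungs_of_protofilament(protofilament)
    if len(rungs) < 3 and assembly.n_protofilaments == 1 and len(assembly.chains) > 2:
        raise TopologyError("dG_diss needs >= 3 rungs for a fibril-like terminal environment")
    chain_id = assembly.terminal_chain_id(protofilament)
    per_atom, per_res = _chain_solvation_terms(assembly, chain_id, cfg)
    # interfacial backbone H-bonds of the terminal chain (inter-chain only)
    units = _collect_backbone(assembly)
    bonds = _ks_hbonds(units, cfg["conformation"]["hbond_energy_cutoff"])
    n_hb = 0
    counted = set()
    for acc_i, don_i in bonds:
        a, b = units[acc_i], units[don_i]
        if a.chain_id == b.chain_id:
            continue
        if chain_id not in (a.chain_id, b.chain_id):
            continue
        pair = frozenset([(a.chain_id, a.seq_id), (b.chain_id, b.seq_id)])
        if pair not in counted:
            counted.add(pair)
            n_hb += 1
    interaction = float(sum(per_res.values()) + cfg["stability"]["e_hb"] * n_hb)
    return -interaction


def per_residue_energy_map(report: EnergyReport) -> Dict[int, float]:
    """Residue-level decomposition; sums to dG_sol_chain minus the H-bond term."""
    return dict(report.per_residue_dG)
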