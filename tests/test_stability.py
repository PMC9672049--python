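"""ΔG_sol / ΔG_diss: oracles, zeros, invariances, monotonicity."""

import copy

import numpy as np
import pytest

from crossbeta._geom import rotation_about_axis
from crossbeta.config import merged
from crossbeta.core import FibrilAssembly
from crossbeta.sasa import compute_sasa
from crossbeta.stability import asp_class, dG_diss, dG_sol, per_residue_energy_map
from crossbeta.synthetic import FibrilSpec, build_fibril

# independent literal copy of the five-class parameter set (kcal/mol/A^2)
ORACLE_ASP = {"C": 0.016, "N/O": -0.006, "O-": -0.024, "N+": -0.050, "S": 0.021}
ORACLE_CHARGED_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
ORACLE_CHARGED_N = {("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"), ("LYS", "NZ")}


def oracle_asp_sum(assembly: FibrilAssembly, chain_id: str) -> float:
    """Spreadsheet-style recomputation: explicit loop over atoms, literal
    parameter values, SASA taken from the same quadrature."""
    iso = compute_sasa(assembly, "isolated_chain", chain_id)
    asm = compute_sasa(assembly, "assembly")
    total = 0.0
    for r in assembly.chain(chain_id).residues:
        for a in r.atoms:
            if a.element == "S":
                cls = "S"
            elif a.name == "OXT" or (r.name, a.name) in ORACLE_CHARGED_O:
                cls = "O-"
            elif (r.name, a.name) in ORACLE_CHARGED_N:
                cls = "N+"
            elif a.element == "C":
                cls = "C"
            else:
                cls = "N/O"
            key = (chain_id, r.seq_id, a.name)
            total += ORACLE_ASP[cls] * (asm.asa_of(key) - iso.asa_of(key))
    return total


@pytest.fixture(scope="module")
def dimer():
    """Two stacked rungs of a 12-residue mixed-sequence strand."""
    return build_fibril(FibrilSpec(template="hairpin", n_res=16,
                                   sequence="AVLRAVDSAVLEAVKS", n_rungs=2,
                                   symmetry="C1", twist_deg=-1.3, rise_A=4.9))


def test_asp_sum_matches_term_by_term_oracle(dimer):
    cfg = merged(None)
    cfg["stability"]["e_hb"] = 0.0  # isolate the ASP term
    for cid in dimer.chain_ids:
        rep = dG_sol(dimer, cid, cfg)
        assert rep.dG_sol_chain == pytest.approx(oracle_asp_sum(dimer, cid), abs=1e-6)


def test_dG_diss_matches_oracle_on_dimer(dimer):
    cfg = merged(None)
    cfg["stability"]["e_hb"] = 0.0
    terminal = dimer.terminal_chain_id(0)
    assert dG_diss(dimer, config=cfg) == pytest.approx(
        -oracle_asp_sum(dimer, terminal), abs=1e-6)
    assert dG_diss(dimer, config=cfg) > 0.0


def test_hbond_term_composes_linearly(default_fibril):
    loose = {"stability": {"buried_rel_asa": 1.0}}  # every partner counts as buried
    rep0 = dG_sol(default_fibril, config={"stability": {"buried_rel_asa": 1.0,
                                                        "e_hb": 0.0}})
    rep1 = dG_sol(default_fibril, config={"stability": {"buried_rel_asa": 1.0,
                                                        "e_hb": -0.6}})
    assert rep1.n_hbonds_buried == rep0.n_hbonds_buried > 0
    assert rep1.dG_sol_chain == pytest.approx(
        rep0.dG_sol_chain - 0.6 * rep1.n_hbonds_buried, abs=1e-9)
    assert rep1.hbond_term == pytest.approx(-0.6 * rep1.n_hbonds_buried)


def test_contact_free_chain_has_zero_dG(default_fibril):
    iso = default_fibril.subset(["C"])
    iso.protofilament_of = {"C": 0}
    iso.rung_of = {"C": 0}
    rep = dG_sol(iso, "C")
    assert rep.dG_sol_chain == pytest.approx(0.0, abs=1e-9)
    assert dG_diss(iso) == 0.0


def test_amyloid_like_assembly_is_stabilizing(default_fibril):
    rep = dG_sol(default_fibril)
    assert rep.dG_sol_chain < 0.0
    assert dG_diss(default_fibril) > 0.0


def test_per_residue_map_reconciles(default_fibril):
    rep = dG_sol(default_fibril)
    m = per_residue_energy_map(rep)
    assert sum(m.values()) == pytest.approx(rep.dG_sol_chain - rep.hbond_term, abs=1e-9)
    assert set(m) == set(default_fibril.chain(rep.chain_id).seq_ids)


def test_exposed_residue_contributes_nearly_nothing(default_fibril):
    rep = dG_sol(default_fibril)
    m = per_residue_energy_map(rep)
    # outer-lane polar residues are solvent-facing; their burial term is tiny
    assert abs(m[94]) < 0.25


def test_energies_invariant_under_rigid_motion(dimer):
    cfg = merged(None)
    rep0 = dG_sol(dimer, dimer.chain_ids[0], cfg)
    R = rotation_about_axis(np.array([1.0, 0.3, -0.4]), 49.0)
    moved = dimer.transformed(R, np.array([7.0, -2.0, 3.0]))
    rep1 = dG_sol(moved, dimer.chain_ids[0], cfg)
    # the fixed quadrature orientation makes this approximate, not exact
    assert rep1.dG_sol_chain == pytest.approx(rep0.dG_sol_chain, abs=0.2)


def test_removing_interface_residues_lowers_dG_diss(default_fibril):
    full = dG_diss(default_fibril)
    pruned = copy.deepcopy(default_fibril)
    # delete the Leu-ladder lane (seq 43..58) from every chain
    for c in pruned.chains:
        c.residues = [r for r in c.residues if not (43 <= r.seq_id <= 58)]
    assert dG_diss(pruned) < full


def test_asp_class_unknown_element_errors():
    with pytest.raises(KeyError):
        asp_class("ALA", "XX", "FE")
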