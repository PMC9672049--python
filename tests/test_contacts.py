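"""Contact detection, clustering, stagger footprints, interface areas."""

from collections import Counter

import numpy as np
import pytest

from crossbeta.contacts import (cluster_hydrophobics, detect_contacts,
                                interface_area, stagger_footprint)
from crossbeta.core import Atom, Chain, FibrilAssembly, Residue, TopologyError
from crossbeta.sasa import compute_sasa
from crossbeta.synthetic import salt_bridge_dimer


def test_salt_bridge_at_cutoff_detected(motifs):
    recs = detect_contacts(motifs["salt_bridge_3p5"], "A", require_interior=False)
    locks = [r for r in recs if r.kind == "ionic_lock"]
    assert locks
    assert min(r.distance_A for r in locks) == pytest.approx(3.5, abs=1e-6)
    # one salt bridge at residue level, even if several atom pairs qualify
    assert len({frozenset(r.residue_pair) for r in locks}) == 1
    assert all(r.interface == "inter_protomer" for r in locks)


def test_salt_bridge_beyond_cutoff_not_detected(motifs):
    recs = detect_contacts(motifs["salt_bridge_4p5"], "A", require_interior=False)
    assert [r for r in recs if r.kind == "ionic_lock"] == []


def test_contact_distances_respect_cutoffs(default_fibril):
    cid = [c for c in default_fibril.interior_chain_ids()
           if default_fibril.rung_of[c] == 0][0]
    recs = detect_contacts(default_fibril, cid)
    cutoffs = {"hbond": 3.5, "ionic_lock": 4.0, "hydrophobic": 4.5}
    for r in recs:
        assert r.distance_A <= cutoffs[r.kind] + 1e-9
        # stored distance reproducible from coordinates
        a = default_fibril.chain(r.atom_a[0]).residue(r.atom_a[1]).coord(r.atom_a[2])
        b = default_fibril.chain(r.atom_b[0]).residue(r.atom_b[1]).coord(r.atom_b[2])
        assert np.linalg.norm(b - a) == pytest.approx(r.distance_A, abs=1e-9)


def test_terminal_reference_chain_rejected(default_fibril):
    term = default_fibril.terminal_chain_id(0)
    with pytest.raises(TopologyError, match="rung 0"):
        detect_contacts(default_fibril, term)


def test_designed_ionic_locks_in_default_fibril(default_fibril):
    cid = [c for c in default_fibril.interior_chain_ids()
           if default_fibril.rung_of[c] == 0][0]
    recs = detect_contacts(default_fibril, cid)
    locks = {frozenset(r.residue_pair) for r in recs if r.kind == "ionic_lock"}
    assert len(locks) == 2  # Arg30<->Asp23 across the C2 axis, both ways
    assert all(r.interface == "inter_protomer"
               for r in recs if r.kind == "ionic_lock")


def _leu_triangle():
    """Three Leu residues in different chains with mutually contacting CD."""
    def leu(chain_id, seq, center):
        c = np.asarray(center, float)
        atoms = [Atom(1, "N", "N", c + [-1.2, 0, 0]), Atom(2, "CA", "C", c),
                 Atom(3, "C", "C", c + [1.2, 0, 0]), Atom(4, "O", "O", c + [1.2, 0, 1.2]),
                 Atom(5, "CB", "C", c + [0, 1.5, 0]), Atom(6, "CG", "C", c + [0, 3.0, 0]),
                 Atom(7, "CD1", "C", c + [0.7, 4.3, 0]), Atom(8, "CD2", "C", c + [-0.7, 4.3, 0])]
        return Chain(chain_id, [Residue(seq, "LEU", atoms)])
    # CA triangle side 8.0; side chains all point at the common centroid
    centers = [(0, 0, 0), (8, 0, 0), (4, 6.9, 0)]
    chains = []
    for k, ctr in enumerate(centers):
        ch = leu("XYZ"[k], 10 + k, ctr)
        # rotate each side chain to aim at the triangle centroid
        centroid = np.mean(centers, axis=0)
        u = centroid - np.asarray(ctr, float)
        u /= np.linalg.norm(u)
        for r in ch.residues:
            for a in r.atoms:
                if a.name in ("CB", "CG", "CD1", "CD2"):
                    d = np.linalg.norm(a.coord - ctr)
                    perp = np.array([-u[1], u[0], 0.0])
                    off = {"CD1": 0.7, "CD2": -0.7}.get(a.name, 0.0)
                    a.coord = np.asarray(ctr) + u * d + perp * off
        chains.append(ch)
    asm = FibrilAssembly(chains=chains, label="leu_triangle")
    asm.protofilament_of = {"X": 0, "Y": 1, "Z": 2}
    asm.rung_of = {"X": 0, "Y": 0, "Z": 0}
    return asm


def test_three_contacting_leucines_form_one_cluster():
    asm = _leu_triangle()
    recs = detect_contacts(asm, "X", require_interior=False)
    hyd = [r for r in recs if r.kind == "hydrophobic"]
    assert hyd
    clusters = cluster_hydrophobics(recs)
    assert len(clusters) == 1
    assert len(clusters[0]) == 3


def test_two_contacting_leucines_below_cluster_size():
    asm = _leu_triangle()
    asm.chains = asm.chains[:2]
    asm.protofilament_of = {"X": 0, "Y": 1}
    asm.rung_of = {"X": 0, "Y": 0}
    recs = detect_contacts(asm, "X", require_interior=False)
    assert [r for r in recs if r.kind == "hydrophobic"]
    assert cluster_hydrophobics(recs) == []


def test_hydrophobic_ladders_in_default_fibril(default_fibril):
    cid = [c for c in default_fibril.interior_chain_ids()
           if default_fibril.rung_of[c] == 0][0]
    recs = detect_contacts(default_fibril, cid)
    clusters = cluster_hydrophobics(recs, interface="intra")
    assert len(clusters) >= 4  # one ladder per designed Leu column
    for cl in clusters:
        assert len(cl) >= 3


def test_planar_contacts_have_zero_axial_stagger(motifs):
    recs = detect_contacts(motifs["salt_bridge_3p5"], "A", require_interior=False)
    hist = stagger_footprint(recs)
    for iface, counts in hist.items():
        assert set(counts) == {0}


def test_backbone_hbond_stagger_spans_adjacent_rungs(default_fibril):
    cid = [c for c in default_fibril.interior_chain_ids()
           if default_fibril.rung_of[c] == 0][0]
    recs = detect_contacts(default_fibril, cid)
    hist = stagger_footprint(recs)
    intra = hist["intra_protomer"]
    assert intra.get(-1, 0) > 0 and intra.get(1, 0) > 0


def test_c2_contact_multiset_invariant_under_protofilament_swap(default_fibril):
    """In a C2 fibril, the inter-protomer contact inventory seen from the two
    rung-0 chains must be identical as a multiset of (kind, |Δ|, residues)."""
    rung0 = [c for c in default_fibril.chain_ids if default_fibril.rung_of[c] == 0]
    inventories = []
    for cid in rung0:
        recs = detect_contacts(default_fibril, cid)
        inv = Counter((r.kind, abs(r.rung_offset),
                       r.atom_a[1], r.atom_b[1])
                      for r in recs if r.interface == "inter_protomer")
        inventories.append(inv)
    assert inventories[0] == inventories[1]


def test_interface_area_nontouching_is_zero():
    asm = salt_bridge_dimer(3.5)
    import copy
    far = copy.deepcopy(asm)
    for r in far.chains[1].residues:
        for a in r.atoms:
            a.coord = a.coord + np.array([200.0, 0.0, 0.0])
    assert interface_area(far, "inter_protomer") == pytest.approx(0.0, abs=1e-6)


def test_interface_area_matches_direct_recomputation(default_fibril):
    area = interface_area(default_fibril, "inter_protomer")
    # independent recomputation straight from SASA totals
    side_a = default_fibril.subset([c.chain_id for c in default_fibril.protofilament_chains(0)])
    side_b = default_fibril.subset([c.chain_id for c in default_fibril.protofilament_chains(1)])
    s_a = compute_sasa(side_a, "assembly").total
    s_b = compute_sasa(side_b, "assembly").total
    s_ab = compute_sasa(default_fibril, "assembly").total
    assert area == pytest.approx((s_a + s_b - s_ab) / 2.0, abs=1e-9)
    assert area > 0.0
    assert interface_area(default_fibril, "intra_protomer") > 0.0
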