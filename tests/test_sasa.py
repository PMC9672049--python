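"""SASA quadrature against closed forms and a Monte-Carlo oracle."""

import numpy as np
import pytest

from crossbeta.sasa import (buried_area, classify_burial, compute_sasa,
                            shrake_rupley, sphere_points)


def mc_sasa_oracle(coords, radii, probe, n_points, seed):
    """Independent Monte-Carlo SASA: uniform random points on each solvated
    sphere, accessibility by direct exhaustive distance checks."""
    rng = np.random.default_rng(seed)
    R = radii + probe
    out = np.empty(len(coords))
    for i in range(len(coords)):
        v = rng.normal(size=(n_points, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = coords[i] + R[i] * v
        acc = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            acc &= ((pts - coords[j]) ** 2).sum(axis=1) >= R[j] ** 2
        out[i] = 4.0 * np.pi * R[i] ** 2 * acc.mean()
    return out


def test_isolated_atom_matches_closed_form():
    asa = shrake_rupley(np.zeros((1, 3)), np.array([1.9]), 1.4, 960)
    exact = 4.0 * np.pi * 3.3 ** 2
    assert abs(asa[0] - exact) / exact < 0.01


def test_non_overlapping_atoms_are_additive():
    coords = np.array([[0.0, 0, 0], [12.0, 0, 0]])
    radii = np.array([1.9, 1.52])
    asa = shrake_rupley(coords, radii, 1.4, 1920)
    for k in range(2):
        alone = shrake_rupley(coords[k:k + 1], radii[k:k + 1], 1.4, 960)
        assert asa[k] == pytest.approx(alone[0], abs=1e-9)


def test_ala_dipeptide_against_monte_carlo_oracle(motifs):
    asm = motifs["ala_dipeptide"]
    coords = np.vstack([a.coord for c in asm.chains for a in c.atoms()])
    radii = np.array([a.vdw_radius for c in asm.chains for a in c.atoms()])
    ours = shrake_rupley(coords, radii, 1.4, 1920)
    oracle = mc_sasa_oracle(coords, radii, 1.4, 1_000_000, seed=7)
    rel = np.abs(ours - oracle) / np.maximum(oracle, 1.0)
    assert rel.max() < 0.02


def test_assembly_sasa_never_exceeds_isolated_sum(default_fibril):
    asm_total = compute_sasa(default_fibril, "assembly").total
    iso_sum = sum(compute_sasa(default_fibril, "isolated_chain", c.chain_id).total
                  for c in default_fibril.chains)
    assert asm_total <= iso_sum


def test_sasa_is_deterministic(default_fibril):
    a = compute_sasa(default_fibril, "assembly").atom_asa
    b = compute_sasa(default_fibril, "assembly").atom_asa
    assert np.array_equal(a, b)


def test_sphere_points_are_unit_and_well_spread():
    pts = sphere_points(960)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    assert np.abs(pts.mean(axis=0)).max() < 0.01


def test_per_residue_sums_match_atoms(default_fibril):
    res = compute_sasa(default_fibril, "assembly")
    total_from_res = sum(res.per_residue.values())
    assert total_from_res == pytest.approx(res.total, abs=1e-6)
    assert (res.atom_asa >= 0).all()


def test_buried_area_distant_chain_is_zero(default_fibril):
    import copy
    asm = copy.deepcopy(default_fibril)
    far = asm.chains[0]
    for r in far.residues:
        for a in r.atoms:
            a.coord = a.coord + np.array([500.0, 0.0, 0.0])
    ba = buried_area(asm, far.chain_id)
    assert ba.total == pytest.approx(0.0, abs=1e-6)


def test_buried_area_symmetric_in_c2_partner(default_fibril):
    # rung-0 chains of the two protofilaments are C2 copies: equal burial
    rung0 = [c for c in default_fibril.chain_ids if default_fibril.rung_of[c] == 0]
    b0 = buried_area(default_fibril, rung0[0]).total
    b1 = buried_area(default_fibril, rung0[1]).total
    assert b0 == pytest.approx(b1, rel=0.01)
    assert b0 > 500.0  # an interior chain buries substantial area


def test_isolated_chain_context_is_fully_exposed(default_fibril):
    cid = default_fibril.chains[0].chain_id
    burial = classify_burial(default_fibril, cid, context="isolated_chain")
    # no partner chains: nothing can be buried
    assert all(v == "exposed" or v == "partially_buried" for v in burial.labels.values())
    assert sum(1 for v in burial.labels.values() if v == "exposed") / len(burial.labels) > 0.7


def test_burial_classes_interior_vs_surface(default_fibril):
    cid = [c for c in default_fibril.interior_chain_ids()
           if default_fibril.rung_of[c] == 0][0]
    burial = classify_burial(default_fibril, cid)
    labels = burial.labels
    assert set(labels) == set(default_fibril.chain(cid).seq_ids)
    # the interior chain is less exposed than an isolated chain
    iso = classify_burial(default_fibril, cid, context="isolated_chain")
    n_exp_asm = sum(1 for v in labels.values() if v == "exposed")
    n_exp_iso = sum(1 for v in iso.labels.values() if v == "exposed")
    assert n_exp_asm < n_exp_iso
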