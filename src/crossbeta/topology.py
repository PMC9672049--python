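"""Protofilament partitioning, rung indexing and point-group detection.

Chains are linked into protofilaments when one superposes onto the other by a
*pure translation* (centroid-matched Cα RMSD below ``topology.stack_rmsd``)
over a common residue window, and their centroids are within 1.5x the rise
scale. Translation-only superposition is deliberate: per-rung twists of a few
degrees move Cα atoms well under 1 Å, so stacking detection needs no axis
estimate and no rotation fit. Rung indices count levels along the fibril
axis, with rung 0 at the axial median of each protofilament and chains of
different protofilaments at the same level sharing an index.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._geom import kabsch
from .config import merged
from .core import Chain, FibrilAssembly, TopologyError


def _common_seq_ids(a: Chain, b: Chain) -> List[int]:
    ids_b = set(b.seq_ids)
    return [s for s in a.seq_ids
            if s in ids_b and a.residue(s).coord("CA") is not None
            and b.residue(s).coord("CA") is not None]


def _translation_rmsd(a: Chain, b: Chain, seq_ids: Sequence[int]) -> float:
    P = a.ca_coords(seq_ids)
    Q = b.ca_coords(seq_ids)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    return float(np.sqrt(((P0 - Q0) ** 2).sum() / len(P0)))


def _reference_point(chain: Chain, rung_ref: Optional[int]) -> np.ndarray:
    """Axial reference of a chain: Cα centroid, or one residue's Cα."""
    if rung_ref is not None:
        res = chain.residue(rung_ref)
        if res is None or res.coord("CA") is None:
            raise TopologyError(f"rung reference residue {rung_ref} missing in chain {chain.chain_id}")
        return res.coord("CA")
    return chain.centroid()


def assign_topology(assembly: FibrilAssembly, config: Optional[dict] = None) -> FibrilAssembly:
    """Fill ``protofilament_of``/``rung_of`` and the fibril axis in place.

    Returns the same assembly for chaining. Raises :class:`TopologyError`
    when two chains share no common residue window of the configured minimum
    length (incompatible models cannot be stacked or compared).
    """
    cfg = merged(config)["topology"]
    chains = assembly.chains
    n = len(chains)
    refs = {c.chain_id: _reference_point(c, cfg["rung_ref"]) for c in chains}

    # pairwise stacking links
    links: List[Tuple[int, int]] = []
    link_vecs: List[np.ndarray] = []
    for i in range(n):
        for j in range(i + 1, n):
            common = _common_seq_ids(chains[i], chains[j])
            if len(common) < cfg["min_common_residues"]:
                raise TopologyError(
                    f"chains {chains[i].chain_id} and {chains[j].chain_id} share only "
                    f"{len(common)} residue positions (< {cfg['min_common_residues']})")
            d = refs[chains[j].chain_id] - refs[chains[i].chain_id]
            if np.linalg.norm(d) >= 1.5 * cfg["stack_dist_scale"]:
                continue
            if _translation_rmsd(chains[i], chains[j], common) < cfg["stack_rmsd"]:
                links.append((i, j))
                link_vecs.append(d)

    # connected components
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in links:
        parent[find(i)] = find(j)
    roots = [find(i) for i in range(n)]
    comp_order: List[int] = []
    for r in roots:
        if r not in comp_order:
            comp_order.append(r)
    # deterministic protofilament labels: by lexicographically smallest chain id
    comp_members: Dict[int, List[int]] = {r: [i for i in range(n) if roots[i] == r] for r in comp_order}
    ordered = sorted(comp_members.values(), key=lambda mem: min(chains[i].chain_id for i in mem))

    # fibril axis from stacking displacement vectors
    axis_dir: Optional[np.ndarray] = None
    if link_vecs:
        vecs = np.vstack(link_vecs)
        ref = vecs[0] / np.linalg.norm(vecs[0])
        vecs = vecs * np.where(vecs @ ref < 0, -1.0, 1.0)[:, None]
        mean = vecs.mean(axis=0)
        axis_dir = mean / np.linalg.norm(mean)
        # deterministic sign: largest-magnitude component positive
        k = int(np.argmax(np.abs(axis_dir)))
        if axis_dir[k] < 0:
            axis_dir = -axis_dir

    protofilament_of: Dict[str, int] = {}
    rung_of: Dict[str, int] = {}
    rise_samples: List[float] = []
    level0: Dict[int, float] = {}

    def assign_rungs(axis: Optional[np.ndarray]) -> None:
        rung_of.clear()
        rise_samples.clear()
        level0.clear()
        for p, members in enumerate(ordered):
            for i in members:
                protofilament_of[chains[i].chain_id] = p
            if axis is None:
                for i in members:
                    rung_of[chains[i].chain_id] = 0
                continue
            zs = [(float(refs[chains[i].chain_id] @ axis), i) for i in members]
            zs.sort()
            m = len(zs)
            for rank, (z, i) in enumerate(zs):
                rung_of[chains[i].chain_id] = rank - m // 2
            level0[p] = zs[m // 2][0]
            rise_samples.extend(b - a for (a, _), (b, _) in zip(zs, zs[1:]))

    assign_rungs(axis_dir)

    # refine the axis from the actual inter-rung rotations: the centroid
    # displacement has a lateral component of (radius x twist) which tilts the
    # translation-based estimate; the screw rotation axis does not
    if axis_dir is not None:
        from ._geom import screw_decompose  # local import avoids cycle at module load
        refined: List[np.ndarray] = []
        for p in range(len(ordered)):
            rungs = {rung_of[chains[i].chain_id]: chains[i] for i in ordered[p]}
            order_r = sorted(rungs)
            for r0, r1 in zip(order_r, order_r[1:]):
                if r1 != r0 + 1:
                    continue
                a, b = rungs[r0], rungs[r1]
                common = _common_seq_ids(a, b)
                if len(common) < 3:
                    continue
                P = a.ca_coords(common)
                # collinear CA traces leave the rotation about the chain axis
                # unconstrained; skip such pairs
                sv = np.linalg.svd(P - P.mean(axis=0), compute_uv=False)
                if sv[1] < 1e-6 * max(sv[0], 1.0):
                    continue
                R, t, _ = kabsch(P, b.ca_coords(common))
                angle, _, u, _ = screw_decompose(R, t, axis_dir)
                if abs(angle) > 0.05:
                    refined.append(u if u @ axis_dir > 0 else -u)
        if refined:
            new_axis = np.mean(refined, axis=0)
            new_axis /= np.linalg.norm(new_axis)
            k = int(np.argmax(np.abs(new_axis)))
            if new_axis[k] < 0:
                new_axis = -new_axis
            axis_dir = new_axis
            assign_rungs(axis_dir)

    # level protofilaments against protofilament 0
    if axis_dir is not None and rise_samples:
        rise = float(np.median(rise_samples))
        if rise > 1e-6 and len(ordered) > 1:
            for p in range(1, len(ordered)):
                if p in level0 and 0 in level0:
                    offset = int(round((level0[p] - level0[0]) / rise))
                    if offset:
                        for i in ordered[p]:
                            rung_of[chains[i].chain_id] += offset

    assembly.protofilament_of = protofilament_of
    assembly.rung_of = rung_of
    assembly.axis_dir = axis_dir
    all_ca = np.vstack([c.ca_coords() for c in chains])
    assembly.axis_point = all_ca.mean(axis=0)
    return assembly


def detect_symmetry(assembly: FibrilAssembly, config: Optional[dict] = None) -> str:
    """Point-group of the two-protofilament fibril: ``"C2"`` or ``"C1"``.

    C2 means a 180° rotation about the fibril axis (with an axial rung-offset
    search of ±2 levels) maps protofilament 0 onto protofilament 1 with Cα
    RMSD below ``topology.sym_rmsd``. A single protofilament is C1.
    """
    cfg = merged(config)["topology"]
    assembly.require_topology()
    if assembly.n_protofilaments == 1:
        assembly.symmetry = "C1"
        return "C1"
    if assembly.n_protofilaments != 2:
        assembly.symmetry = "C1"
        return "C1"
    pf0 = assembly.rungs_of_protofilament(0)
    pf1 = assembly.rungs_of_protofilament(1)
    if len(pf0) != len(pf1) or assembly.axis_dir is None:
        assembly.symmetry = "C1"
        return "C1"
    u = assembly.axis_dir
    R180 = 2.0 * np.outer(u, u) - np.eye(3)

    best = np.inf
    for offset in range(-cfg["sym_rung_search"], cfg["sym_rung_search"] + 1):
        pairs = [(pf0[r], pf1[r + offset]) for r in pf0 if (r + offset) in pf1]
        if not pairs:
            continue
        A, B = [], []
        for ca, cb in pairs:
            common = _common_seq_ids(ca, cb)
            if not common:
                continue
            A.append(ca.ca_coords(common))
            B.append(cb.ca_coords(common))
        if not A:
            continue
        A = np.vstack(A)
        B = np.vstack(B)
        # optimal C2 axis position: mean midpoint of (rotated A, B) pairs in
        # the plane normal to u; optimal axial shift: mean axial difference
        A_rot = A @ R180.T
        diff = B - A_rot
        axial = (diff @ u).mean()
        perp = diff - np.outer(diff @ u, u)
        shift = perp.mean(axis=0)  # equals 2*p_perp correction
        resid = diff - axial * u - shift
        rmsd = float(np.sqrt((resid ** 2).sum() / len(A)))
        if rmsd < best:
            best = rmsd
    sym = "C2" if best < cfg["sym_rmsd"] else "C1"
    assembly.symmetry = sym
    return sym
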