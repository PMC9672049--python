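"""Idealized helical fibril generator with known ground-truth parameters.

Builds stacked-rung cross-β assemblies from a per-rung Cα path: rung *k* is
rung 0 rotated by ``k x twist`` about the z axis and translated ``k x rise``
along it; a C2 partner protofilament is the 180°-rotated copy. Backbone N, C
and O atoms are placed so that carbonyls and amides point along the stacking
axis with alternating parity, which gives genuine Kabsch–Sander β-ladders
between rungs (the defining feature of cross-β architecture). Side chains
beyond Cβ are synthesized with idealized straight-arm rotamers only for the
residue types the contact detectors need (Arg, Asp, Glu, Lys, Leu); all other
residues carry a Cβ only. Coordinate noise, when requested, is seeded and
applied after symmetry expansion so symmetry detection under noise is a real
statistical test.

The default spec mirrors the study conditions of an SAA-type fibril: two
protofilaments of five 76-residue hairpin chains (author numbering 19–94),
C2 symmetry, left-handed twist of 1.3° per rung and a 4.9 Å rise.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._geom import rotation_about_axis
from .core import Atom, Chain, FibrilAssembly, ONE_TO_THREE, Residue, StructureError

Z = np.array([0.0, 0.0, 1.0])

#: Synthetic 76-residue meander test sequence (NOT a natural SAA sequence).
#: Four 16-residue lanes joined by turns: the inner (face) lane carries an
#: Asp/Arg pair placed mirror-symmetrically so the C2 partner forms ionic
#: locks across the inter-protomer interface; the middle lanes carry Leu
#: whose stacked rotamers form hydrophobic ladders along the fibril axis;
#: the outer (edge) lane is polar and exposed.
SYNTHETIC_CORE_SEQUENCE = (
    "AVAVDAVAVAVRAVAV"   # lane 0 (inner/face), D and R point at the C2 axis
    "GGGG"               # turn 1
    "ASAVLAVALAVSAVAS"   # lane 1, Leu ladders
    "GGGG"               # turn 2
    "SAVALAVLAVASAVSA"   # lane 3 of the meander, Leu ladders
    "GGGG"               # turn 3
    "SQSNSGSQTNSQSGNS"   # outer/edge lane, polar (Asn at author position 93)
)

#: side-chain direction overrides for the sequence above (index -> ±1):
#: the Asp-23 and Arg-30 side chains (0-based path indices 4 and 11) must
#: both point toward the C2 axis to form the designed inter-protomer locks.
SYNTHETIC_CORE_SIDE_SIGNS = {4: 1, 11: 1}


def synthetic_core_record() -> "SequenceRecord":
    """The synthetic 76-residue fibril-core sequence as a record
    (author numbering 19–94)."""
    from .core import SequenceRecord
    return SequenceRecord("synthetic-core", SYNTHETIC_CORE_SEQUENCE)


def synthetic_variant_record() -> "SequenceRecord":
    """Synthetic near-identical ortholog: one N→S substitution at author
    position 93 of the core (75/76 identical positions)."""
    from .core import SequenceRecord
    idx = 93 - 19
    seq = SYNTHETIC_CORE_SEQUENCE
    assert seq[idx] == "N"
    return SequenceRecord("synthetic-variant-N93S", seq[:idx] + "S" + seq[idx + 1:])


def synthetic_distant_record(n_substitutions: int = 18) -> "SequenceRecord":
    """Synthetic distant ortholog: deterministic substitutions spread across
    the core (18 changes over 76 positions ≈ 76% identity)."""
    from .core import SequenceRecord
    swap = {"A": "G", "V": "T", "L": "M", "S": "T", "Q": "E",
            "N": "D", "G": "A", "T": "S", "D": "E", "R": "K"}
    seq = list(SYNTHETIC_CORE_SEQUENCE)
    step = max(1, len(seq) // n_substitutions)
    changed = 0
    for i in range(0, len(seq), step):
        if changed >= n_substitutions:
            break
        seq[i] = swap.get(seq[i], "G")
        changed += 1
    return SequenceRecord("synthetic-distant", "".join(seq))


@dataclass
class FibrilSpec:
    """Ground-truth recipe for one synthetic fibril."""

    template: str = "hairpin"            # straight_strand | hairpin | beta_arch | meander
    rung_path: Optional[np.ndarray] = None  # explicit (n,2|3) Cα path overrides template
    sequence: Optional[str] = None       # 1-letter codes; poly-Ala if omitted
    n_res: int = 76
    n_rungs: int = 5
    twist_deg: float = -1.3
    rise_A: float = 4.9
    symmetry: str = "C2"                 # C1 | C2
    tilt_segments: Sequence[Tuple[int, int, float]] = ()  # (start_idx, end_idx, deg), 0-based
    noise_sd_A: float = 0.0
    seed: int = 0
    start_seq_id: int = 19               # author numbering of the first residue
    arm_gap_A: float = 11.5              # hairpin arm / meander lane separation
    c2_gap_A: float = 15.7               # gap between protofilaments across the C2 axis
    ca_spacing_A: float = 3.8
    side_signs: Optional[Sequence[int]] = None  # per-residue ±1 side-chain direction

    def resolved_sequence(self, n: int) -> str:
        if self.sequence is not None:
            if len(self.sequence) != n:
                raise ValueError(f"sequence length {len(self.sequence)} != path length {n}")
            return self.sequence.upper()
        return "A" * n


def saa_like_spec(seed: int = 0, noise_sd_A: float = 0.0) -> FibrilSpec:
    """Default study-condition spec: C2, 5 rungs/protofilament, 76-residue
    meandering chain numbered 19–94, twist −1.3°, rise 4.9 Å."""
    n = len(SYNTHETIC_CORE_SEQUENCE)
    signs = [(1 if i % 2 == 0 else -1) for i in range(n)]
    for idx, s in SYNTHETIC_CORE_SIDE_SIGNS.items():
        signs[idx] = s
    return FibrilSpec(template="meander", sequence=SYNTHETIC_CORE_SEQUENCE,
                      arm_gap_A=9.5, seed=seed, noise_sd_A=noise_sd_A,
                      side_signs=signs)


# ---------------------------------------------------------------- paths

def _straight_path(n: int, spacing: float) -> np.ndarray:
    x = np.arange(n) * spacing
    return np.stack([x, np.zeros(n), np.zeros(n)], axis=1)


def _hairpin_path(n: int, spacing: float, gap: float, turn_scale: float = 1.0) -> np.ndarray:
    """Two antiparallel arms joined by a semicircular turn, in the z=0 plane."""
    r = turn_scale * gap / 2.0
    n_turn = max(3, int(round(np.pi * r / spacing)) - 1)
    n_arm = (n - n_turn) // 2
    if n_arm < 3:
        raise ValueError(f"path of {n} residues too short for a hairpin")
    n_arm2 = n - n_turn - n_arm
    L = (n_arm - 1) * spacing
    pts = []
    for i in range(n_arm):
        pts.append([i * spacing, gap / 2.0, 0.0])
    dth = np.pi / (n_turn + 1)
    for k in range(1, n_turn + 1):
        th = np.pi / 2.0 - k * dth
        pts.append([L + r * np.cos(th), r * np.sin(th) + (gap / 2.0 - r), 0.0])
    # second arm runs back along -x at y = gap/2 - 2r
    y2 = gap / 2.0 - 2.0 * r
    for j in range(n_arm2):
        pts.append([L - (j + 1) * spacing + (n_arm2 - n_arm) * 0.0, y2, 0.0])
    return np.asarray(pts)


def _meander_path(n: int, spacing: float, gap: float, lane_len: int = 16) -> np.ndarray:
    """Serpentine of lanes along y stacked in x — a compact cross-β fold
    (four direction reversals keep a 76-residue chain within a realistic
    ~50 Å cross-section radius)."""
    pts: List[List[float]] = []
    lane = 0
    i = 0
    direction = 1
    while i < n:
        x = lane * gap
        take = min(lane_len, n - i)
        start_y = 0.0 if direction > 0 else (lane_len - 1) * spacing
        for k in range(take):
            pts.append([x, start_y + direction * k * spacing, 0.0])
        i += take
        if i >= n:
            break
        # turn: semicircular bulge beyond the lane end toward the next lane
        end_y = pts[-1][1]
        r = gap / 2.0
        n_turn = min(4, n - i)
        dth = np.pi / (n_turn + 1)
        for k in range(1, n_turn + 1):
            th = np.pi - k * dth
            pts.append([x + r + r * np.cos(th),
                        end_y + direction * r * np.sin(th), 0.0])
        i += n_turn
        lane += 1
        direction = -direction
    path = np.asarray(pts[:n])
    path[:, 1] -= path[:, 1].mean()
    return path


def _template_path(spec: FibrilSpec) -> np.ndarray:
    if spec.rung_path is not None:
        path = np.asarray(spec.rung_path, float)
        if path.shape[1] == 2:
            path = np.column_stack([path, np.zeros(len(path))])
        return path.copy()
    if spec.template == "straight_strand":
        return _straight_path(spec.n_res, spec.ca_spacing_A)
    if spec.template == "hairpin":
        return _hairpin_path(spec.n_res, spec.ca_spacing_A, spec.arm_gap_A)
    if spec.template == "beta_arch":
        return _hairpin_path(spec.n_res, spec.ca_spacing_A, spec.arm_gap_A, turn_scale=1.6)
    if spec.template == "meander":
        return _meander_path(spec.n_res, spec.ca_spacing_A, spec.arm_gap_A)
    raise ValueError(f"unknown template {spec.template!r}")


def _apply_tilts(path: np.ndarray, tilts: Sequence[Tuple[int, int, float]]) -> np.ndarray:
    """Rotate each [i0, i1] segment of the path out of the rung plane by the
    given angle, about the in-plane axis perpendicular to its mean tangent."""
    out = path.copy()
    for i0, i1, deg in tilts:
        seg = out[i0:i1 + 1]
        if len(seg) < 2:
            continue
        tangent = seg[-1] - seg[0]
        tangent[2] = 0.0
        tangent /= np.linalg.norm(tangent)
        pivot_axis = np.cross(Z, tangent)
        R = rotation_about_axis(pivot_axis, deg)
        center = seg.mean(axis=0)
        out[i0:i1 + 1] = (seg - center) @ R.T + center
    return out


# ---------------------------------------------------------------- atoms

def element_of(atom_name: str) -> str:
    """Element from a PDB heavy-atom name (first alphabetic character)."""
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def _tangents(path: np.ndarray) -> np.ndarray:
    t = np.empty_like(path)
    t[1:-1] = path[2:] - path[:-2]
    t[0] = path[1] - path[0]
    t[-1] = path[-1] - path[-2]
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def _sidechain(one: str, ca: np.ndarray, u: np.ndarray, p: np.ndarray) -> List[Tuple[str, np.ndarray]]:
    """Idealized straight-arm side chain along unit direction u (p = in-plane
    perpendicular used to splay branched tips)."""
    if one == "G":
        return []
    out = [("CB", ca + 1.53 * u)]
    if one == "L":
        # CD1/CD2 splay along the stacking axis so Leu rotamers of adjacent
        # rungs interdigitate (hydrophobic ladders along the fibril)
        cg = ca + (1.53 + 1.52) * u
        out += [("CG", cg),
                ("CD1", cg + 1.52 * _unit(u + 0.8 * Z)),
                ("CD2", cg + 1.52 * _unit(u - 0.8 * Z))]
    elif one == "R":
        cg = ca + 3.05 * u
        cd = ca + 4.57 * u
        ne = ca + 6.03 * u
        cz = ca + 7.36 * u
        out += [("CG", cg), ("CD", cd), ("NE", ne), ("CZ", cz),
                ("NH1", cz + 1.33 * _unit(u + 0.6 * p)),
                ("NH2", cz + 1.33 * _unit(u - 0.6 * p))]
    elif one == "D":
        cg = ca + 3.05 * u
        out += [("CG", cg),
                ("OD1", cg + 1.25 * _unit(u + 0.6 * p)),
                ("OD2", cg + 1.25 * _unit(u - 0.6 * p))]
    elif one == "E":
        cg = ca + 3.05 * u
        cd = ca + 4.57 * u
        out += [("CG", cg), ("CD", cd),
                ("OE1", cd + 1.25 * _unit(u + 0.6 * p)),
                ("OE2", cd + 1.25 * _unit(u - 0.6 * p))]
    elif one == "K":
        out += [("CG", ca + 3.05 * u), ("CD", ca + 4.57 * u),
                ("CE", ca + 6.03 * u), ("NZ", ca + 7.5 * u)]
    elif one == "V":
        cb = ca + 1.53 * u
        out += [("CG1", cb + 1.52 * _unit(u + 0.8 * Z)),
                ("CG2", cb + 1.52 * _unit(u - 0.8 * Z))]
    elif one == "S":
        out += [("OG", ca + 2.95 * u)]
    elif one == "T":
        cb = ca + 1.53 * u
        out += [("OG1", cb + 1.42 * _unit(u + 0.8 * Z)),
                ("CG2", cb + 1.52 * _unit(u - 0.8 * Z))]
    elif one == "N":
        cg = ca + 3.05 * u
        out += [("CG", cg),
                ("OD1", cg + 1.23 * _unit(u + 0.7 * Z)),
                ("ND2", cg + 1.33 * _unit(u - 0.7 * Z))]
    elif one == "Q":
        cg = ca + 3.05 * u
        cd = ca + 4.57 * u
        out += [("CG", cg), ("CD", cd),
                ("OE1", cd + 1.23 * _unit(u + 0.7 * Z)),
                ("NE2", cd + 1.33 * _unit(u - 0.7 * Z))]
    return out


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def build_rung_atoms(path: np.ndarray, sequence: str, start_seq_id: int,
                     bond_axis: np.ndarray = Z,
                     side_signs: Optional[Sequence[int]] = None,
                     parity_hbonds: bool = True) -> List[Residue]:
    """Place backbone + side-chain atoms along a Cα path.

    Carbonyl O and (implicit) amide H point along ``bond_axis`` with
    alternating per-residue parity when ``parity_hbonds`` (cross-β stacking
    geometry: even residues donate to the rung below, odd to the rung above).
    """
    n = len(path)
    if n < 2:
        raise ValueError("path needs at least 2 residues")
    d = np.linalg.norm(path[1:] - path[:-1], axis=1)
    # self-clash check over non-adjacent Cα pairs
    for i in range(n):
        for j in range(i + 2, n):
            if np.linalg.norm(path[i] - path[j]) < 2.5:
                raise StructureError(f"self-clashing path: CA {i} and {j} closer than 2.5 A")
    tang = _tangents(path)
    residues: List[Residue] = []
    serial = 0
    for i in range(n):
        one = sequence[i]
        sigma = 1.0 if (i % 2 == 0) else -1.0
        w = (-sigma if parity_hbonds else 1.0) * np.asarray(bond_axis, float)
        t = tang[i]
        a = path[i]
        atoms: List[Tuple[str, np.ndarray]] = [
            ("N", a - 1.2 * t + 0.35 * w),
            ("CA", a.copy()),
            ("C", a + 1.2 * t + 0.35 * w),
            ("O", a + 1.2 * t + 1.58 * w),
        ]
        m = np.cross(np.asarray(bond_axis, float), t)
        nm = np.linalg.norm(m)
        if nm > 1e-9 and one != "G":
            m = m / nm
            sign = (side_signs[i] if side_signs is not None else (1 if i % 2 == 0 else -1))
            atoms += _sidechain(one, a, float(sign) * m, t)
        res_atoms = []
        for name, coord in atoms:
            serial += 1
            res_atoms.append(Atom(serial, name, element_of(name), coord))
        residues.append(Residue(seq_id=start_seq_id + i,
                                name=ONE_TO_THREE.get(one, "ALA"), atoms=res_atoms))
    return residues


def _copy_residues(residues: List[Residue], R: np.ndarray, t: np.ndarray) -> List[Residue]:
    out = []
    for r in residues:
        atoms = [Atom(a.serial, a.name, a.element, R @ a.coord + t, a.occupancy, a.bfactor)
                 for a in r.atoms]
        out.append(Residue(r.seq_id, r.name, atoms))
    return out


def build_fibril(spec: FibrilSpec) -> FibrilAssembly:
    """Assemble the fibril described by ``spec``; ground-truth topology maps
    (protofilament, rung with the median-zero convention) are filled in."""
    if spec.n_rungs < 1:
        raise ValueError("n_rungs must be >= 1")
    if spec.noise_sd_A < 0:
        raise ValueError("noise_sd_A must be >= 0")
    if spec.symmetry not in ("C1", "C2"):
        raise ValueError(f"unknown symmetry {spec.symmetry!r}")
    path = _template_path(spec)
    n = len(path)
    sequence = spec.resolved_sequence(n)
    if spec.tilt_segments:
        path = _apply_tilts(path, spec.tilt_segments)
    if spec.symmetry == "C2":
        # keep the protofilament clear of the C2 (z) axis
        shift = spec.c2_gap_A / 2.0 - path[:, 0].min()
        path = path + np.array([shift, 0.0, 0.0])
    rung0 = build_rung_atoms(path, sequence, spec.start_seq_id,
                             side_signs=spec.side_signs)

    n_pf = 2 if spec.symmetry == "C2" else 1
    letters = string.ascii_uppercase + string.ascii_lowercase
    chains: List[Chain] = []
    protofilament_of: Dict[str, int] = {}
    rung_of: Dict[str, int] = {}
    ci = 0
    R_c2 = rotation_about_axis(Z, 180.0)
    for pf in range(n_pf):
        for k in range(spec.n_rungs):
            R = rotation_about_axis(Z, k * spec.twist_deg)
            t = np.array([0.0, 0.0, k * spec.rise_A])
            if pf == 1:
                R = R @ R_c2
            cid = letters[ci]
            ci += 1
            chains.append(Chain(cid, _copy_residues(rung0, R, t)))
            protofilament_of[cid] = pf
            rung_of[cid] = k - spec.n_rungs // 2
    if spec.noise_sd_A > 0:
        rng = np.random.default_rng(spec.seed)
        for c in chains:
            for a in c.atoms():
                a.coord = a.coord + rng.normal(0.0, spec.noise_sd_A, 3)
    asm = FibrilAssembly(chains=chains, label=f"synthetic_{spec.template}")
    asm.protofilament_of = protofilament_of
    asm.rung_of = rung_of
    asm.symmetry = spec.symmetry
    asm.axis_dir = Z.copy()
    asm.axis_point = np.zeros(3)
    return asm


# ------------------------------------------------------- small test motifs

_IDEAL = {
    ("N", "CA"): 1.458, ("CA", "C"): 1.525, ("C", "N"): 1.329, ("C", "O"): 1.231,
}
_ANGLES = {"N-CA-C": 111.2, "CA-C-N": 117.2, "C-N-CA": 121.7, "CA-C-O": 120.5}


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          dist: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension reference frame placement of a fourth atom."""
    th = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    bc = _unit(c - b)
    nplane = _unit(np.cross(b - a, bc))
    m = np.cross(nplane, bc)
    d2 = np.array([-dist * np.cos(th),
                   dist * np.sin(th) * np.cos(chi),
                   dist * np.sin(th) * np.sin(chi)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * nplane


def build_backbone(phi_psi_omega: Sequence[Tuple[float, float, float]],
                   names: Sequence[str]) -> List[Residue]:
    """Ideal-geometry backbone from (phi, psi, omega) per residue via NERF.

    omega[i] is the peptide bond *preceding* residue i+1 (i.e. applied when
    placing N of residue i+1); phi[0] is unused.
    """
    n = len(names)
    coords: List[Dict[str, np.ndarray]] = [dict() for _ in range(n)]
    coords[0]["N"] = np.array([0.0, 0.0, 0.0])
    coords[0]["CA"] = np.array([_IDEAL[("N", "CA")], 0.0, 0.0])
    th = np.deg2rad(_ANGLES["N-CA-C"])
    coords[0]["C"] = coords[0]["CA"] + _IDEAL[("CA", "C")] * np.array([-np.cos(th), np.sin(th), 0.0])
    for i in range(n - 1):
        phi_next, psi_i, omega_i = phi_psi_omega[i + 1][0], phi_psi_omega[i][1], phi_psi_omega[i][2]
        Ni, CAi, Ci = coords[i]["N"], coords[i]["CA"], coords[i]["C"]
        N1 = _nerf(Ni, CAi, Ci, _IDEAL[("C", "N")], _ANGLES["CA-C-N"], psi_i)
        coords[i]["O"] = _nerf(Ni, CAi, Ci, _IDEAL[("C", "O")], _ANGLES["CA-C-O"], psi_i - 180.0)
        CA1 = _nerf(CAi, Ci, N1, _IDEAL[("N", "CA")], _ANGLES["C-N-CA"], omega_i)
        C1 = _nerf(Ci, N1, CA1, _IDEAL[("CA", "C")], _ANGLES["N-CA-C"], phi_next)
        coords[i + 1]["N"], coords[i + 1]["CA"], coords[i + 1]["C"] = N1, CA1, C1
    # terminal O
    last = n - 1
    coords[last]["O"] = _nerf(coords[last]["N"], coords[last]["CA"], coords[last]["C"],
                              _IDEAL[("C", "O")], _ANGLES["CA-C-O"],
                              phi_psi_omega[last][1] - 180.0)
    residues = []
    serial = 0
    for i, nm in enumerate(names):
        atoms = []
        for an in ("N", "CA", "C", "O"):
            serial += 1
            atoms.append(Atom(serial, an, element_of(an), coords[i][an]))
        residues.append(Residue(seq_id=i + 1, name=nm, atoms=atoms))
    return residues


def _single_chain_assembly(residues: List[Residue], label: str,
                           chain_id: str = "A") -> FibrilAssembly:
    asm = FibrilAssembly(chains=[Chain(chain_id, residues)], label=label)
    asm.protofilament_of = {chain_id: 0}
    asm.rung_of = {chain_id: 0}
    asm.symmetry = "C1"
    return asm


def salt_bridge_dimer(nh_od_distance: float = 3.5) -> FibrilAssembly:
    """Arg and Asp single-residue chains facing each other, with the closest
    NH1–OD1 pair at the requested distance (an ionic-lock fixture)."""
    path = np.array([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [7.6, 0.0, 0.0]])
    seq_signs = [1, 1, 1]
    arg = build_rung_atoms(path, "ARA", 1, side_signs=seq_signs)
    asp = build_rung_atoms(path, "ADA", 101, side_signs=[-1, -1, -1])
    # Arg side chain points +y reaching ~ y=+8.0 (NH tips); Asp at y0 points -y
    # reaching ~ -4.3 from its CA. Position the Asp chain so NH1-OD1 = target.
    a_asm = FibrilAssembly(chains=[Chain("A", arg)])
    nh1 = a_asm.chain("A").residue(2).coord("NH1")
    b_asm = FibrilAssembly(chains=[Chain("B", asp)])
    od1 = b_asm.chain("B").residue(102).coord("OD1")
    target = nh1 + np.array([0.0, nh_od_distance, 0.0])
    shift = target - od1
    asp_shifted = _copy_residues(asp, np.eye(3), shift)
    asm = FibrilAssembly(chains=[Chain("A", arg), Chain("B", asp_shifted)],
                         label="salt_bridge_dimer")
    asm.protofilament_of = {"A": 0, "B": 1}
    asm.rung_of = {"A": 0, "B": 0}
    asm.symmetry = "C1"
    asm.axis_dir = Z.copy()
    asm.axis_point = np.zeros(3)
    return asm


def build_test_motifs() -> Dict[str, FibrilAssembly]:
    """Constructed fixtures exercising each detector.

    Keys: ``alpha_helix`` (20-residue ideal helix), ``beta_hairpin``
    (antiparallel two-strand hairpin with in-plane H-bonds),
    ``salt_bridge_3p5``/``salt_bridge_4p5`` (Arg–Asp dimers at/beyond the
    ionic cutoff), ``ala_dipeptide``, ``cis_proline`` and ``trans_proline``
    dipeptides (ω = 0°/180°).
    """
    motifs: Dict[str, FibrilAssembly] = {}
    helix = build_backbone([(-57.0, -47.0, 180.0)] * 20, ["ALA"] * 20)
    motifs["alpha_helix"] = _single_chain_assembly(helix, "alpha_helix")

    # hairpin: arms along ±x at y = 0 / 4.8, amide/carbonyl axes pointing at
    # each other across the gap -> every aligned pair H-bonds both ways
    n_arm, gap = 8, 4.8
    pts, axes = [], []
    for i in range(n_arm):
        pts.append([i * 3.8, 0.0, 0.0])
        axes.append(np.array([0.0, 1.0, 0.0]))
    for k, th in enumerate(np.linspace(np.pi / 2, -np.pi / 2, 4)[1:-1], start=1):
        pts.append([(n_arm - 1) * 3.8 + (gap / 2) * np.cos(th), gap / 2 + (gap / 2) * np.sin(th), 2.0 * k])
        axes.append(np.array([0.0, 1.0, 0.0]))
    for j in range(n_arm):
        pts.append([(n_arm - 2 - j) * 3.8, gap, 0.0])
        axes.append(np.array([0.0, -1.0, 0.0]))
    path = np.asarray(pts)
    residues = []
    serial = 0
    tang = _tangents(path)
    for i in range(len(path)):
        w = axes[i]
        a = path[i]
        t = tang[i]
        atoms = []
        for name, coord in [("N", a - 1.2 * t + 0.35 * w), ("CA", a.copy()),
                            ("C", a + 1.2 * t + 0.35 * w), ("O", a + 1.2 * t + 1.58 * w)]:
            serial += 1
            atoms.append(Atom(serial, name, element_of(name), coord))
        residues.append(Residue(seq_id=i + 1, name="ALA", atoms=atoms))
    motifs["beta_hairpin"] = _single_chain_assembly(residues, "beta_hairpin")

    motifs["salt_bridge_3p5"] = salt_bridge_dimer(3.5)
    motifs["salt_bridge_4p5"] = salt_bridge_dimer(4.5)

    ala2 = build_backbone([(-120.0, 120.0, 180.0)] * 2, ["ALA", "ALA"])
    motifs["ala_dipeptide"] = _single_chain_assembly(ala2, "ala_dipeptide")

    for nm, omega in (("cis_proline", 0.0), ("trans_proline", 180.0)):
        res = build_backbone([(-70.0, 150.0, omega), (-75.0, 145.0, 180.0)],
                             ["ALA", "PRO"])
        motifs[nm] = _single_chain_assembly(res, nm)
    return motifs
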