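"""Helical (screw) parameters, crossover distance, axial spans and tilts.

The fibril is modelled as a discrete helix: consecutive rungs of a
protofilament are related by a screw operation of ``twist_deg`` about the
fibril axis plus ``rise_A`` along it. Twist is signed — negative means a
left-handed helix. The crossover distance is the axial length over which the
fibril completes a half turn (180°), the repeat visible in projection images
of two-protofilament fibrils.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from ._geom import kabsch, principal_axis, screw_decompose
from .config import merged
from .core import FibrilAssembly, GeometryError


@dataclass
class HelicalParameters:
    """Per-protofilament screw parameters averaged over rung pairs."""

    twist_deg: float
    rise_A: float
    axis_point: np.ndarray
    axis_dir: np.ndarray
    n_pairs: int = 0
    pair_rmsd_A: List[float] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    @property
    def handedness(self) -> str:
        return "left" if self.twist_deg < 0 else "right"

    @property
    def crossover_A(self) -> float:
        return crossover_distance(self.twist_deg, self.rise_A)


@dataclass
class SegmentGeometry:
    residue_range: Tuple[int, int]
    tilt_deg: float
    axial_span_A: float


def estimate_screw(assembly: FibrilAssembly, config: Optional[dict] = None) -> HelicalParameters:
    """Estimate twist/rise by screw-decomposing consecutive-rung transforms.

    For every consecutive rung pair in every protofilament the optimal rigid
    superposition (shared Cα atoms) is computed and decomposed into rotation
    about / translation along the screw axis; parameters are averaged over
    pairs. Pairs superposing worse than ``geometry.pair_rmsd_warn`` are kept
    but recorded as warnings.
    """
    cfg = merged(config)["geometry"]
    assembly.require_topology()
    if assembly.axis_dir is None:
        raise GeometryError("no fibril axis: assembly has no stacked chains")
    ref_axis = assembly.axis_dir

    angles: List[float] = []
    rises: List[float] = []
    axes: List[np.ndarray] = []
    points: List[np.ndarray] = []
    rmsds: List[float] = []
    warnings: List[str] = []
    for p in range(assembly.n_protofilaments):
        rungs = assembly.rungs_of_protofilament(p)
        order = sorted(rungs)
        for r0, r1 in zip(order, order[1:]):
            if r1 != r0 + 1:
                continue
            a, b = rungs[r0], rungs[r1]
            common = [s for s in a.seq_ids if b.residue(s) is not None
                      and a.residue(s).coord("CA") is not None
                      and b.residue(s).coord("CA") is not None]
            if len(common) < 3:
                continue
            R, t, rmsd = kabsch(a.ca_coords(common), b.ca_coords(common))
            if rmsd > cfg["pair_rmsd_warn"]:
                warnings.append(f"rung pair ({p}:{r0}->{r1}) superposes at {rmsd:.2f} A RMSD")
            angle, rise, u, pt = screw_decompose(R, t, ref_axis)
            angles.append(angle)
            rises.append(abs(rise))
            axes.append(u if u @ ref_axis > 0 else -u)
            points.append(pt)
            rmsds.append(rmsd)
    if not angles:
        raise GeometryError("screw estimation needs at least one protofilament with >= 2 rungs")
    axis_dir = np.mean(axes, axis=0)
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    return HelicalParameters(
        twist_deg=float(np.mean(angles)),
        rise_A=float(np.mean(rises)),
        axis_point=np.mean(points, axis=0),
        axis_dir=axis_dir,
        n_pairs=len(angles),
        pair_rmsd_A=rmsds,
        warnings=warnings,
    )


def crossover_distance(twist_deg: float, rise_A: float) -> float:
    """Axial distance for a 180° rotation: (180 / |twist|) x rise, Å.

    This half-turn definition reproduces the apparent crossover repeat of a
    two-protofilament fibril in projection.
    """
    if twist_deg == 0:
        raise GeometryError("zero twist: crossover distance is infinite")
    if rise_A <= 0:
        raise GeometryError("rise must be positive")
    return (180.0 / abs(twist_deg)) * rise_A


def _axis(assembly: FibrilAssembly) -> np.ndarray:
    if assembly.axis_dir is None:
        raise GeometryError("fibril axis not assigned; run assign_topology/estimate_screw")
    return assembly.axis_dir


def axial_span(assembly: FibrilAssembly, chain_id: str) -> float:
    """Extent of one chain's Cα trace along the fibril axis, Å (max - min)."""
    u = _axis(assembly)
    ca = assembly.chain(chain_id).ca_coords()
    z = ca @ u
    return float(z.max() - z.min())


def layer_crossing(assembly: FibrilAssembly, chain_id: str, rise_A: float) -> float:
    """How many rung layers a chain traverses: axial span / rise."""
    if rise_A <= 0:
        raise GeometryError("rise must be positive")
    return axial_span(assembly, chain_id) / rise_A


def segment_tilt(assembly: FibrilAssembly, chain_id: str,
                 residue_range: Tuple[int, int]) -> SegmentGeometry:
    """Tilt of a segment's best-fit Cα line against the plane normal to the axis.

    0° means the segment lies in a rung plane; 90° means it runs along the
    fibril axis. The best-fit line is the principal axis of the Cα scatter.
    """
    u = _axis(assembly)
    lo, hi = residue_range
    chain = assembly.chain(chain_id)
    ids = [s for s in chain.seq_ids if lo <= s <= hi]
    ca = chain.ca_coords(ids)
    if len(ca) < 3:
        raise GeometryError(f"segment {lo}-{hi}: fewer than 3 residues with CA")
    line = principal_axis(ca)
    tilt = float(np.degrees(np.arcsin(np.clip(abs(line @ u), 0.0, 1.0))))
    z = ca @ u
    return SegmentGeometry(residue_range=(lo, hi), tilt_deg=tilt,
                           axial_span_A=float(z.max() - z.min()))
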