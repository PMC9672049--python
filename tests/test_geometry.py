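"""Screw parameter estimation, crossover, spans and tilts."""

import numpy as np
import pytest

from crossbeta._geom import rotation_about_axis
from crossbeta.core import GeometryError
from crossbeta.geometry import (axial_span, crossover_distance, estimate_screw,
                                layer_crossing, segment_tilt)
from crossbeta.synthetic import FibrilSpec, build_fibril
from crossbeta.topology import assign_topology

TWISTS = [0.5, 1.0, 1.3, 2.0, 4.0]
RISES = [4.7, 4.75, 4.9]


def _fresh(spec, stack_rmsd=1.0):
    asm = build_fibril(spec)
    asm.protofilament_of = {}
    asm.rung_of = {}
    asm.axis_dir = None
    # wide-twist fibrils displace atoms by radius x twist between rungs, so
    # the translation-only stacking check needs a proportionate threshold
    return assign_topology(asm, {"topology": {"stack_rmsd": stack_rmsd}})


@pytest.mark.parametrize("twist", TWISTS)
@pytest.mark.parametrize("rise", RISES)
def test_noiseless_parameter_recovery_grid(twist, rise):
    # hairpin template: non-collinear CA trace, so the inter-rung rotation is
    # fully determined (a perfectly straight strand leaves spin about its own
    # axis unconstrained)
    asm = _fresh(FibrilSpec(template="hairpin", n_res=24, sequence="A" * 24,
                            n_rungs=3, symmetry="C1", twist_deg=-twist, rise_A=rise),
                 stack_rmsd=2.5)
    hp = estimate_screw(asm)
    assert abs(abs(hp.twist_deg) - twist) < 0.01
    assert abs(hp.rise_A - rise) < 0.01
    assert hp.handedness == "left" if hp.twist_deg < 0 else "right"
    # crossover consistency within 0.1%
    assert hp.crossover_A == pytest.approx((180.0 / twist) * rise, rel=1e-3)


def test_twist_recovery_under_noise():
    """Gaussian coordinate noise sigma = 0.2 A: twist recovered within 0.1 deg
    for every one of 20 seeds."""
    errs = []
    for seed in range(20):
        asm = _fresh(FibrilSpec(template="meander", n_res=76, sequence="A" * 76,
                                n_rungs=5, symmetry="C2", arm_gap_A=9.5,
                                twist_deg=-1.3, rise_A=4.9,
                                noise_sd_A=0.2, seed=seed),
                     stack_rmsd=2.0)
        hp = estimate_screw(asm)
        errs.append(abs(abs(hp.twist_deg) - 1.3))
    assert max(errs) < 0.1


def test_estimates_invariant_under_rigid_motion(default_fibril_retopo):
    asm = default_fibril_retopo
    hp0 = estimate_screw(asm)
    R = rotation_about_axis(np.array([0.3, -1.0, 0.7]), -119.0)
    moved = asm.transformed(R, np.array([5.0, 6.0, 7.0]))
    moved.protofilament_of = {}
    moved.rung_of = {}
    moved.axis_dir = None
    assign_topology(moved)
    hp1 = estimate_screw(moved)
    assert abs(hp1.twist_deg) == pytest.approx(abs(hp0.twist_deg), abs=1e-6)
    assert hp1.rise_A == pytest.approx(hp0.rise_A, abs=1e-6)


def test_crossover_closed_forms():
    assert crossover_distance(1.3, 4.9) == pytest.approx(678.4615384615, abs=1e-6)
    assert crossover_distance(1.0, 4.75) == pytest.approx(855.0, abs=1e-9)
    for rise in (2.0, 4.75, 10.0):
        assert crossover_distance(180.0, rise) == pytest.approx(rise)
    with pytest.raises(GeometryError):
        crossover_distance(0.0, 4.9)


def test_screw_requires_two_rungs():
    asm = _fresh(FibrilSpec(template="straight_strand", n_res=12, sequence="A" * 12,
                            n_rungs=1, symmetry="C1"))
    with pytest.raises(GeometryError):
        estimate_screw(asm)


def test_axial_span_planar_chain_is_zero(default_fibril_retopo):
    for cid in default_fibril_retopo.chain_ids:
        assert axial_span(default_fibril_retopo, cid) == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("alpha", [5.0, 15.0, 30.0])
def test_axial_span_of_tilted_straight_chain_is_analytic(alpha):
    n = 20
    # untwisted stack: a straight (collinear) chain leaves the inter-rung
    # rotation degenerate, so the analytic construction uses twist 0
    asm = _fresh(FibrilSpec(template="straight_strand", n_res=n, sequence="A" * n,
                            n_rungs=3, symmetry="C1", twist_deg=0.0,
                            tilt_segments=[(0, n - 1, alpha)]))
    cid = asm.chains[0].chain_id
    expected = (n - 1) * 3.8 * np.sin(np.deg2rad(alpha))
    assert axial_span(asm, cid) == pytest.approx(expected, abs=1e-6)
    assert layer_crossing(asm, cid, 4.9) == pytest.approx(expected / 4.9, abs=1e-6)


@pytest.mark.parametrize("alpha", [0.0, 10.0, 15.0])
def test_segment_tilt_recovers_construction(alpha):
    n = 20
    asm = _fresh(FibrilSpec(template="straight_strand", n_res=n, sequence="A" * n,
                            n_rungs=3, symmetry="C1", twist_deg=0.0,
                            tilt_segments=[(0, n - 1, alpha)]))
    cid = asm.chains[0].chain_id
    seg = segment_tilt(asm, cid, (19, 19 + n - 1))
    assert seg.tilt_deg == pytest.approx(alpha, abs=1e-6)


def test_segment_tilt_invariant_under_rotation(default_fibril_retopo):
    asm = default_fibril_retopo
    cid = asm.interior_chain_ids()[0]
    t0 = segment_tilt(asm, cid, (19, 49)).tilt_deg
    R = rotation_about_axis(np.array([1.0, 1.0, 0.2]), 37.0)
    moved = asm.transformed(R, np.zeros(3))
    t1 = segment_tilt(moved, cid, (19, 49)).tilt_deg
    assert t1 == pytest.approx(t0, abs=1e-9)
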