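"""Shared fixtures: synthetic assemblies are built once per session (SASA
results are content-cached, so reuse across tests is cheap)."""

import numpy as np
import pytest

from crossbeta.synthetic import (FibrilSpec, build_fibril, build_test_motifs,
                                 saa_like_spec)
from crossbeta.topology import assign_topology, detect_symmetry


@pytest.fixture(scope="session")
def default_fibril():
    """Study-condition fibril: C2, 2x5 rungs, 76-residue meander, −1.3°/4.9 Å."""
    return build_fibril(saa_like_spec())


@pytest.fixture(scope="session")
def default_fibril_retopo():
    """Same fibril with topology re-derived from geometry (not generator truth)."""
    asm = build_fibril(saa_like_spec())
    asm.protofilament_of = {}
    asm.rung_of = {}
    asm.axis_dir = None
    assign_topology(asm)
    detect_symmetry(asm)
    return asm


@pytest.fixture(scope="session")
def motifs():
    return build_test_motifs()


@pytest.fixture(scope="session")
def single_stack():
    """C1 single protofilament: 4 rungs of a 20-residue straight strand."""
    return build_fibril(FibrilSpec(template="straight_strand", n_res=20,
                                   sequence="A" * 20, n_rungs=4, symmetry="C1",
                                   twist_deg=-1.3, rise_A=4.9))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
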