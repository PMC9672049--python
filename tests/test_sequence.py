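"""Alignment vs an exhaustive DP oracle; identity; tolerance rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossbeta.core import SequenceRecord
from crossbeta.sasa import BurialClass
from crossbeta.sequence import (align_pair, classify_substitution,
                                identity_table, tolerance_map)
from crossbeta.synthetic import (synthetic_core_record, synthetic_distant_record,
                                 synthetic_variant_record)

AA = "ACDEFGHIKLMNPQRSTVWY"


def gotoh_score(a: str, b: str, matrix, open_=-11.0, ext=-1.0) -> float:
    """Independent affine-gap global alignment score (Gotoh recurrences);
    gap of length k costs open + (k-1)*ext, end gaps penalized."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a aligned to gap)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = open_ + (i - 1) * ext
    for j in range(1, m + 1):
        Y[0, j] = open_ + (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + ext, Y[i - 1, j] + open_)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + ext, X[i, j - 1] + open_)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def test_alignment_score_matches_dp_oracle_on_random_pairs():
    from Bio.Align import substitution_matrices
    blosum = substitution_matrices.load("BLOSUM62")
    rng = np.random.default_rng(42)
    for _ in range(100):
        la, lb = rng.integers(1, 13, size=2)
        sa = "".join(rng.choice(list(AA), la))
        sb = "".join(rng.choice(list(AA), lb))
        res = align_pair(SequenceRecord("a", sa), SequenceRecord("b", sb))
        assert res.score == pytest.approx(gotoh_score(sa, sb, blosum), abs=1e-9)


def test_identity_trivial_cases():
    r = align_pair(SequenceRecord("a", "ACDE"), SequenceRecord("b", "ACDE"))
    assert r.identity_pct == 100.0
    r = align_pair(SequenceRecord("a", "AAAA"), SequenceRecord("b", "AAAT"))
    assert r.identity_pct == 75.0


def test_identity_symmetric():
    a = synthetic_core_record()
    b = synthetic_distant_record()
    assert align_pair(a, b).identity_pct == pytest.approx(
        align_pair(b, a).identity_pct, abs=1e-9)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.text(alphabet=AA, min_size=1, max_size=15),
       st.text(alphabet=AA, min_size=1, max_size=15))
def test_identity_bounded_and_symmetric(sa, sb):
    a, b = SequenceRecord("a", sa), SequenceRecord("b", sb)
    r = align_pair(a, b)
    assert 0.0 <= r.identity_pct <= 100.0
    assert r.identity_pct == pytest.approx(align_pair(b, a).identity_pct, abs=1e-9)


def test_terminal_gaps_excluded_from_identity():
    core = SequenceRecord("core", "MKVLATGFFW")
    precursor = SequenceRecord("pre", "AAAA" + "MKVLATGFFW" + "CCCC")
    r = align_pair(core, precursor)
    assert r.identity_pct == 100.0


def test_single_substitution_reports_99_percent():
    r = align_pair(synthetic_core_record(), synthetic_variant_record(),
                   numbering_offset=18)
    assert r.identity_pct_reported == 99
    assert r.substitutions == [(93, "N", "S")]


def test_distant_ortholog_identity_above_70():
    r = align_pair(synthetic_core_record(), synthetic_distant_record())
    assert 70.0 < r.identity_pct < 90.0


def test_identity_table_structure():
    tab = identity_table(synthetic_core_record(),
                         [synthetic_variant_record(), synthetic_distant_record()],
                         region=(19, 94), numbering_offset=18)
    assert list(tab["identity_pct_reported"]) == [99, 76]
    assert set(tab["region"]) == {"19-94"}


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        align_pair(SequenceRecord("a", ""), SequenceRecord("b", "ACD"))


# ---- substitution tolerance rules -----------------------------------------

def _burial(label):
    return BurialClass(chain_id="A", labels={50: label}, rel_asa={50: 0.5})


@pytest.mark.parametrize("ref,alt,label,expected", [
    ("N", "S", "exposed", "tolerated"),                 # small polar swap, surface
    ("A", "S", "exposed", "tolerated"),
    ("L", "K", "buried", "not_tolerated"),              # charge into the core
    ("L", "W", "buried", "not_tolerated"),              # large volume increase
    ("L", "I", "buried", "tolerated"),                  # conservative same-class swap
    ("L", "A", "buried", "tolerated_with_adjustments"), # cavity-creating shrink
    ("S", "R", "partially_buried", "tolerated_with_adjustments"),
    ("S", "T", "partially_buried", "tolerated"),
])
def test_tolerance_rules(ref, alt, label, expected):
    call = classify_substitution(50, ref, alt, _burial(label))
    assert call.label == expected


def test_proline_mid_strand_is_flagged():
    call = classify_substitution(50, "A", "P", _burial("exposed"), in_strand=True)
    assert call.label == "tolerated_with_adjustments"


def test_unmodeled_position_classified_from_sequence():
    call = classify_substitution(999, "N", "S", _burial("exposed"))
    assert call.from_sequence_only
    assert call.label == "tolerated"


def test_variant_substitution_tolerated_on_structure(default_fibril):
    """The single exposed Asn->Ser change of the synthetic variant is fully
    compatible with the fibril structure."""
    aln = align_pair(synthetic_core_record(), synthetic_variant_record(),
                     numbering_offset=18)
    calls = tolerance_map(default_fibril, aln)
    assert len(calls) == 1
    assert calls[0].position == 93
    assert calls[0].label == "tolerated"
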