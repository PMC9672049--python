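"""Pairwise global alignment, percent identity and substitution tolerance.

Alignment is Needleman–Wunsch with affine gaps (BLOSUM62, open −11 /
extend −1 by default) via Biopython's PairwiseAligner. Percent identity uses
alignment columns excluding terminal-gap columns, so comparing a fibril-core
fragment against a full precursor reports identity over the shared region;
internal gaps count as mismatches. Reported identity is rounded half-up to
an integer, the convention used when quoting "99% identical".

Substitution tolerance against a fibril structure is a rule-based
classification from burial class, side-chain volume change and charge:
an explicit codification of the "simple structural considerations" used to
colour substitution maps green/yellow/red.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .config import RESIDUE_VOLUME, merged
from .core import FibrilAssembly, SequenceRecord
from .sasa import BurialClass, classify_burial

_NEGATIVE = set("DE")
_POSITIVE = set("KRH")
_CLASSES = {
    "hydrophobic": set("AVLIMFWY"),
    "polar": set("STNQC"),
    "positive": _POSITIVE,
    "negative": _NEGATIVE,
    "special": set("GP"),
}


@dataclass
class AlignmentResult:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float                   # exact value
    substitutions: List[Tuple[int, str, str]] = field(default_factory=list)

    @property
    def identity_pct_reported(self) -> int:
        """Identity rounded half-up to an integer for reporting."""
        return int(math.floor(self.identity_pct + 0.5))


@dataclass
class ToleranceCall:
    position: int
    ref_residue: str
    alt_residue: str
    label: str                            # tolerated | tolerated_with_adjustments | not_tolerated
    reason: str = ""
    from_sequence_only: bool = False


def _aligner(cfg: dict) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(cfg["matrix"])
    aligner.open_gap_score = cfg["gap_open"]
    aligner.extend_gap_score = cfg["gap_extend"]
    return aligner


def align_pair(a: SequenceRecord, b: SequenceRecord,
               numbering_offset: int = 0,
               config: Optional[dict] = None) -> AlignmentResult:
    """Global alignment of two sequences with identity and substitution list.

    ``numbering_offset``: author number of position 1 of sequence ``a`` minus
    one (e.g. 18 when the first residue of ``a`` is precursor residue 19), so
    substitution positions are reported in author numbering.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align an empty sequence")
    cfg = merged(config)["sequence"]
    aln = _aligner(cfg).align(a.sequence, b.sequence)[0]
    ga, gb = str(aln[0]), str(aln[1])
    # terminal-gap window: columns where both sequences have started/not ended
    def core(s: str) -> Tuple[int, int]:
        start = len(s) - len(s.lstrip("-"))
        end = len(s.rstrip("-"))
        return start, end
    sa, ea = core(ga)
    sb, eb = core(gb)
    lo, hi = max(sa, sb), min(ea, eb)
    n_cols = hi - lo
    if n_cols <= 0:
        raise ValueError("alignment has no overlapping columns")
    identities = sum(1 for k in range(lo, hi) if ga[k] == gb[k] and ga[k] != "-")
    subs: List[Tuple[int, str, str]] = []
    pos_a = 0
    for k in range(len(ga)):
        if ga[k] != "-":
            pos_a += 1
        if lo <= k < hi and ga[k] != "-" and gb[k] != "-" and ga[k] != gb[k]:
            subs.append((pos_a + numbering_offset, ga[k], gb[k]))
    return AlignmentResult(
        id_a=a.id, id_b=b.id, aligned_a=ga, aligned_b=gb,
        score=float(aln.score),
        identity_pct=100.0 * identities / n_cols,
        substitutions=subs,
    )


def identity_table(reference: SequenceRecord, others: Sequence[SequenceRecord],
                   region: Optional[Tuple[int, int]] = None,
                   numbering_offset: int = 0,
                   config: Optional[dict] = None) -> pd.DataFrame:
    """Percent identity of each sequence against the reference.

    ``region`` restricts the reference to author positions start..end before
    aligning (the fibril-core convention); the table records the region used.
    """
    ref = reference
    if region is not None:
        ref = reference.region(region[0], region[1], numbering_offset)
    rows = []
    for other in others:
        res = align_pair(ref, other, config=config)
        rows.append({
            "reference": reference.id,
            "other": other.id,
            "region": f"{region[0]}-{region[1]}" if region else "full",
            "identity_pct": res.identity_pct,
            "identity_pct_reported": res.identity_pct_reported,
            "n_substitutions": len(res.substitutions),
        })
    return pd.DataFrame(rows)


def _charge(one: str) -> int:
    if one in _POSITIVE:
        return 1
    if one in _NEGATIVE:
        return -1
    return 0


def _same_class(a: str, b: str) -> bool:
    return any(a in cls and b in cls for cls in _CLASSES.values())


def classify_substitution(position: int, ref_residue: str, alt_residue: str,
                          burial: Optional[BurialClass] = None,
                          in_strand: bool = False,
                          config: Optional[dict] = None) -> ToleranceCall:
    """Rule-based tolerance of one substitution at a structure position.

    Rules (volume tolerance 40 Å³, configurable): exposed positions tolerate
    anything except a mid-strand proline; partially buried positions need
    adjustments for large volume or charge changes; buried positions reject
    introduced charge or large volume increases and otherwise need
    adjustments; conservative same-class swaps within the volume budget are
    tolerated everywhere. Positions absent from the structure are classified
    from sequence alone and flagged.
    """
    cfg = merged(config)["sequence"]
    vol_tol = cfg["volume_tolerance_A3"]
    ref, alt = ref_residue.upper(), alt_residue.upper()
    dvol = RESIDUE_VOLUME.get(alt, 140.0) - RESIDUE_VOLUME.get(ref, 140.0)
    charge_change = _charge(ref) != _charge(alt)
    conservative = _same_class(ref, alt) and abs(dvol) <= vol_tol

    label_src: Optional[str] = None
    if burial is not None and position in burial.labels:
        label_src = burial.labels[position]
    if label_src is None:
        # sequence-only fallback
        if conservative:
            call = ("tolerated", "conservative swap (sequence only)")
        elif charge_change or abs(dvol) > vol_tol:
            call = ("tolerated_with_adjustments", "charge/volume change (sequence only)")
        else:
            call = ("tolerated", "minor change (sequence only)")
        return ToleranceCall(position, ref, alt, call[0], call[1], from_sequence_only=True)

    if label_src == "exposed":
        if alt == "P" and in_strand:
            return ToleranceCall(position, ref, alt, "tolerated_with_adjustments",
                                 "proline introduced mid-strand")
        return ToleranceCall(position, ref, alt, "tolerated", "exposed position")
    if conservative:
        return ToleranceCall(position, ref, alt, "tolerated", "conservative same-class swap")
    if label_src == "partially_buried":
        if abs(dvol) > vol_tol or charge_change:
            return ToleranceCall(position, ref, alt, "tolerated_with_adjustments",
                                 "volume/charge change at partially buried position")
        return ToleranceCall(position, ref, alt, "tolerated", "small neutral change")
    # buried
    if (_charge(alt) != 0 and _charge(ref) == 0) or dvol > vol_tol:
        return ToleranceCall(position, ref, alt, "not_tolerated",
                             "charge or volume increase in buried core")
    return ToleranceCall(position, ref, alt, "tolerated_with_adjustments",
                         "buried position, repackable change")


def tolerance_map(assembly: FibrilAssembly, alignment: AlignmentResult,
                  chain_id: Optional[str] = None,
                  strand_positions: Optional[set] = None,
                  config: Optional[dict] = None) -> List[ToleranceCall]:
    """Tolerance calls for every substitution in an alignment, using the
    assembly's burial classification (interior chain by default)."""
    burial = classify_burial(assembly, chain_id, config=config)
    strand_positions = strand_positions or set()
    return [classify_substitution(pos, ref, alt, burial,
                                  in_strand=pos in strand_positions, config=config)
            for pos, ref, alt in alignment.substitutions]
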