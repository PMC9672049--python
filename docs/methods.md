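# Methods

This note documents the models, numerical choices and known limits of the
analyses in `crossbeta`. Every default named here lives in
`crossbeta.config` under one namespace per module and is echoed into
reports, so a result can always be traced to the exact thresholds that
produced it.

## Coordinate model and reduction

Structures are reduced to a single-conformer, hydrogen-free, heavy-atom
model: waters and hetero compounds are dropped, the highest-occupancy
altloc wins (ties broken by altloc identifier), hydrogens are removed, and
author residue numbering is preserved everywhere — for SAA-derived fibrils
that is the precursor numbering in which the modelled core runs 19–94.
Van der Waals radii are the Bondi (1964) set; an element without a tabulated
radius is an error, never a silent default.

## Protofilament topology and rung indexing

Two chains stack when (i) their reference points (Cα centroids by default; a
`rung_ref` residue reproduces conventions that level rungs on a specific
residue) are closer than 1.5× the rise scale (default 4.9 Å) and (ii) their
shared-residue Cα traces superpose under **pure translation** with RMSD
below `topology.stack_rmsd` (1 Å). Translation-only superposition is
deliberate: at a per-rung twist of ~1°, rotation moves atoms well under 1 Å,
so stacking detection needs no prior axis. For strongly twisted assemblies
the threshold scales with (radius × twist); it is a config key.

Protofilaments are the connected components of the stacking graph. The fibril
axis is first estimated from stacking displacement vectors, then refined
from the actual inter-rung rotation axes (the displacement estimate is
biased by the lateral component radius × twist; the rotation axis is not).
Chains whose Cα trace is essentially collinear are excluded from the
refinement because their inter-rung rotation is not identifiable. Rung
indices count axial order with rung 0 at each protofilament's median chain,
and protofilaments are levelled against each other by rounding their axial
offset to whole rises, so chains at one level share an index.

C2 symmetry is declared when a 180° rotation about the fibril axis (axis
position optimized in closed form from pair midpoints, axial shift free,
rung-offset search ±2) maps one protofilament onto the other with Cα RMSD
below 2 Å. One protofilament, or more than two, is reported C1.

## Screw parameters and crossover

For each consecutive rung pair the optimal rigid transform (Kabsch, proper
rotation enforced) is decomposed into a rotation angle about the axis — sign
taken relative to the fibril axis, negative = left-handed — and the
translation component along it; twist and rise are the averages over pairs.
Pairs superposing worse than 2 Å RMSD are kept but recorded as warnings.
The crossover distance is defined as the **half-turn** axial length
(180/|θ|)·d: that is the repeat distance a two-protofilament fibril shows in
projection, and it is the definition consistent with quoting ~680 Å for
1.3°/4.9 Å (a full-turn definition would give ~1357 Å). Segment tilt is the
angle between the principal axis of a residue range's Cα scatter and the
plane normal to the fibril axis (0° = lies in a rung plane); a segment
collinear with the axis returns 90°.

## Secondary structure and peptide isomers

H-bonds use the Kabsch–Sander electrostatic model, E = 0.084·332·(1/r_ON +
1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with the standard −0.5 kcal/mol cutoff.
Deposited fibril models carry no hydrogens, so the amide H is reconstructed
1.0 Å from N along the direction opposing the bisector of C(i−1)–N and
CA–N; prolines and chain-start residues do not donate. β-bridges follow the
Kabsch–Sander parallel/antiparallel definitions with partners in any chain
(|Δseq| ≥ 3 within a chain); ladders of at least two consecutive bridges
mark strand residues, and strands are maximal runs of at least two. In a
cross-β fibril these H-bonds run between rungs, so a chain is always
assigned in its assembly context.

ω is the CA(i−1)–C(i−1)–N(i)–CA(i) dihedral; cis iff |ω| ≤ 30°, trans iff
|ω| ≥ 150°, otherwise "twisted". The bands are symmetric and exhaustive, and
the numeric ω is always reported alongside the label because near-threshold
assignments in ~3 Å maps are genuinely uncertain. Bonds across chain breaks
(consecutive Cα > 4.5 Å) are skipped.

## Surface areas, burial, interfaces

SASA is Shrake–Rupley with a 1.4 Å probe and a deterministic golden-spiral
point set, 1920 points per atom by default — the resolution at which the
quadrature agrees with a 10⁶-point Monte-Carlo reference to ~1% on occluded
atoms (the spiral is exact on isolated spheres at any count). Determinism
matters more than speed here: identical input gives bit-identical areas, so
the energies built on SASA are reproducible; results are content-cached.
Rigid-body invariance is approximate at the 0.1% level because the point set
has a fixed orientation.

Burial classes use relative SASA against the theoretical Gly-X-Gly maxima
(Tien et al. 2013): buried < 10%, exposed > 40%, partially buried between.
The two thresholds are config keys; they codify the three-way classification
that structure papers usually assign by eye.

Contacts are heavy-atom pairs: H-bond = N/O/S donor (with implicit H) to N/O
acceptor ≤ 3.5 Å with a ≥ 90° donor-antecedent angle; ionic lock = Arg/Lys/
His side-chain nitrogen to Asp/Glu carboxylate oxygen (or OXT) ≤ 4.0 Å;
hydrophobic = side-chain carbons of Ala/Val/Leu/Ile/Met/Phe/Trp/Pro (Tyr:
ring carbons only) ≤ 4.5 Å. Salt-bridge pairs are not double-counted as
H-bonds. Same-chain pairs with |Δseq| ≤ 2 are never interface contacts.
Contacts are attributed to intra-chain / intra-protofilament /
inter-protofilament interfaces and to a rung offset Δ = rung(partner) −
rung(reference); hydrophobic clusters are connected components of the
residue-level hydrophobic graph with ≥ 3 members. Published contact
inventories were produced by webservers with unstated settings, so counts at
these defaults may shift by ±1 per interface; the cutoff set used is always
reported with the counts. Interface area is half the SASA lost when the two
sides separate, recomputable directly from three SASA totals.

## Solvation stability

ΔG_sol of a chain is Σ σ(class)·[ASA(assembly) − ASA(chain alone)] +
E_HB·n, with the five-class Eisenberg–McLachlan (1986) atomic solvation
parameters (C +0.016, N/O −0.006, O⁻ −0.024, N⁺ −0.050, S +0.021
kcal mol⁻¹ Å⁻²). With this orientation burying carbon surface is
stabilizing (negative) and burying charged surface costs energy, which is
what makes hydrophobe-burying amyloid cores come out negative. The reference
state is the same chain conformation extracted alone — not an extended-chain
model — matching the "buried upon fibril formation" logic and requiring no
remodelling. n counts backbone H-bonds (Kabsch–Sander machinery) whose two
partner residues are both buried (< 10% relative SASA); E_HB defaults to
−0.6 kcal/mol per bond, a mid-range literature value for a water-shielded
backbone H-bond, and is a config key (`stability.e_hb`) because published
pipelines differ on it. A flag (`include_sidechain_hbonds`) exists for
side-chain H-bonds but defaults off.

ΔG_diss is the sign-flipped interaction solvation energy of the terminal
(highest-rung) chain — the same ASP sum over that chain plus E_HB times its
inter-chain backbone H-bonds, so a stable fibril end has ΔG_diss > 0. It is
a solvation-based estimate, not an assembly-thermodynamics calculation of
the PISA type; cross-method agreement should be judged at the
few-kcal/mol level.

## Sequence conservation and substitution tolerance

Alignments are global Needleman–Wunsch with affine gaps (BLOSUM62, open −11,
extend −1; Biopython's PairwiseAligner, verified against an independent
Gotoh implementation). Percent identity divides identities by alignment
columns **excluding terminal-gap columns**, so a fibril-core fragment scores
against the matching region of a full precursor; internal gaps count as
mismatches. Reported identities are rounded half-up to integers.

Tolerance rules (all parameters config): exposed positions tolerate any
substitution except a proline introduced mid-strand; a conservative
same-class swap within a 40 Å³ volume budget is tolerated anywhere;
partially buried positions need adjustments for larger volume or charge
changes; buried positions reject introduced charge or > 40 Å³ volume growth
and otherwise need adjustments. The classifier is advisory — it encodes
"simple structural considerations", not an energy calculation — and returns
its reasoning with each call.

## Synthetic fibril generator

The generator builds stacked-rung assemblies from a per-rung Cα path: rung k
is rung 0 rotated k·twist about z and translated k·rise; the C2 partner is
the 180° copy; seeded Gaussian noise, when requested, is applied after
symmetry expansion so symmetry detection under noise is a genuine test.
Backbone N/C/O are placed so carbonyls and amides point along the stacking
axis with alternating parity, which yields true Kabsch–Sander parallel
β-ladders between rungs. Side chains beyond Cβ exist only for the residue
types the detectors need (Arg, Asp, Glu, Lys, Leu, Val, Ser, Thr, Asn, Gln)
as idealized straight-arm rotamers; Leu/Val methyls splay along the axis so
stacked copies interdigitate into hydrophobic ladders.

The default spec mirrors the study conditions of a two-protofilament SAA
fibril: C2, five rungs per protofilament, 76-residue chains numbered 19–94,
twist −1.3°, rise 4.9 Å. The default path is a four-lane meander (lane gap
9.5 Å) rather than a single long hairpin so the chain stays within a
realistic ~50 Å cross-section radius — at 1.3°/rung, atoms at radius r shift
laterally by r·θ between rungs, and beyond ~70 Å that breaks the inter-rung
H-bond register that real, compactly folded fibril chains maintain. The
designed 76-mer sequence is synthetic (it is not an SAA sequence): an inner
lane carrying a mirror-symmetric Asp/Arg pair that forms ionic locks across
the C2 interface, Leu ladder columns in the middle lanes, and a polar outer
lane with an Asn at author position 93 whose N→S variant record emulates a
single-substitution ortholog (75/76 identities → 99% reported).

What the generator does **not** emulate: real rotamer geometry and packing
density (lanes leave solvent channels a real core excludes, so synthetic
ΔG_sol magnitudes are a few kcal/mol, not tens), sequence-dependent strand
breaks (idealized rungs ladder almost end to end, so strand counts merge),
chain tilt out of the rung plane unless requested, and polymorph variety.
Green synthetic tests therefore demonstrate estimator correctness —
exact parameter recovery, correct classifications, oracle-level energy
arithmetic — not that real fibrils attain particular values; the
published-value checks on deposited models cover that, and run only when
those public files are present (`data/reference/`).

## Numerical choices and degenerate inputs

Kabsch superposition enforces a proper rotation (smallest-singular-direction
flip). Screw decomposition takes the rotation axis from the skew part for
ordinary angles and the symmetric eigenvector near 180°; the axis point
solves (I − R)p = t⊥ by least squares, which is weakly conditioned for
near-identity rotations and reported for completeness only — twist, rise and
axis direction are the load-bearing outputs. Axis sign is fixed by making
the largest-magnitude component positive; rise is reported positive along
increasing rung index. Zero twist makes the crossover infinite and raises.
Collinear Cα sets are rejected where a rotation would be unidentifiable.
Alignment identity on non-overlapping sequences raises rather than returning
0. Reports serialize floats at ≥ 6 significant digits, and a fixed config
hash in each report header makes byte-identical reruns checkable.

## Known limitations

Topology assumes at most two protofilaments of one fold (no mixed-polymorph
bundles, no pseudo-2₁ screw detection). Secondary structure is three-state
(strand/turn/coil), not full 8-state. ΔG_sol depends on an H-bond energy
constant the literature does not agree on; the default is documented above
and every report carries it. The substitution-tolerance classifier is
rule-based and advisory. SASA rigid-body invariance is approximate at the
quadrature level (~0.1%).
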