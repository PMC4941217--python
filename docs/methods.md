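# Methods

## Scope and model

The package counts, per backbone-carbonyl oxygen, the noncovalent
interactions (NCIs) that can satisfy its two lone pairs: hydrogen bonds
from N–H, O–H, C–H and water donors, and n→π\* donation into a
neighbouring carbonyl's π\* orbital. The unit of observation is the
*residue-step* — one (carbonyl, snapshot) cell — and the central object is
the residue × snapshot matrix of reported NCI counts, from which all
distributions, densities, combination tables and motif calls derive.

## Geometric criteria

All cutoffs are inclusive and configurable (`NCIThresholds`); defaults:

- N–H donors: d(H⋯O) ≤ 2.44 Å; O–H donors (hydroxyl, water): ≤ 2.31 Å;
  C–H donors: ≤ 2.68 Å. All donors: ω = ∠(heavy–H⋯O) ≥ 90° and
  ρ = ∠(H⋯O=C) ≥ 90°. ω and ρ are the standard donor-linearity and
  acceptor-approach angles; the numeric distance cutoffs derive from
  electron-density-topology revisions of hydrogen-bond criteria.
- C–H donors additionally require the hydrogen's *elevation* above the
  acceptor's sp² plane (through Cα, C, O, measured at O) to be < 50°,
  restricting these weak donors to in-plane lone-pair approaches.
- n→π\*: d(O⋯C) ≤ 3.22 Å (the O/C van-der-Waals sum) and
  95° ≤ θ ≤ 125°, where θ = ∠(O_don⋯C_acc=O_acc) — the Bürgi–Dunitz-type
  approach window. The printed source range ("95 ≥ θ ≥ 125") is
  unsatisfiable as written and is read as the closed interval.
- χ screen: χ = |dihedral(Cα_acc, C_acc, O_don, H)| ≥ 120°, with H the
  polar hydrogen hydrogen-bonded to the donor oxygen (nearest N–H/O–H
  hydrogen within 2.5 Å, covalent neighbours excluded). Rationale: the
  donor oxygen's two lone pairs should engage the hydrogen bond and the
  π\* face on opposite sides (trans); a cis arrangement means the O⋯C
  contact is part of the hydrogen-bond cluster, not an independent
  interaction. On the ideal α-helix χ = 141.7° and on the 3₁₀-helix
  164.4°, while hydrogen-bond-like approaches fall well below 120°. The
  anchor choice is genuinely underdetermined by the available description;
  alternatives (`chi_hydrogen` = "donor" or "acceptor" residue amide H,
  measuring 61.9° and 36.3° on the ideal helix and thereby rejecting the
  canonical helix n→π\*, or "none") are configuration options. A donor
  oxygen with no hydrogen-bond partner passes the screen.

Hydrogen–heavy-atom bonding is always inferred by distance (≤ 1.2 Å),
never by atom name, so PDB v2 and v3 hydrogen dialects both work.

**Exclusions.** Donors belonging to the acceptor's own residue, and the
backbone N–H of the following residue (the N–H of the same peptide unit as
the carbonyl), are excluded: their geometry is fixed by covalent structure
and they are not noncovalent partners. A donor group contributes at most
one record per carbonyl (its best hydrogen by distance) but may bond two
different carbonyls — which is exactly a bifurcated hydrogen bond.

**Water rule.** If every qualifying record of a carbonyl is to water and at
least one water oxygen lies within 3.5 Å of the carbonyl oxygen
(exposure), the reported count is set to 2 — the assumption that a fully
exposed carbonyl is saturated by solvent, which removes the bias of
under-solvated snapshots. The rule applies only to water-only carbonyls;
mixed protein + water sets keep their raw count.

**Prefilters.** Candidate donors are gathered within 5 Å of each carbonyl
oxygen and candidate carbonyl pairs within d_npistar_max + 1 Å. Both radii
strictly exceed any geometric cutoff plus the covalent H offset (asserted
at run time), so the prefilter cannot change results; equality with a
no-prefilter brute-force double loop is tested on 50 random structures.

## Secondary structure

A Kabsch–Sander energy core: E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH −
1/r_CN) kcal/mol with a bond iff E < −0.5 (proline and missing amide H
give no bond; atoms closer than 0.5 Å are treated as colliding, not
bonded). Two consecutive i→i+4 turns make H, i→i+3 G, i→i+5 I;
inter-strand bridges (DSSP parallel/antiparallel patterns) make E (laddered)
or B (isolated); remaining turn spans are T; Cα-trace kinks with vertex
angle ∠(Cα(i−2), Cα(i), Cα(i+2)) < 110° are bends (S). Priority
H > E/B > G > I > T > S. Labels collapse to six classes with E and B
merged into β-strand and G and I into a 3₁₀/π class. This is a documented
simplified core, not a port of any particular assignment program; an
external DSSP output file can be imported to override it. The "little h" flag marks the first and last
four residues of each helix segment, and each helical residue records which
terminus it is nearer (segments of ≤ 8 residues count as both) — the
context used by the capping-motif rules, with the deliberately generous
reading that a capping carbonyl may sit just inside the terminal turn.
Secondary structure is assigned once on the reference (first) snapshot and
reused across the ensemble by default; a per-snapshot mode (majority label)
exists behind a flag.

## Ensemble statistics

Four count distributions: static (reference structure), per-snapshot
(pooled residue-steps), modal (one modal count per residue, ties broken to
the smaller value so oversatisfaction is never inflated), and
occupancy-filtered (residue-steps of residues spending ≥ 50 % — inclusive —
of the ensemble at their mode). Combination identity is the unordered
multiset of interaction types; under the water rule it is two waters.
Count-2 combination tables pool residue-steps; count-1 and count-3 tables
use the sustained (modal + occupancy) convention, each residue contributing
its modal combination once. A 2 % display threshold is a reporting option,
never applied to stored tables. NCI density is the mean reported count per
residue-step, overall or per class; hydrogen bonds per residue count only
N–H, O–H and water donors (C–H and n→π\* excluded). The bifurcation
fraction is reported with two denominators — per-residue-step records
(default) and unique donor→acceptor bonds — since the pooling convention is
ambiguous in the source material.

## Synthetic structures

Backbones are grown by internal-coordinate (NeRF) chain extension with
ideal bonds (N–Cα 1.46, Cα–C 1.52, C–N 1.33, C=O 1.23 Å), ideal angles, ω
= 180° and canonical template torsions: α (−57, −47), 3₁₀ (−49, −26),
antiparallel strand (−139, 135), parallel strand (−119, 113). Torsions
follow the IUPAC sign convention and are verified against an independent
reference implementation; Cα centres are L-configured (verified by CIP
assignment of built coordinates). Amide H sits in the peptide plane on the
bisector opposite Cα/C(prev); the N-terminal nitrogen carries no H (so it
donates nothing). Side chains cover Ala, Gly, Ser and Thr — enough for
backbone NCIs plus hydroxyl-capping fixtures.

Sp³ rotamers use a fixed 75° offset from the reference eclipse. The offset
is a free convention; it is the one orientation for which no side-chain
hydrogen of an ideal template satisfies the C–H criteria adventitiously,
so each template carries exactly its designed interaction multiset. This is
a knife-edge feature of idealized geometry worth stating plainly: in an
ideal poly-Ala α-helix the i+3 methyl hydrogens pass 2.71 Å from the
carbonyl oxygen — 0.03 Å outside the 2.68 Å cutoff — and other rotamer
conventions put a methyl H inside it. Real helices live on both sides of
this threshold, which is consistent with CH_X appearing in helical
combination tables as soon as ensemble jitter is applied.

Two-strand sheets place a second built strand by rigid-body least squares
against the canonical hydrogen-bond registry (antiparallel: both bonds on
alternating rungs between residue i of strand A and n−1−i of strand B;
parallel: NH(X,i)→O(Y,i−1) on every rung). The antiparallel fit is exact
and also reproduces the cross-strand CαH contact characteristic of
β-structure. Two identical, uniformly twisted strands cannot satisfy the
full parallel registry, so the robust fit distributes the misfit and only
roughly alternating rungs qualify — a known limitation; the antiparallel
template is the primary β fixture.

Solvation places waters on the carbonyl's in-plane lone-pair directions
(±60° from the C=O axis; a third, axial position for per-site 3) with one
O–H pointing at the oxygen at d(H⋯O) = 1.9 Å, clash-checked at 2.4 Å.
Ensembles are i.i.d. Gaussian coordinate jitter (seeded NumPy generator),
a statistical stand-in for dynamics: it reproduces occupancy fluctuation of
interaction counts without any physics. Jittered snapshots keep the
reference topology (peptide connectivity is frozen from the first model),
so the count matrix stays complete even when noise distorts covalent
geometry; multi-model PDB files are treated the same way on reading. In the
acceptance script the fluctuation ensemble uses σ = 0.12 Å, n = 20
snapshots on a 20-mer helix — inside the regime where per-residue
occupancies are strictly between 0 and 1 — and the breakdown check uses
σ = 1.0 Å, where the mean count collapses.

What the generator does *not* emulate: torsional (correlated) motion,
side-chain rotamer exchange, realistic solvent shells, long-range packing,
sequence diversity beyond A/G/S/T, and crystallographic artefacts
(alt-locs, incomplete residues are exercised only through hand-written
parser fixtures). Passing tests therefore demonstrate correctness of the
classification and statistics machinery on structures with known designed
content, not field performance on crystal structures.

## Motif definitions

Sustained = modal count equal to the target held in ≥ 50 % of snapshots.
Named 3-NCI clusters: M1 = {NH_bb, n→π\*, CH_X} in α-helix (any position);
M2 = {2×NH_bb, n→π\*} in α-helix with the two donors at i+3 and i+4 (a
bifurcated pair) and N-terminal-turn context; M3 = {NH_bb, OH_sc, n→π\*}
with C-terminal-turn context and the hydroxyl donated by Ser/Thr; M4 =
{NH_bb, CαH, HOH} in β-strand. Sustained 1-NCI residues are reported as
undersatisfied, with an optional scan of sub-van-der-Waals O⋯H contacts
(same-residue amide H, next-residue Hα; cutoff 2.72 Å = 1.52 + 1.20 Å
van-der-Waals radii, configurable) that may quietly compensate them.
"Unique examples" are distinct (structure, residue) pairs;
`snapshots_matching` counts matching snapshots.

## Numerical choices and degenerate inputs

Angles clamp their cosine into [−1, 1]; coincident or collinear points
raise a degenerate-geometry error rather than returning garbage. Dihedrals
are reported as magnitudes in [0, 180°] because every threshold is
one-sided. Alt-locs resolve to the highest-occupancy conformer (ties to the
alphabetically first altLoc). C-terminal carboxylates are not amide
carbonyls and yield no acceptor site. Waters without explicit hydrogens
cannot be measured as donors; they are excluded and counted per structure
so users know solvent exposure is underestimated. Histograms carry mass
conservation checks (sum to 100 ± 0.01 %).

## Problem sizes

Tests and the acceptance script run on 6–30-residue synthetic structures,
ensembles of 3–20 snapshots, 50-structure oracle sweeps and 5-seed noise
sweeps — sizes chosen so the designed content is hand-checkable while every
code path (prefilters, ensemble alignment, motif context rules) is
exercised.
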