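# Methods

## The design problem

Bispecific antibodies built on heavy-chain heterodimers need a pair of
C-terminal constant domains (CH3 in IgG, CH4 in IgM) that prefer
pairing with each other over forming homodimers. `igxchange`
implements heterodimer design by **interface exchange**: the residues
of an acceptor homodimer's protein–protein interface are replaced by
the residues found at the 3D-equivalent positions of a donor
interface — either the complete interface of a natural heterodimer
(the TCR Cα–Cβ or Cγ–Cδ constant-domain pairs) or half of a second
homodimer's interface. Because the IMGT unique numbering for C-DOMAIN
labels structurally equivalent positions across the whole Ig/TCR
constant-domain family, the donor residue for every acceptor position
is read off directly; no per-design structural modelling is required
to write the substitution lists.

## Coordinates: IMGT C-DOMAIN numbering

Positions are labels such as `22`, `84.2`, `85.1`. The package
implements the chain-order convention for the D/E transition
explicitly: `84.x` ascend away from 84 and `85.x` descend into 85
(`84 < 84.1 < … < 85.2 < 85.1 < 85`); inserted positions elsewhere
(`45.x`, `96.x`) simply ascend. This ordering is a strict total order
over every label the package emits, which the test suite checks
property-style.

The packaged references share a 103-position layout: A strand 1–15, B
16–26, BC loop 27–30/35–38, C 39–45, CD transversal strand 45.1–45.4,
D 77–84, D/E insertions 84.1–84.4 + 85.4–85.1, E 85–96, F 97–104, FG
loop 105–110/112–117, G 118–127. The layout was anchored on the IgG1
CH3 correspondence with EU numbering (IMGT 22 = T366, 26 = K370, 84.2
= D399, 84.4 = D401, 85.1 = F405, 86 = Y407, 88 = K409, 115 = H435)
and on the fold-conserved Cys 23/Cys 104 and Trp 41.

## Reference domains

Nine classes are packaged: IgG1/IgG3/IgA/IgD CH3, IgM CH4, TCR
Cα/Cβ/Cγ/Cδ. The IgG1 CH3 entry is the human IGHG1 germline CH3; the
IgG3 entry differs in the Protein A region (Arg 115, Phe 116 — the
determinants of IgG3's non-binding). The remaining entries are
**curated reconstructions**: germline-flavoured sequences on the
shared layout, constrained at every position whose identity the
packaged engineered designs pin down (for example TCR Cα must carry
Lys 20, Thr 26, Trp 88, Ser 85.1, Val 86, and must agree with IgG1
CH3 at 3, 5, 7, 81, 84, 84.2 for the skip-identical mechanics to emit
exactly the canonical chain-A list). `validate_references()` enforces
all of these identities plus the numbering invariants and is run by
the tests; if a reference were edited inconsistently the build fails
loudly rather than silently emitting different designs. The
reconstructions are not verbatim database alleles, and
structure-facing work against real deposited coordinates should
renumber those sequences via `assign_imgt_numbering` rather than
assume identity with the packaged fixtures.

## Numbering transfer

User sequences acquire numbering by global alignment to a same-class
reference (BLOSUM62, gap open −11 / extend −1, free end gaps so
terminally truncated constructs are tolerated) followed by columnwise
label transfer. Residues aligned to reference gaps receive no label
and are flagged as insertions. Two hard checks: alignment identity
below a configurable floor (default 30% of reference length) raises
"not a recognizable C-domain", and any of the 15 interface positions
landing on a gap raises an explicit error listing the positions —
interface completeness is non-negotiable for design work. Ties in
alignment are resolved by the aligner's deterministic first-alignment
rule, so transfer is reproducible.

## The interface catalog and graft mechanics

The interface comprises 15 positions: 3, 5, 7, 20, 22, 26, 27, 79,
81, 84, 84.2, 85.1, 86, 88, 90. Four key sets (two reciprocal pairs)
do the symmetry breaking — {88 on one chain; 85.1, 86 on the other}
and {20 on one chain; 26 on the other} — supported by 3, 5, 7, 22,
79, 81, 84, 84.2, 90. The default full-graft set is key ∪ supporting
(14 positions); position 27 belongs to the catalog but to no group
and is left untouched by every packaged design. For half-interface
mixing the key sets collapse to two and the interface partitions into
disjoint halves: side 1 = {20, 88} + {79, 81, 90}, side 2 =
{26, 85.1, 86} + {3, 5, 84, 84.2} (7 and 22 belong to neither half).

Grafting applies two rules, both logged per event in the pair's audit
trail:

* **skip-identical** — a substitution is emitted only where donor and
  acceptor residues differ, so the emitted lists match the compact
  published notation;
* **cys-avoidance** — a donor cysteine at any grafted position is
  imported as alanine (the TCR Cβ interface cysteine at 85.1 is the
  motivating case: importing it would invite disulfide mispairing).

Engine invariants, all tested: determinism (identical inputs give
identical pairs), idempotence (re-grafting an engineered chain with
the same donor emits nothing), locality (positions outside the
requested set are never altered), round-trip (applying the emitted
list to the acceptor reproduces the chain string-for-string), no
emitted substitution is silent, and no engineered chain gains a
cysteine at a grafted position.

Mixed-interface designs are auto-named by the two-letter convention:
per engineered chain, first letter = Ig class providing position 88,
second letter = class providing 85.1/86; e.g. IgD half-interfaces on
IgG1 CH3 give `MI (CH3) DG/GD`, IgG1 halves on IgM CH4 give
`MI (CH4) GM/MG`.

## Variants and Protein A engineering

A closed registry holds the named refinement rules: `Q3A` (chain A,
trims steric bulk), `R90T` (chain B, reverts T90R, removing the
Arg 90/Glu 84.2–Asp 84.4 interactions that stabilise the unwanted
B/B homodimer), `D84.4Q` (same goal by removing the acid), and `W81T`
(the tryptophan-81 probe for mixed-interface and strand-exchanged
designs). Application is revert-or-add: a rule that undoes an
existing substitution deletes the list entry; otherwise it appends
one. A rule whose expected wild type does not match the observed
residue raises with the observed residue (so applying `R90T` twice is
an error, not a no-op). Arbitrary ad-hoc mutations bypass design
provenance and go through the fixture generator's
`make_mutant_sequence` instead. Protein A binding is engineered into
CH4 domains only, via exactly R115H + V116Y; the annotation of
binding-competent sites on assembled constructs is a static isotype
tag (IgG3 CH3 and unengineered CH4 → non-binding), deliberately not a
binding predictor.

## Structural analysis

**Contacts.** The contact kernel is distance-criterion based, in the
style of the Protein Interactions Calculator: hydrophobic = side-chain
carbons of {Ala, Val, Leu, Ile, Met, Phe, Trp, Pro, Tyr} within 5.0 Å
across chains; ionic = side-chain N/O of {Lys, Arg, His} vs
{Asp, Glu} within 6.0 Å. Both cutoffs are configurable. One contact
per unordered residue pair and kind carries the minimal qualifying
distance; the result is invariant in chain-argument order. The kernel
is verified against an exhaustive all-atom-pairs scan on hundreds of
randomized fixtures. Hydrogen-bond and cation-π detection are out of
scope; the two reported kinds are the ones the interface diagrams
track.

**Superposition.** Least-squares rigid Cα superposition with pairing
by IMGT position where annotated (author number otherwise). The
solver constrains the solution to proper rotations (det = +1), the
reflection guard. Verified against an independent Euler-grid +
Nelder-Mead minimiser to 10⁻³ Å, plus rigid-motion-invariance and
symmetry properties.

**Side-chain conservation.** "The imported residue kept its donor
orientation" is operationalised as: the χ1 dihedral (N–CA–CB–γ)
differs by less than a tolerance, default 60° — one rotamer-well
width. Gly/Ala have no χ1 and count as conserved; positions
unresolvable in either structure are excluded and reported, never
silently dropped. The fraction is monotone non-increasing as the
tolerance tightens (tested). This χ1 criterion is this package's
declared operationalisation of side-chain orientation; other
reasonable criteria (all-χ, RMSD-based) would give somewhat different
fractions.

Structure I/O accepts PDB and mmCIF (first model, altloc A preferred,
hydrogens ignored, Å units). The optional crystal-structure tests
(engineered-Fc vs reference CH3 backbone RMSD, grafted-residue χ1
conservation vs the TCR donor, the symmetric Lys 26/Glu 13 and Tyr 86
contacts of the IgG1 CH3 interface) require deposited coordinates
fetched by `scripts/fetch_structures.py` and skip when absent.

## Synthetic fixtures

The fixture generator emulates exactly what the kernels consume, not
protein chemistry. Contact fixtures are two-chain models of "stick"
residues (only the atoms the criteria need, canonical 1.5 Å spacing)
whose designated contact atoms face each other at an exact prescribed
distance, with pairs 25 Å apart so they cannot cross-talk and a
seeded rigid motion making each fixture unique yet reproducible;
unrealizable distances are rejected. Rotamer fixtures place
N/CA/CB/γ with canonical internal coordinates at prescribed χ1
angles. Consequently, passing kernel tests demonstrate correctness of
the distance and dihedral logic on idealized geometry; they say
nothing about crystallographic noise, alternate conformations, or
missing atoms in real structures — those paths are exercised only by
the optional accession-gated tests.

## Construct assembly and masses

Fc-like chains are hinge (DKTHTCPPCP) + IgG1 CH2 + engineered domain;
a VL domain antibody fused N-terminally to one chain creates the
molecular-weight signature used to distinguish hetero- from
homodimers on a gel (~11.4 kDa difference with the packaged
placeholder VL). The scFv × Fab assembly produces three chains
(scFv-Fc, Fab heavy chain, light chain) with placeholder variable
domains and a (G₄S)₃ linker — the exact clinical V regions are not
part of the package. Masses are average polypeptide masses from a
standard residue table (empty chain = water, 18.015 Da), excluding
glycans and other modifications, and are cross-checked against an
independent average-weight computation in the tests.

## Problem sizes and determinism

All packaged computations are small and deterministic: design
generation is instantaneous; the randomized verification suites use
~100–120 seeded fixtures for the contact kernel, 10–25-point clouds
for superposition, and 8–12-residue rotamer sets for χ1 monotonicity.
`scripts/acceptance.py --seed N` drives every stochastic element from
the given seed and finishes in about a second.

## Known limitations

* The non-IgG1 reference sequences are curated reconstructions, not
  database alleles; designs against them are internally consistent
  (and pinned at every published position) but non-interface residues
  should not be quoted as germline.
* No free-energy scoring, no interface redesign, and no prediction of
  heterodimerization percentages, expression, stability, or affinity —
  those are experimental observables outside what sequence bookkeeping
  and geometry can provide.
* Homology-model construction is out of scope; the structural kernels
  accept any coordinates but do not build them.
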