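# igxchange

Design heterodimeric antibody Fc domains by **immunoglobulin
interface exchange**, and analyse the resulting interfaces.

Heavy-chain heterodimers are the workhorse architecture of bispecific
antibodies: two different heavy chains must pair with each other
instead of homodimerizing, which is engineered through their
C-terminal constant domains (CH3 in IgG, CH4 in IgM). `igxchange`
implements a biomimetic route to such pairs: the interface residues of
an acceptor homodimer are replaced by the residues found at the
3D-equivalent positions of a donor interface — the complete interface
of a natural heterodimer such as the TCR Cα–Cβ constant-domain pair,
or half of another homodimer's interface. Equivalent positions across
the Ig/TCR constant-domain family are identified by the IMGT unique
numbering for C-DOMAIN, so the donor residue for every acceptor
position is read straight off the numbering, with two mechanical
rules: substitutions are emitted only where donor and acceptor differ
(*skip-identical*), and donor cysteines are imported as alanine
(*cys-avoidance*).

The interface comprises 15 IMGT positions — 3, 5, 7, 20, 22, 26, 27,
79, 81, 84, 84.2, 85.1, 86, 88, 90 — organised into four key sets
({88 ↔ 85.1, 86} and {20 ↔ 26}, each in both orientations) plus
supporting positions. For mixing two homodimers the interface
partitions into disjoint halves: side 1 = {20, 88; 79, 81, 90},
side 2 = {26, 85.1, 86; 3, 5, 84, 84.2}.

The package provides:

* curated IMGT-numbered reference domains (IgG1/IgG3/IgA/IgD CH3,
  IgM CH4, TCR Cα/Cβ/Cγ/Cδ) and alignment-based numbering transfer
  for user sequences;
* full- and half-interface grafting with audit trails, named variant
  rules (Q3A, R90T, D84.4Q, W81T), and CH4 Protein A engineering
  (R115H + V116Y);
* structural analysis: PIC-style hydrophobic/ionic interdomain
  contact maps, least-squares Cα superposition with RMSD (proper
  rotations only), χ1-based side-chain orientation conservation;
* sequence-level construct assembly (Fc-like with a VL-dAb mass tag,
  scFv × Fab chain sets) with average-mass and Protein-A-site
  annotations;
* a deterministic synthetic-fixture generator so every kernel is
  testable without downloading structures.

## Worked example

```python
>>> from igxchange import beat, apply_variant
>>> pair = beat()                      # TCR Ca-Cb interface onto IgG1 CH3
>>> ", ".join(pair.compact("A"))
'S20K, T22V, K26T, K79Y, F85.1S, Y86V, K88W, T90N'
>>> ", ".join(pair.compact("B"))
'Q3E, Y5A, L7F, S20T, T22V, K26T, T81D, V84L, D84.2E, F85.1A, Y86S, K88R, T90R'
>>> apply_variant(pair, "D84.4Q@B").compact("B")[9]
'D84.4Q'
```

Chain A carries the Cα side of the TCR interface (8 substitutions,
including Trp 88 that packs against Ala 85.1 across the interface)
and chain B the Cβ side (13 substitutions; F85.1A is the imported Cβ
cysteine written as alanine). The `D84.4Q` variant appends the
homodimer-destabilising substitution to chain B. Mixed-interface
designs follow the two-letter naming convention:

```python
>>> from igxchange import mixed_interface
>>> mi = mixed_interface("IgG1-CH3", "IgD-CH3")
>>> mi.design_name, mi.compact("A")
('MI (CH3) DG/GD', ('S20A', 'K79R', 'T81S', 'K88R', 'T90Q'))
```

The `examples/` directory walks through each capability (numbering,
grafting, mixing, variants, contact maps, superposition/χ1,
assembly); each script builds its own input and prints what the
numbers mean. A thin CLI mirrors the library:

```
igx report --design beat
igx graft --mode half --acceptor IgG1-CH3 --donor IgD-CH3 --out-dir out/
igx contacts structure.pdb --chains A,B
```

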