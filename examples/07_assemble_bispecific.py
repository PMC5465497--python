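"""Assemble Fc-like and scFv x Fab chains from an engineered pair.

An Fc-like protein is hinge + CH2 + engineered CH3 per chain; fusing a
VL domain antibody to one chain gives homo- and heterodimers distinct
molecular weights.  Tagging chain A as IgG3-derived CH3 (a natural
non-Protein-A-binding isotype) leaves the heterodimer with exactly one
binding-competent site, the handle for removing homodimer traces.
"""

from igxchange import ConstructTemplate, assemble_fc_like, assemble_scfv_fab, beat

pair = beat()

cs = assemble_fc_like(pair, fusion_chain="B")
for name, seq in cs.chains.items():
    print(f"{name:<10} {len(seq):>4} aa  {cs.masses_kda()[name]:6.1f} kDa")
print("Protein A sites:", cs.protein_a_label)

asym = assemble_fc_like(
    pair, template=ConstructTemplate(isotype_tags={"A": "IgG3-CH3"}), fusion_chain="B"
)
print("with IgG3-derived chain A:", asym.protein_a_label)

bsab = assemble_scfv_fab(pair)
print("\nscFv x Fab chain set (placeholder V domains):")
for name, seq in bsab.chains.items():
    print(f"  {name:<10} {len(seq):>4} aa  {bsab.masses_kda()[name]:6.1f} kDa")
# The ~11 kDa VL fusion separates the species on a gel; the scFv x Fab
# format needs no light-chain steering because only one arm has a Fab.
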