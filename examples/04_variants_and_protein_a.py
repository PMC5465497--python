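"""Named variant rules and Protein A engineering.

D84.4Q destabilises the chain-(B) homodimer (it removes the Arg 90 /
Asp 84.4 electrostatic pair the unwanted homodimer relies on); R90T
reverts T90R for the same reason; Q3A trims steric bulk on chain (A).
CH4 domains gain Protein A binding through R115H + V116Y.
"""

from igxchange import (
    add_protein_a_binding,
    apply_variant,
    beat,
    beat_ch4,
    get_reference,
    with_protein_a,
)

pair = beat()
improved = apply_variant(pair, "D84.4Q@B")
print("chain B after D84.4Q:", ", ".join(improved.compact("B")))

reverted = apply_variant(pair, "R90T@B")
print("chain B after R90T:  ", ", ".join(reverted.compact("B")))

pa = add_protein_a_binding(get_reference("IgM-CH4"))
print("IgM CH4 pA residues: 115 ->", pa.residue_at(115), " 116 ->", pa.residue_at(116))

ch4 = with_protein_a(beat_ch4())
print(ch4.design_name, "chain A:", ", ".join(ch4.compact("A")))
# The pA entries (R115H, V116Y) ride along with the graft substitutions.
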