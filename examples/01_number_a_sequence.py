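"""Assign IMGT C-DOMAIN numbering to a CH3 sequence by reference alignment.

The IMGT unique numbering labels 3D-equivalent positions across Ig and
TCR constant domains, which is what makes interface residues
transferable between classes.
"""

from igxchange import assign_imgt_numbering, get_reference, interface_positions, make_mutant_sequence

ref = get_reference("IgG1-CH3")

# a CH3 variant with two point changes away from the interface
query = make_mutant_sequence(ref, [("11", "A"), ("118", "A")])
numbered = assign_imgt_numbering(query, ref)

print(f"numbered {len(numbered.numbering)} of {len(query)} residues")
print("interface residues (position: residue):")
print("  " + "  ".join(f"{p}:{numbered.residue_at(p)}" for p in interface_positions()))
# The 15 interface positions keep the IgG1 wild-type letters: the two
# mutations sit outside the dimerization interface.
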