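"""Graft the TCR Ca-Cb heterodimer interface onto the IgG1 CH3 homodimer.

This is the flagship full-interface exchange: chain A inherits the Ca
side of the TCR interface, chain B the Cb side, and the engine emits a
substitution only where donor and acceptor differ.  The Cb interface
cysteine at 85.1 is imported as alanine to avoid disulfide mispairing.
"""

from igxchange import beat, design_report

pair = beat()
print(design_report(pair))
# chain (A) carries 8 substitutions and chain (B) 13 - together they
# break the CH3 homodimer symmetry and recreate the key TCR contacts
# (Trp 88 / Ala 85.1 packing on one side, the preserved Lys 88
# electrostatic network on the other).
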