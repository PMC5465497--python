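"""Build heterodimers by mixing two homodimeric interfaces (MI designs).

Half of the donor homodimer's interface replaces the equivalent half
of the acceptor's: one chain is substituted at positions 88/20 (with
supporting 79, 81, 90), the other at 26/85.1/86 (with supporting 3, 5,
84, 84.2).  Names follow the two-letter convention: first letter = the
class at position 88, second = the class at 85.1/86.
"""

from igxchange import mixed_interface

for acceptor, donor in [
    ("IgG1-CH3", "IgA-CH3"),
    ("IgG1-CH3", "IgD-CH3"),
    ("IgG1-CH3", "IgM-CH4"),
    ("IgM-CH4", "IgG1-CH3"),
]:
    pair = mixed_interface(acceptor, donor)
    print(f"{pair.design_name:<18} chain 1: {', '.join(pair.compact('A'))}")
    print(f"{'':<18} chain 2: {', '.join(pair.compact('B'))}")
# Each chain touches only its half of the interface partition, so the
# two half-exchanges cannot collide.
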