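"""The interface-position catalog.

Fifteen IMGT C-DOMAIN positions carry the interdomain contacts of
every homo- and heterodimeric Ig/TCR constant-domain pair: 3, 5, 7,
20, 22, 26, 27, 79, 81, 84, 84.2, 85.1, 86, 88 and 90.  Engineering a
heterodimer from a donor interface touches them in structured groups:

* four *key sets* (two reciprocal pairs) that break the homodimer
  symmetry — position 88 on one chain paired with 85.1/86 on the
  other, and position 20 on one chain paired with 26 on the other;
* nine *supporting* positions (3, 5, 7, 22, 79, 81, 84, 84.2, 90)
  that carry asymmetric contacts or spatially accommodate the key
  substitutions.

For half-interface mixing of two homodimers the four key sets
collapse into two and the interface is partitioned into two disjoint
half-sides: side 1 = {20, 88} with supporting {79, 81, 90}; side 2 =
{26, 85.1, 86} with supporting {3, 5, 84, 84.2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .positions import ImgtPosition, positions

#: The 15 interface positions, in chain order.
INTERFACE_POSITIONS: tuple[ImgtPosition, ...] = positions(
    3, 5, 7, 20, 22, 26, 27, 79, 81, 84, "84.2", "85.1", 86, 88, 90
)


@dataclass(frozen=True)
class KeySet:
    """One key residue set: positions on chain A paired with positions on B."""

    name: str
    chain_a: tuple[ImgtPosition, ...]
    chain_b: tuple[ImgtPosition, ...]


_KEY_SETS = (
    KeySet("set1", positions(88), positions("85.1", 86)),
    KeySet("set2", positions("85.1", 86), positions(88)),
    KeySet("set3", positions(20), positions(26)),
    KeySet("set4", positions(26), positions(20)),
)
_SUPPORTING = positions(3, 5, 7, 22, 79, 81, 84, "84.2", 90)
_HALF_SIDE_1 = positions(20, 79, 81, 88, 90)
_HALF_SIDE_2 = positions(3, 5, 26, 84, "84.2", "85.1", 86)


@dataclass(frozen=True)
class InterfaceCatalog:
    """Fixed interface position set with role annotations."""

    positions: tuple[ImgtPosition, ...] = INTERFACE_POSITIONS
    key_sets: tuple[KeySet, ...] = _KEY_SETS
    supporting: tuple[ImgtPosition, ...] = _SUPPORTING
    half_side_1: tuple[ImgtPosition, ...] = _HALF_SIDE_1
    half_side_2: tuple[ImgtPosition, ...] = _HALF_SIDE_2

    def __post_init__(self):
        pos_set = set(self.positions)
        key_pos = {p for ks in self.key_sets for p in ks.chain_a + ks.chain_b}
        if not key_pos <= pos_set:
            raise ValueError("key-set positions escape the catalog")
        if not set(self.supporting) <= pos_set:
            raise ValueError("supporting positions escape the catalog")
        if set(self.half_side_1) & set(self.half_side_2):
            raise ValueError("half-interface sides overlap")

    @property
    def graft_positions(self) -> tuple[ImgtPosition, ...]:
        """Default full-graft set: key sets plus supporting, in chain order.

        Position 27 belongs to the catalog but to no key or supporting
        group, so the default graft leaves it untouched.
        """
        wanted = {p for ks in self.key_sets for p in ks.chain_a + ks.chain_b}
        wanted |= set(self.supporting)
        return tuple(p for p in self.positions if p in wanted)


#: Module-level singleton; the catalog is fixed.
CATALOG = InterfaceCatalog()


def interface_positions() -> tuple[ImgtPosition, ...]:
    """The 15 interface positions in chain order."""
    return INTERFACE_POSITIONS
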