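"""IMGT C-DOMAIN position labels.

The IMGT unique numbering for constant domains (C-DOMAIN) labels
structurally equivalent positions across immunoglobulin and T-cell
receptor constant domains.  Most labels are plain integers; inserted
positions carry a decimal suffix (``84.2``, ``85.1``).  The chain-order
convention for the D/E transition is asymmetric: positions ``84.x``
ascend away from 84, while positions ``85.x`` descend into 85, i.e.

    84 < 84.1 < 84.2 < ... < 85.3 < 85.2 < 85.1 < 85

Inserted positions elsewhere (``45.x`` in the CD transversal strand,
``96.x`` in the EF turn) simply ascend after their anchor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import total_ordering

# Anchors whose decimal positions run *backwards* into the anchor.
_DESCENDING_ANCHORS = frozenset({85})

_POSITION_RE = re.compile(r"^(\d+)(?:\.(\d+))?$")


@total_ordering
@dataclass(frozen=True)
class ImgtPosition:
    """A single IMGT C-DOMAIN coordinate label.

    Parameters
    ----------
    main:
        The integer part of the label (positive).
    sub:
        Optional decimal suffix for inserted positions (positive);
        ``None`` for plain positions.
    """

    main: int
    sub: int | None = None

    def __post_init__(self):
        if self.main <= 0:
            raise ValueError(f"main position must be positive, got {self.main}")
        if self.sub is not None and self.sub <= 0:
            raise ValueError(f"decimal suffix must be positive, got {self.sub}")

    @classmethod
    def parse(cls, text: str | int | float | "ImgtPosition") -> "ImgtPosition":
        """Parse ``"84"`` or ``"84.2"`` (also accepts ints and ImgtPosition)."""
        if isinstance(text, ImgtPosition):
            return text
        if isinstance(text, int):
            return cls(text)
        m = _POSITION_RE.match(str(text).strip())
        if not m:
            raise ValueError(f"not an IMGT position label: {text!r}")
        main = int(m.group(1))
        sub = int(m.group(2)) if m.group(2) is not None else None
        return cls(main, sub)

    def __str__(self) -> str:
        if self.sub is None:
            return str(self.main)
        return f"{self.main}.{self.sub}"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ImgtPosition({self})"

    @property
    def sort_key(self) -> tuple[int, int, int]:
        """Key realising the chain-order convention (strict total order)."""
        if self.sub is None:
            return (self.main, 0, 0)
        if self.main in _DESCENDING_ANCHORS:
            # 85.x precede 85 and descend: 85.2 < 85.1 < 85
            return (self.main, -1, -self.sub)
        return (self.main, 1, self.sub)

    def __lt__(self, other: "ImgtPosition") -> bool:
        if not isinstance(other, ImgtPosition):
            return NotImplemented
        return self.sort_key < other.sort_key


def pos(label) -> ImgtPosition:
    """Shorthand parser: ``pos("85.1")``."""
    return ImgtPosition.parse(label)


def positions(*labels) -> tuple[ImgtPosition, ...]:
    return tuple(ImgtPosition.parse(v) for v in labels)
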