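"""Curated IMGT-numbered reference domains and numbering transfer.

The package ships one reference constant domain per supported class
(IgG1/IgG3/IgA/IgD CH3, IgM CH4, TCR Ca/Cb/Cg/Cd), each carrying a
complete residue-index -> IMGT C-DOMAIN label map on a shared
103-position layout (A strand 1-15, B 16-26, gapped BC loop, C 39-45,
CD transversal 45.1-45.4, D 77-84, D/E insertions 84.1-84.4 and
85.4-85.1, E 85-96, F 97-104, gapped FG loop up to 117, G 118-127).

The reference sequences are curated reconstructions: germline-derived
where possible (the IgG1 CH3 entry is the human IGHG1 germline CH3)
and constrained everywhere to the wild-type residue identities that
the packaged engineered designs imply.  ``validate_references`` checks
those identities and is exercised by the test suite.

User-supplied sequences acquire numbering by global alignment to a
reference of the same class followed by column-wise label transfer
(:func:`assign_imgt_numbering`).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

from Bio import Align
from Bio.Align import substitution_matrices

from .catalog import INTERFACE_POSITIONS, interface_positions  # re-export  # noqa: F401
from .errors import AlignmentFloorError, MissingInterfacePositionError
from .positions import ImgtPosition

#: Domain classes with a packaged reference.
DOMAIN_CLASSES = (
    "IgG1-CH3",
    "IgG3-CH3",
    "IgA-CH3",
    "IgD-CH3",
    "IgM-CH4",
    "TCR-Ca",
    "TCR-Cb",
    "TCR-Cg",
    "TCR-Cd",
)

#: Classes that form homodimers (acceptors / half-interface donors).
HOMODIMER_CLASSES = frozenset(
    {"IgG1-CH3", "IgG3-CH3", "IgA-CH3", "IgD-CH3", "IgM-CH4"}
)

#: One-letter Ig class code used by the mixed-interface naming convention.
CLASS_LETTER = {
    "IgA-CH3": "A",
    "IgD-CH3": "D",
    "IgG1-CH3": "G",
    "IgG3-CH3": "G",
    "IgM-CH4": "M",
}


@dataclass(frozen=True)
class NumberedDomain:
    """A constant-domain sequence with an IMGT position for each residue.

    ``numbering`` maps residue index (0-based) to :class:`ImgtPosition`.
    For packaged references the map is total; domains numbered by
    alignment may lack terminal positions and may carry unlabelled
    inserted residues (listed in ``insertions``).
    """

    domain_class: str
    sequence: str
    numbering: tuple[tuple[int, ImgtPosition], ...]
    name: str = ""
    provenance: str = ""
    insertions: tuple[int, ...] = ()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_map(cls, domain_class, sequence, index_to_position, **kw):
        items = tuple(sorted(index_to_position.items()))
        return cls(domain_class, sequence, items, **kw)

    # -- lookups --------------------------------------------------------------

    @property
    def index_map(self) -> dict[int, ImgtPosition]:
        return dict(self.numbering)

    @property
    def position_map(self) -> dict[ImgtPosition, int]:
        return {p: i for i, p in self.numbering}

    def positions(self) -> tuple[ImgtPosition, ...]:
        """All labelled positions in chain order."""
        return tuple(sorted((p for _, p in self.numbering)))

    def has_position(self, position) -> bool:
        return ImgtPosition.parse(position) in self.position_map

    def residue_at(self, position) -> str:
        """One-letter residue at an IMGT position (KeyError if absent)."""
        return self.sequence[self.position_map[ImgtPosition.parse(position)]]

    def position_of(self, index: int) -> ImgtPosition | None:
        return self.index_map.get(index)

    # -- invariants -----------------------------------------------------------

    def validate(self, complete: bool = True) -> None:
        """Check the numbering invariants.

        With ``complete`` every residue must carry exactly one position,
        no position may repeat, and walking the positions in chain order
        must reproduce the sequence.
        """
        idx = [i for i, _ in self.numbering]
        pos = [p for _, p in self.numbering]
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate residue index in numbering")
        if len(set(pos)) != len(pos):
            raise ValueError("duplicate IMGT position in numbering")
        if any(i < 0 or i >= len(self.sequence) for i in idx):
            raise ValueError("numbering index outside sequence")
        if complete:
            if len(idx) != len(self.sequence):
                raise ValueError("numbering does not cover every residue")
            ordered = "".join(
                self.sequence[i]
                for i, _ in sorted(self.numbering, key=lambda ip: ip[1])
            )
            if ordered != self.sequence:
                raise ValueError("chain-order walk does not reproduce sequence")


@dataclass(frozen=True)
class ReferenceSet:
    """The packaged references, keyed by domain class."""

    references: dict[str, NumberedDomain] = field(default_factory=dict)

    def __getitem__(self, domain_class: str) -> NumberedDomain:
        try:
            return self.references[domain_class]
        except KeyError:
            known = ", ".join(sorted(self.references))
            raise KeyError(
                f"no reference for {domain_class!r}; known classes: {known}"
            ) from None

    def __iter__(self):
        return iter(self.references.values())

    def classes(self) -> tuple[str, ...]:
        return tuple(self.references)


_cache: ReferenceSet | None = None


def _read_fasta_text(text: str) -> list[tuple[str, str, str]]:
    records, name, desc, chunks = [], None, "", []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records.append((name, desc, "".join(chunks)))
            head = line[1:].split(None, 1)
            name, desc, chunks = head[0], head[1] if len(head) > 1 else "", []
        else:
            chunks.append(line)
    if name is not None:
        records.append((name, desc, "".join(chunks)))
    return records


def load_references() -> ReferenceSet:
    """Load (and cache) the packaged reference set."""
    global _cache
    if _cache is not None:
        return _cache
    data = resources.files("igxchange.data")
    fasta = _read_fasta_text(data.joinpath("references.fasta").read_text())
    numbering: dict[str, dict[int, ImgtPosition]] = {}
    with resources.as_file(data.joinpath("numbering.tsv")) as path:
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                numbering.setdefault(row["domain_class"], {})[
                    int(row["residue_index"])
                ] = ImgtPosition.parse(row["imgt_label"])
    refs = {}
    for name, desc, seq in fasta:
        dom = NumberedDomain.from_map(
            name, seq, numbering[name], name=name, provenance=desc
        )
        dom.validate(complete=True)
        refs[name] = dom
    missing = set(DOMAIN_CLASSES) - set(refs)
    if missing:
        raise RuntimeError(f"packaged reference(s) missing: {sorted(missing)}")
    _cache = ReferenceSet(refs)
    return _cache


def get_reference(domain_class: str) -> NumberedDomain:
    return load_references()[domain_class]


# -- numbering transfer -------------------------------------------------------


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # terminal truncation is tolerated: end gaps are free
    aligner.end_gap_score = 0.0
    aligner.mode = "global"
    return aligner


def assign_imgt_numbering(
    seq: str,
    reference: NumberedDomain,
    identity_floor: float = 0.30,
    name: str = "",
) -> NumberedDomain:
    """Number ``seq`` by global alignment to ``reference`` and label transfer.

    Aligned columns inherit the reference label; residues of ``seq``
    aligned to reference gaps receive no label and are flagged in
    ``insertions``.  Raises :class:`AlignmentFloorError` when fewer than
    ``identity_floor`` of the reference residues find an identical
    partner, and :class:`MissingInterfacePositionError` when any of the
    15 catalog interface positions falls on a gap in ``seq``.
    """
    seq = str(seq).strip().upper()
    if not (80 <= len(seq) <= 140):
        raise ValueError(
            f"sequence length {len(seq)} outside the constant-domain range [80, 140]"
        )
    aln = _make_aligner().align(reference.sequence, seq)[0]
    ref_map = reference.index_map

    index_to_position: dict[int, ImgtPosition] = {}
    matches = 0
    aligned_query = set()
    for (r0, r1), (q0, q1) in zip(*aln.aligned):
        for off in range(r1 - r0):
            ri, qi = r0 + off, q0 + off
            aligned_query.add(qi)
            if reference.sequence[ri] == seq[qi]:
                matches += 1
            label = ref_map.get(ri)
            if label is not None:
                index_to_position[qi] = label

    identity = matches / len(reference.sequence)
    if identity < identity_floor:
        raise AlignmentFloorError(
            "not a recognizable C-domain: alignment identity "
            f"{identity:.0%} below floor {identity_floor:.0%}"
        )

    labelled = set(index_to_position.values())
    missing = [p for p in INTERFACE_POSITIONS if p not in labelled]
    if missing:
        raise MissingInterfacePositionError(missing)

    insertions = tuple(i for i in range(len(seq)) if i not in aligned_query)
    out = NumberedDomain.from_map(
        reference.domain_class,
        seq,
        index_to_position,
        name=name or f"{reference.domain_class} (renumbered)",
        provenance=f"numbered by alignment to {reference.name or reference.domain_class}",
        insertions=insertions,
    )
    out.validate(complete=not insertions and len(index_to_position) == len(seq))
    return out


# -- consistency check --------------------------------------------------------

#: Residue identities every packaged reference must satisfy.  Interface
#: letters follow from the engineered designs (skip-identical mechanics:
#: a position absent from a printed substitution list must already agree
#: with the acceptor); 23/41/104 are the fold-conserved Cys/Trp/Cys;
#: 115/116 anchor the Protein A region.
REQUIRED_RESIDUES: dict[str, dict[str, str]] = {
    "IgG1-CH3": {
        "3": "Q", "5": "Y", "7": "L", "13": "E", "16": "K", "20": "S",
        "22": "T", "23": "C", "24": "L", "26": "K", "27": "G", "41": "W",
        "79": "K", "81": "T", "84": "V", "84.2": "D", "84.4": "D",
        "85.1": "F", "86": "Y", "88": "K", "90": "T", "104": "C",
        "115": "H", "116": "Y",
    },
    "IgG3-CH3": {"23": "C", "41": "W", "104": "C", "115": "R", "116": "F"},
    "TCR-Ca": {
        "3": "Q", "5": "Y", "7": "L", "20": "K", "22": "V", "23": "C",
        "26": "T", "27": "G", "41": "W", "79": "Y", "81": "T", "84": "V",
        "84.2": "D", "85.1": "S", "86": "V", "88": "W", "90": "N", "104": "C",
    },
    "TCR-Cb": {
        "3": "E", "5": "A", "7": "F", "20": "T", "22": "V", "23": "C",
        "26": "T", "27": "G", "41": "W", "79": "K", "81": "D", "84": "L",
        "84.2": "E", "85.1": "C", "86": "S", "88": "R", "90": "R", "104": "C",
    },
    "TCR-Cg": {"23": "C", "27": "G", "41": "W", "88": "W", "104": "C"},
    "TCR-Cd": {"23": "C", "27": "G", "41": "W", "88": "F", "104": "C"},
    "IgA-CH3": {
        "3": "E", "23": "C", "26": "R", "27": "G", "41": "W", "81": "W",
        "90": "R", "104": "C",
    },
    "IgD-CH3": {"23": "C", "27": "G", "41": "W", "104": "C"},
    "IgM-CH4": {"23": "C", "27": "G", "41": "W", "104": "C", "115": "R", "116": "V"},
}


def validate_references(refs: ReferenceSet | None = None) -> None:
    """Fail loudly if any packaged reference breaks a required identity.

    Also re-checks the structural invariants: complete bijective
    numbering and presence of all 15 interface positions.
    """
    refs = refs or load_references()
    problems = []
    for domain_class in DOMAIN_CLASSES:
        ref = refs[domain_class]
        ref.validate(complete=True)
        have = set(ref.positions())
        for p in INTERFACE_POSITIONS:
            if p not in have:
                problems.append(f"{domain_class}: interface position {p} absent")
        for label, want in REQUIRED_RESIDUES.get(domain_class, {}).items():
            got = ref.residue_at(label)
            if got != want:
                problems.append(f"{domain_class} {label}: expected {want}, found {got}")
    if problems:
        raise AssertionError("reference consistency check failed:\n" + "\n".join(problems))
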