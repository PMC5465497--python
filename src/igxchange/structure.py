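"""Interface structural analysis.

Three kernels support the design and validation of interface
exchanges:

* :func:`compute_contacts` — interdomain residue-residue contact
  detection in the style of the Protein Interactions Calculator:
  hydrophobic contacts between side-chain carbons of apolar residues
  (default cutoff 5.0 A) and ionic contacts between side-chain N/O
  atoms of basic and acidic residues (default 6.0 A);
* :func:`superpose_calpha` — least-squares rigid C-alpha superposition
  (proper rotations only) with RMSD;
* :func:`sidechain_conservation` — the fraction of listed positions
  whose chi1 dihedral is preserved between a graft structure and its
  donor, the operational criterion for "side-chain orientation
  maintained".

Coordinates are in Angstrom; readers keep the first model of
multi-model files, prefer altloc "A" and ignore hydrogens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .errors import IgxError
from .positions import ImgtPosition
from .reference import NumberedDomain, assign_imgt_numbering

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Apolar residues whose side-chain carbons count as hydrophobic.
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR"}
)
BASIC_RESIDUES = frozenset({"LYS", "ARG", "HIS"})
ACIDIC_RESIDUES = frozenset({"ASP", "GLU"})

#: Atom bearing the chi1-defining gamma position, by residue type.
_GAMMA_ATOM = {
    "SER": "OG", "THR": "OG1", "VAL": "CG1", "ILE": "CG1", "CYS": "SG",
}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)


@dataclass(frozen=True)
class Residue:
    name: str            # three-letter code
    number: int          # author residue number
    atoms: tuple[Atom, ...]
    imgt: ImgtPosition | None = None

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def sidechain_atoms(self) -> tuple[Atom, ...]:
        return tuple(a for a in self.atoms if a.name not in BACKBONE_ATOMS)


@dataclass(frozen=True)
class ChainModel:
    chain_id: str
    residues: tuple[Residue, ...]

    def residue_at(self, position) -> Residue | None:
        p = ImgtPosition.parse(position)
        for r in self.residues:
            if r.imgt == p:
                return r
        return None

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass(frozen=True)
class StructureModel:
    name: str
    chains: tuple[ChainModel, ...]

    def chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not in structure {self.name!r}")

    def validate(self) -> None:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    if not all(math.isfinite(v) for v in a.xyz):
                        raise ValueError(
                            f"non-finite coordinate: {c.chain_id}/{r.name}{r.number}/{a.name}"
                        )


# -- I/O ----------------------------------------------------------------------


def read_structure(path, name: str | None = None) -> StructureModel:
    """Read PDB or mmCIF into a StructureModel (first model, altloc A, no H)."""
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    chains = []
    for ch in model:
        residues = []
        for res in ch:
            atoms = []
            for at in res:
                if at.element.is_hydrogen:
                    continue
                if at.altloc not in ("", "\x00", "A"):
                    continue
                atoms.append(
                    Atom(at.name, at.element.name, (at.pos.x, at.pos.y, at.pos.z))
                )
            if res.name in THREE_TO_ONE and atoms:
                residues.append(Residue(res.name, res.seqid.num, tuple(atoms)))
        if residues:
            chains.append(ChainModel(ch.name, tuple(residues)))
    return StructureModel(name or str(path), tuple(chains))


def write_pdb(model: StructureModel, path) -> None:
    """Write a StructureModel as PDB (fixtures are inspectable this way)."""
    import gemmi

    st = gemmi.Structure()
    st.name = model.name
    md = gemmi.Model("1")
    for ch in model.chains:
        gch = gemmi.Chain(ch.chain_id)
        for r in ch.residues:
            gres = gemmi.Residue()
            gres.name = r.name
            gres.seqid = gemmi.SeqId(r.number, " ")
            for a in r.atoms:
                gat = gemmi.Atom()
                gat.name = a.name
                gat.element = gemmi.Element(a.element)
                gat.pos = gemmi.Position(*a.xyz)
                gres.add_atom(gat)
            gch.add_residue(gres)
        md.add_chain(gch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


# -- contacts -----------------------------------------------------------------


@dataclass(frozen=True)
class ContactCriteria:
    """Distance criteria for interdomain contact detection."""

    hydrophobic_cutoff: float = 5.0
    ionic_cutoff: float = 6.0
    hydrophobic_residues: frozenset = HYDROPHOBIC_RESIDUES
    basic_residues: frozenset = BASIC_RESIDUES
    acidic_residues: frozenset = ACIDIC_RESIDUES


DEFAULT_CRITERIA = ContactCriteria()


@dataclass(frozen=True)
class ContactEnd:
    chain: str
    residue_name: str
    number: int
    imgt: ImgtPosition | None

    @property
    def label(self) -> str:
        tag = str(self.imgt) if self.imgt is not None else str(self.number)
        return f"{self.chain}:{self.residue_name} {tag}"


@dataclass(frozen=True)
class Contact:
    kind: str  # "hydrophobic" | "ionic"
    res_i: ContactEnd
    res_j: ContactEnd
    min_distance: float


@dataclass(frozen=True)
class ContactMap:
    contacts: tuple[Contact, ...]
    criteria: ContactCriteria = DEFAULT_CRITERIA

    def __len__(self):
        return len(self.contacts)

    def of_kind(self, kind: str) -> tuple[Contact, ...]:
        return tuple(c for c in self.contacts if c.kind == kind)


def _charged_atoms(residue: Residue) -> tuple[Atom, ...]:
    return tuple(
        a for a in residue.sidechain_atoms() if a.element in ("N", "O")
    )


def _hydrophobic_atoms(residue: Residue) -> tuple[Atom, ...]:
    return tuple(a for a in residue.sidechain_atoms() if a.element == "C")


def _residue_pairs_min_distance(atoms_i, atoms_j) -> float | None:
    if not atoms_i or not atoms_j:
        return None
    xi = np.array([a.xyz for a in atoms_i], dtype=float)
    xj = np.array([a.xyz for a in atoms_j], dtype=float)
    return float(cdist(xi, xj).min())


def compute_contacts(
    model: StructureModel,
    chain_pair: tuple[str, str],
    criteria: ContactCriteria = DEFAULT_CRITERIA,
) -> ContactMap:
    """All interdomain hydrophobic/ionic contacts between two chains.

    One contact per unordered residue pair and kind, carrying the
    minimal qualifying atom-atom distance.  The result is invariant in
    the order of ``chain_pair`` (ends are reported for the
    lexicographically smaller chain first).  Chains with no qualifying
    atoms yield an empty map.
    """
    ca, cb = sorted(chain_pair)
    chain_i, chain_j = model.chain(ca), model.chain(cb)
    contacts = []
    for ri in chain_i.residues:
        for rj in chain_j.residues:
            # hydrophobic: side-chain carbons of apolar residues
            if (
                ri.name in criteria.hydrophobic_residues
                and rj.name in criteria.hydrophobic_residues
            ):
                d = _residue_pairs_min_distance(
                    _hydrophobic_atoms(ri), _hydrophobic_atoms(rj)
                )
                if d is not None and d <= criteria.hydrophobic_cutoff:
                    contacts.append(_contact("hydrophobic", ca, ri, cb, rj, d))
            # ionic: side-chain N/O between basic and acidic residues
            basic_acidic = (
                ri.name in criteria.basic_residues
                and rj.name in criteria.acidic_residues
            ) or (
                ri.name in criteria.acidic_residues
                and rj.name in criteria.basic_residues
            )
            if basic_acidic:
                d = _residue_pairs_min_distance(
                    _charged_atoms(ri), _charged_atoms(rj)
                )
                if d is not None and d <= criteria.ionic_cutoff:
                    contacts.append(_contact("ionic", ca, ri, cb, rj, d))
    contacts.sort(
        key=lambda c: (c.kind, c.res_i.number, c.res_j.number, c.min_distance)
    )
    return ContactMap(tuple(contacts), criteria)


def _contact(kind, chain_i, res_i, chain_j, res_j, dist) -> Contact:
    return Contact(
        kind,
        ContactEnd(chain_i, res_i.name, res_i.number, res_i.imgt),
        ContactEnd(chain_j, res_j.name, res_j.number, res_j.imgt),
        dist,
    )


# -- superposition ------------------------------------------------------------


@dataclass(frozen=True)
class Superposition:
    rotation: np.ndarray      # 3x3 proper rotation
    translation: np.ndarray   # length-3
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose_calpha(mobile: np.ndarray, target: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of paired C-alpha coordinates.

    Returns the proper rotation + translation minimising the RMSD of
    ``mobile`` onto ``target`` (Kabsch problem; the solver constrains
    the solution to det(R) = +1, guarding against reflections).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must be matching Nx3 arrays")
    if len(mobile) < 3:
        raise ValueError("at least 3 paired atoms are required")
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - ct, mobile - cm)
    R = rot.as_matrix()
    moved = (mobile - cm) @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - (target - ct)) ** 2, axis=1))))
    return Superposition(R, ct - R @ cm, rmsd)


def select_calpha(
    model: StructureModel, chain_id: str, positions=None, by: str = "auto"
) -> tuple[np.ndarray, tuple]:
    """C-alpha coordinates of a chain, keyed by IMGT position or author number.

    With ``positions`` only those residues are selected (in the given
    order); otherwise every residue with a CA atom, keyed by IMGT
    position where annotated (``by="auto"``).
    Returns (Nx3 array, keys).
    """
    chain = model.chain(chain_id)
    coords, keys = [], []
    if positions is not None:
        for p in positions:
            res = chain.residue_at(p) if by in ("auto", "imgt") else None
            if res is None and by in ("auto", "author"):
                res = next((r for r in chain.residues if r.number == int(str(p))), None)
            if res is None:
                raise KeyError(f"position {p} not found in chain {chain_id}")
            ca = res.atom("CA")
            if ca is None:
                raise IgxError(f"no CA atom at {p} in chain {chain_id}")
            coords.append(ca.xyz)
            keys.append(p)
    else:
        for r in chain.residues:
            ca = r.atom("CA")
            if ca is not None:
                coords.append(ca.xyz)
                keys.append(r.imgt if r.imgt is not None else r.number)
    return np.asarray(coords, dtype=float), tuple(keys)


def paired_calpha(
    model_a: StructureModel, chain_a: str, model_b: StructureModel, chain_b: str
) -> tuple[np.ndarray, np.ndarray, tuple]:
    """CA coordinate pairs shared by two chains (paired by IMGT position
    where both are annotated, else by author number)."""
    xa, ka = select_calpha(model_a, chain_a)
    xb, kb = select_calpha(model_b, chain_b)
    index_b = {k: i for i, k in enumerate(kb)}
    pa, pb, keys = [], [], []
    for i, k in enumerate(ka):
        j = index_b.get(k)
        if j is not None:
            pa.append(xa[i])
            pb.append(xb[j])
            keys.append(k)
    return np.asarray(pa), np.asarray(pb), tuple(keys)


# -- side-chain conservation --------------------------------------------------


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees for four points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def chi1(residue: Residue) -> float | None:
    """Chi1 dihedral (N-CA-CB-gamma) in degrees; None when undefined."""
    if residue.name in ("GLY", "ALA"):
        return None
    gamma_name = _GAMMA_ATOM.get(residue.name, "CG")
    atoms = [residue.atom(n) for n in ("N", "CA", "CB", gamma_name)]
    if any(a is None for a in atoms):
        return None
    return dihedral(*(a.coords for a in atoms))


def _angle_diff(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


@dataclass(frozen=True)
class ConservationResult:
    fraction: float
    conserved: tuple = ()
    changed: tuple = ()
    excluded: tuple = ()   # unresolvable positions, reported not dropped silently

    def __float__(self):
        return self.fraction


def sidechain_conservation(
    graft: StructureModel,
    donor: StructureModel,
    positions,
    tolerance_deg: float = 60.0,
    graft_chain: str | None = None,
    donor_chain: str | None = None,
) -> ConservationResult:
    """Fraction of positions whose chi1 orientation is preserved.

    A position counts as conserved when the chi1 dihedrals in graft and
    donor differ by less than ``tolerance_deg`` (default 60 degrees, the
    rotamer-well width); residues without a chi1 (Gly, Ala) count as
    conserved.  Positions missing atoms in either structure are
    excluded and reported.  Chains default to searching all chains.
    """
    def _find(model, chain_id, p):
        chains = [model.chain(chain_id)] if chain_id else model.chains
        for c in chains:
            r = c.residue_at(p)
            if r is not None:
                return r
        return None

    conserved, changed, excluded = [], [], []
    for p in positions:
        rg = _find(graft, graft_chain, p)
        rd = _find(donor, donor_chain, p)
        if rg is None or rd is None:
            excluded.append((p, "unresolved position"))
            continue
        cg, cd = chi1(rg), chi1(rd)
        if cg is None and cd is None:
            conserved.append(p)  # Gly/Ala: no chi1 to change
            continue
        if cg is None or cd is None:
            excluded.append((p, "missing chi1 atoms"))
            continue
        if _angle_diff(cg, cd) < tolerance_deg:
            conserved.append(p)
        else:
            changed.append(p)
    compared = len(conserved) + len(changed)
    fraction = len(conserved) / compared if compared else 0.0
    return ConservationResult(
        fraction, tuple(conserved), tuple(changed), tuple(excluded)
    )


# -- annotation ---------------------------------------------------------------


def annotate_structure(
    model: StructureModel, numbered: NumberedDomain, chain_id: str
) -> StructureModel:
    """Label one chain's residues with IMGT positions.

    The chain sequence is extracted from the coordinates, numbered by
    alignment to ``numbered``, and the labels copied onto the residues.
    Unaligned residues (e.g. unmodelled termini handled by the free end
    gaps) stay unlabelled.
    """
    chain = model.chain(chain_id)
    dom = assign_imgt_numbering(chain.sequence, numbered)
    imap = dom.index_map
    new_residues = tuple(
        replace(r, imgt=imap.get(i)) for i, r in enumerate(chain.residues)
    )
    new_chains = tuple(
        ChainModel(c.chain_id, new_residues) if c.chain_id == chain_id else c
        for c in model.chains
    )
    return StructureModel(model.name, new_chains)


# -- reporting ----------------------------------------------------------------


def render_interface_diagram(cmap: ContactMap) -> str:
    """Deterministic text rendering of an interdomain contact map.

    Contacts are grouped by kind and listed in IMGT/author order; a
    pair is flagged ``symmetric`` when the reciprocal position pair is
    also in contact (the signature of an unbroken homodimer contact),
    otherwise ``asymmetric``.
    """
    lines = [
        "interface contact map",
        f"  hydrophobic cutoff {cmap.criteria.hydrophobic_cutoff:.1f} A | "
        f"ionic cutoff {cmap.criteria.ionic_cutoff:.1f} A",
    ]

    def _key(end: ContactEnd):
        return str(end.imgt) if end.imgt is not None else str(end.number)

    pairs = {(c.kind, _key(c.res_i), _key(c.res_j)) for c in cmap.contacts}
    for kind in ("ionic", "hydrophobic"):
        rows = cmap.of_kind(kind)
        lines.append(f"{kind} ({len(rows)})")
        for c in rows:
            sym = (
                "symmetric"
                if (kind, _key(c.res_j), _key(c.res_i)) in pairs
                else "asymmetric"
            )
            lines.append(
                f"  {c.res_i.label:<18} -- {c.res_j.label:<18} "
                f"{c.min_distance:6.2f} A  {sym}"
            )
    return "\n".join(lines) + "\n"
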