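"""Deterministic toy sequences and structures for testing the kernels.

The generator builds two-chain models with idealised residue geometry:
each residue is a short linear stick of the atoms the contact criteria
need, with the designated contact atoms of a pair facing each other at
an exact prescribed distance.  Pairs are spaced far apart so they
cannot interact; a seeded rigid motion of the whole model makes every
fixture unique yet bit-for-bit reproducible.  Fixtures exercise the
contact/superposition/chi1 kernels, not chemistry: there is no
Ramachandran or clash validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .positions import ImgtPosition
from .reference import NumberedDomain
from .structure import Atom, ChainModel, Residue, StructureModel

#: Side chains as linear sticks, listed backbone-out; the last atom is
#: the designated contact atom.  (name, element) per atom.
_TEMPLATES: dict[str, tuple[tuple[str, str], ...]] = {
    "LYS": (("N", "N"), ("CA", "C"), ("CB", "C"), ("CG", "C"), ("CD", "C"), ("CE", "C"), ("NZ", "N")),
    "ARG": (("N", "N"), ("CA", "C"), ("CB", "C"), ("CG", "C"), ("CD", "C"), ("NE", "N"), ("NH1", "N")),
    "HIS": (("N", "N"), ("CA", "C"), ("CB", "C"), ("CG", "C"), ("ND1", "N")),
    "GLU": (("N", "N"), ("CA", "C"), ("CB", "C"), ("CG", "C"), ("CD", "C"), ("OE1", "O")),
    "ASP": (("N", "N"), ("CA", "C"), ("CB", "C"), ("CG", "C"), ("OD1", "O")),
    "LEU": (("N", "N"), ("CA", "C"), ("CB", "C"), ("CG", "C"), ("CD1", "C")),
    "ILE": (("N", "N"), ("CA", "C"), ("CB", "C"), ("CG1", "C"), ("CD1", "C")),
    "VAL": (("N", "N"), ("CA", "C"), ("CB", "C"), ("CG1", "C")),
    "MET": (("N", "N"), ("CA", "C"), ("CB", "C"), ("CG", "C"), ("SD", "S"), ("CE", "C")),
    "PHE": (("N", "N"), ("CA", "C"), ("CB", "C"), ("CG", "C"), ("CD1", "C")),
    "TYR": (("N", "N"), ("CA", "C"), ("CB", "C"), ("CG", "C"), ("CD1", "C")),
    "TRP": (("N", "N"), ("CA", "C"), ("CB", "C"), ("CG", "C"), ("CD1", "C")),
    "PRO": (("N", "N"), ("CA", "C"), ("CB", "C"), ("CG", "C"), ("CD", "C")),
    "ALA": (("N", "N"), ("CA", "C"), ("CB", "C")),
    "SER": (("N", "N"), ("CA", "C"), ("CB", "C"), ("OG", "O")),
    "THR": (("N", "N"), ("CA", "C"), ("CB", "C"), ("OG1", "O")),
    "GLN": (("N", "N"), ("CA", "C"), ("CB", "C"), ("CG", "C"), ("CD", "C"), ("NE2", "N")),
    "ASN": (("N", "N"), ("CA", "C"), ("CB", "C"), ("CG", "C"), ("ND2", "N")),
    "GLY": (("N", "N"), ("CA", "C")),
    "CYS": (("N", "N"), ("CA", "C"), ("CB", "C"), ("SG", "S")),
}

_ATOM_SPACING = 1.5   # A between consecutive stick atoms
_PAIR_SPACING = 25.0  # A between consecutive pairs: beyond any cutoff


@dataclass(frozen=True)
class ContactPairSpec:
    """One facing residue pair with an exact contact-atom distance."""

    res_a: str
    res_b: str
    distance: float
    imgt_a: ImgtPosition | None = None
    imgt_b: ImgtPosition | None = None


@dataclass(frozen=True)
class FixtureSpec:
    """A reproducible two-chain contact fixture."""

    seed: int = 0
    pairs: tuple[ContactPairSpec, ...] = ()

    def __post_init__(self):
        for p in self.pairs:
            if p.res_a not in _TEMPLATES or p.res_b not in _TEMPLATES:
                raise ValueError(f"unknown residue in pair: {p.res_a}/{p.res_b}")
            if not (0.5 <= p.distance <= _PAIR_SPACING - 5.0):
                raise ValueError(
                    f"unrealizable contact distance {p.distance} A "
                    f"(must lie in [0.5, {_PAIR_SPACING - 5.0}] A)"
                )


def _stick(template, tip: np.ndarray, direction: np.ndarray) -> list[Atom]:
    """Build a residue stick with its last (contact) atom at ``tip``
    and earlier atoms receding along ``direction``."""
    atoms = []
    n = len(template)
    for k, (name, element) in enumerate(template):
        offset = (n - 1 - k) * _ATOM_SPACING
        xyz = tip + direction * offset
        atoms.append(Atom(name, element, tuple(float(v) for v in xyz)))
    return atoms


def _random_rigid_motion(rng: np.random.Generator):
    # uniform-ish random rotation from a normalised quaternion
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-50, 50, size=3)
    return R, t


def make_contact_fixture(spec: FixtureSpec) -> StructureModel:
    """Two-chain model whose qualifying contact distances match the spec.

    Within each pair the contact atoms face each other across the
    interface axis at exactly the prescribed distance; the remaining
    stick atoms recede away from the partner chain, so the pairwise
    minimum over qualifying atoms equals the spec distance.  The whole
    model is then moved by a seeded rigid motion (distances preserved).
    """
    rng = np.random.default_rng(spec.seed)
    R, t = _random_rigid_motion(rng)

    res_a, res_b = [], []
    for k, pair in enumerate(spec.pairs):
        y = k * _PAIR_SPACING
        tip_a = np.array([0.0, y, 0.0])
        tip_b = np.array([pair.distance, y, 0.0])
        atoms_a = _stick(_TEMPLATES[pair.res_a], tip_a, np.array([-1.0, 0.0, 0.0]))
        atoms_b = _stick(_TEMPLATES[pair.res_b], tip_b, np.array([1.0, 0.0, 0.0]))
        atoms_a = [Atom(a.name, a.element, tuple(R @ a.coords + t)) for a in atoms_a]
        atoms_b = [Atom(a.name, a.element, tuple(R @ a.coords + t)) for a in atoms_b]
        res_a.append(Residue(pair.res_a, k + 1, tuple(atoms_a), imgt=pair.imgt_a))
        res_b.append(Residue(pair.res_b, k + 1, tuple(atoms_b), imgt=pair.imgt_b))

    model = StructureModel(
        f"contact-fixture(seed={spec.seed})",
        (ChainModel("A", tuple(res_a)), ChainModel("B", tuple(res_b))),
    )
    model.validate()
    return model


def _place_dihedral(a, b, c, bond, angle_deg, dihedral_deg) -> np.ndarray:
    """Internal-to-cartesian placement (NeRF) of a fourth atom."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = math.radians(angle_deg)
    # +180: the frame below measures the torsion from the eclipsed
    # direction, whereas the IUPAC convention is anti = 180
    dih = math.radians(dihedral_deg + 180.0)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array(
        [-math.cos(ang), math.sin(ang) * math.cos(dih), math.sin(ang) * math.sin(dih)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


_GAMMA_NAME = {"SER": "OG", "THR": "OG1", "VAL": "CG1", "ILE": "CG1", "CYS": "SG"}


def make_rotamer_fixture(
    residues, chi1_angles, chain_id: str = "A", imgt=None, name: str = "rotamer-fixture"
) -> StructureModel:
    """Single-chain model with residues at prescribed chi1 dihedrals.

    Each residue carries N, CA, CB and its gamma atom built with
    canonical bond geometry (1.46/1.53/1.52 A, 111 deg angles) so the
    measured N-CA-CB-gamma torsion equals the requested angle.
    """
    residues = list(residues)
    chi1_angles = list(chi1_angles)
    if len(residues) != len(chi1_angles):
        raise ValueError("one chi1 angle per residue required")
    imgt = list(imgt) if imgt is not None else [None] * len(residues)
    out = []
    for k, (rname, chi, label) in enumerate(zip(residues, chi1_angles, imgt)):
        if rname in ("GLY", "ALA"):
            raise ValueError(f"{rname} has no chi1")
        offset = np.array([0.0, 10.0 * k, 0.0])
        ca = offset
        n = offset + np.array([1.46, 0.0, 0.0])
        cb = offset + 1.53 * np.array(
            [math.cos(math.radians(111.0)), math.sin(math.radians(111.0)), 0.0]
        )
        gname = _GAMMA_NAME.get(rname, "CG")
        g = _place_dihedral(n, ca, cb, 1.52, 111.0, chi)
        atoms = (
            Atom("N", "N", tuple(n)),
            Atom("CA", "C", tuple(ca)),
            Atom("CB", "C", tuple(cb)),
            Atom(gname, "O" if gname.startswith("O") else ("S" if gname.startswith("S") else "C"), tuple(g)),
        )
        lab = ImgtPosition.parse(label) if label is not None else None
        out.append(Residue(rname, k + 1, atoms, imgt=lab))
    return StructureModel(name, (ChainModel(chain_id, tuple(out)),))


def make_mutant_sequence(reference: NumberedDomain, perturbations) -> str:
    """Reference sequence with point changes at IMGT positions.

    ``perturbations`` is an iterable of (position, new_residue); unknown
    positions raise KeyError.
    """
    seq = list(reference.sequence)
    pmap = reference.position_map
    for label, aa in perturbations:
        p = ImgtPosition.parse(label)
        if p not in pmap:
            raise KeyError(f"position {p} not in {reference.domain_class}")
        seq[pmap[p]] = aa
    return "".join(seq)
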