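"""Heterodimer design by interface exchange.

Two routes generate an engineered pair from the packaged references:

* **full-interface grafting** — a natural heterodimer (TCR Ca-Cb or
  Cg-Cd) donates its complete interface to both chains of an acceptor
  homodimer (:func:`full_interface_graft`);
* **half-interface mixing** — two homodimers each donate one half of
  the interface partition, breaking the acceptor's symmetry
  (:func:`half_interface_graft`).

Both routes share the same mechanics: at every grafted position the
acceptor residue is replaced by the donor residue at the 3D-equivalent
IMGT position; a substitution is emitted only where the two differ
(*skip-identical*), and a donor cysteine is imported as alanine to
prevent disulfide mispairing (*cys-avoidance*), with every rule firing
recorded in the audit trail.

Named variants (Q3A, R90T, D84.4Q, W81T, Protein-A engineering) refine
a generated pair through :func:`apply_variant` /
:func:`add_protein_a_binding`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .catalog import CATALOG, InterfaceCatalog
from .errors import MissingPositionError, VariantNotApplicableError
from .positions import ImgtPosition
from .reference import (
    CLASS_LETTER,
    HOMODIMER_CLASSES,
    NumberedDomain,
    get_reference,
)

_SUB_RE = re.compile(r"^([A-Z])(\d+(?:\.\d+)?)([A-Z])$")


@dataclass(frozen=True)
class Substitution:
    """A point substitution in compact notation, e.g. ``S20K``, ``F85.1A``."""

    wt: str
    position: ImgtPosition
    mut: str

    def __post_init__(self):
        if self.wt == self.mut:
            raise ValueError(f"wt equals mut at {self.position}: {self.wt}")

    @classmethod
    def parse(cls, text: str) -> "Substitution":
        m = _SUB_RE.match(text.strip())
        if not m:
            raise ValueError(f"not a substitution: {text!r}")
        return cls(m.group(1), ImgtPosition.parse(m.group(2)), m.group(3))

    def __str__(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"


def apply_substitutions(
    domain: NumberedDomain, subs: tuple[Substitution, ...], name: str = ""
) -> NumberedDomain:
    """Apply substitutions to a numbered domain, checking wild types."""
    seq = list(domain.sequence)
    pmap = domain.position_map
    for s in subs:
        try:
            i = pmap[s.position]
        except KeyError:
            raise MissingPositionError(domain.name or domain.domain_class, s.position)
        if seq[i] != s.wt:
            raise ValueError(
                f"wild-type mismatch at {s.position}: expected {s.wt}, found {seq[i]}"
            )
        seq[i] = s.mut
    return replace(domain, sequence="".join(seq), name=name or domain.name)


@dataclass(frozen=True)
class EngineeredPair:
    """Two engineered chains with their substitution lists and provenance."""

    chain_a: NumberedDomain
    chain_b: NumberedDomain
    subs_a: tuple[Substitution, ...]
    subs_b: tuple[Substitution, ...]
    design_name: str
    acceptor: str = ""
    donor_a: str = ""
    donor_b: str = ""
    rules_applied: tuple[str, ...] = ()

    def compact(self, chain: str) -> tuple[str, ...]:
        """Substitutions of one chain ("A" or "B") in compact notation."""
        return tuple(str(s) for s in self._subs(chain))

    def _subs(self, chain: str) -> tuple[Substitution, ...]:
        if chain == "A":
            return self.subs_a
        if chain == "B":
            return self.subs_b
        raise ValueError(f"chain must be 'A' or 'B', got {chain!r}")

    def _chain(self, chain: str) -> NumberedDomain:
        return self.chain_a if chain == "A" else self.chain_b


def _sorted_positions(labels) -> tuple[ImgtPosition, ...]:
    return tuple(sorted(ImgtPosition.parse(p) for p in labels))


def _graft_chain(
    acceptor: NumberedDomain,
    donor: NumberedDomain,
    positions,
    chain_name: str,
    log: list[str],
) -> tuple[NumberedDomain, tuple[Substitution, ...]]:
    subs = []
    for p in _sorted_positions(positions):
        for party in (acceptor, donor):
            if not party.has_position(p):
                raise MissingPositionError(party.name or party.domain_class, p)
        acc_res = acceptor.residue_at(p)
        don_res = donor.residue_at(p)
        if don_res == "C":
            log.append(
                f"cys-avoidance[{chain_name}]: donor Cys at {p} imported as Ala"
            )
            don_res = "A"
        if don_res == acc_res:
            log.append(f"skip-identical[{chain_name}]: {acc_res}{p}")
            continue
        subs.append(Substitution(acc_res, p, don_res))
    subs = tuple(subs)
    chain = apply_substitutions(acceptor, subs, name=chain_name)
    return chain, subs


def full_interface_graft(
    acceptor: NumberedDomain,
    donor_a: NumberedDomain,
    donor_b: NumberedDomain,
    positions=None,
    positions_a=None,
    positions_b=None,
    design_name: str | None = None,
    catalog: InterfaceCatalog = CATALOG,
) -> EngineeredPair:
    """Graft a donor interface pair onto an acceptor homodimer.

    Chain A receives ``donor_a``'s residues, chain B ``donor_b``'s, at
    the requested positions (default: the catalog's key sets plus
    supporting positions).  ``positions_a``/``positions_b`` override the
    per-chain set, which reduced designs use.
    """
    base = catalog.graft_positions if positions is None else _sorted_positions(positions)
    pa = base if positions_a is None else _sorted_positions(positions_a)
    pb = base if positions_b is None else _sorted_positions(positions_b)
    name = design_name or (
        f"graft({acceptor.domain_class} <- {donor_a.domain_class}/{donor_b.domain_class})"
    )
    log: list[str] = []
    chain_a, subs_a = _graft_chain(acceptor, donor_a, pa, f"{name} (A)", log)
    chain_b, subs_b = _graft_chain(acceptor, donor_b, pb, f"{name} (B)", log)
    return EngineeredPair(
        chain_a,
        chain_b,
        subs_a,
        subs_b,
        design_name=name,
        acceptor=acceptor.domain_class,
        donor_a=donor_a.domain_class,
        donor_b=donor_b.domain_class,
        rules_applied=tuple(log),
    )


def half_interface_graft(
    acceptor: NumberedDomain,
    donor: NumberedDomain,
    catalog: InterfaceCatalog = CATALOG,
) -> EngineeredPair:
    """Mix two homodimer interfaces into a heterodimer (MI design).

    Chain 1 takes the donor's residues on half-side 1 (88, 20 with
    supporting 79, 81, 90), chain 2 on half-side 2 (26, 85.1, 86 with
    supporting 3, 5, 84, 84.2).  The design name follows the two-letter
    convention: first letter = Ig class providing position 88, second =
    class providing 85.1/86.
    """
    for party in (acceptor, donor):
        if party.domain_class not in HOMODIMER_CLASSES:
            raise ValueError(
                f"{party.domain_class} is not a homodimer-forming class; "
                "half-interface mixing needs two homodimers"
            )
    acc = CLASS_LETTER[acceptor.domain_class]
    don = CLASS_LETTER[donor.domain_class]
    dom_type = "CH4" if acceptor.domain_class.endswith("CH4") else "CH3"
    c1, c2 = don + acc, acc + don
    name = f"MI ({dom_type}) {c1}/{c2}"
    log: list[str] = []
    chain_1, subs_1 = _graft_chain(acceptor, donor, catalog.half_side_1, c1, log)
    chain_2, subs_2 = _graft_chain(acceptor, donor, catalog.half_side_2, c2, log)
    return EngineeredPair(
        chain_1,
        chain_2,
        subs_1,
        subs_2,
        design_name=name,
        acceptor=acceptor.domain_class,
        donor_a=donor.domain_class,
        donor_b=donor.domain_class,
        rules_applied=tuple(log),
    )


# -- named variants -----------------------------------------------------------

#: Closed registry of named variant rules: target position, residue the
#: rule expects to find, residue it installs.  Application is
#: revert-or-add: if the rule undoes an existing substitution the entry
#: is removed, otherwise a new substitution is appended.
VARIANT_REGISTRY: dict[str, tuple[str, str, str]] = {
    "Q3A": ("3", "Q", "A"),        # reduce steric bulk on chain (A)
    "R90T": ("90", "R", "T"),      # undo T90R on chain (B)
    "D84.4Q": ("84.4", "D", "Q"),  # destabilise (B)/(B) homodimer
    "W81T": ("81", "W", "T"),      # Trp 81 probe for mixed/strand-exchanged designs
}


def apply_variant(pair: EngineeredPair, variant: str, chain: str = None) -> EngineeredPair:
    """Apply a named variant rule to one chain of an engineered pair.

    ``variant`` accepts ``"D84.4Q@B"`` or (``"D84.4Q"``, ``chain="B"``).
    """
    if "@" in variant:
        variant, chain = variant.split("@", 1)
    if chain not in ("A", "B"):
        raise ValueError("variant needs a target chain 'A' or 'B'")
    if variant not in VARIANT_REGISTRY:
        raise ValueError(
            f"unknown variant {variant!r}; registry: {sorted(VARIANT_REGISTRY)}"
        )
    label, expected, new_res = VARIANT_REGISTRY[variant]
    position = ImgtPosition.parse(label)

    target = pair._chain(chain)
    subs = list(pair._subs(chain))
    if not target.has_position(position):
        raise MissingPositionError(target.name or target.domain_class, position)
    observed = target.residue_at(position)
    if observed != expected:
        raise VariantNotApplicableError(variant, position, expected, observed)

    existing = [s for s in subs if s.position == position]
    if existing and existing[0].wt == new_res:
        # the rule reverts a previous substitution: drop the entry
        subs.remove(existing[0])
        audit = f"variant {variant}@{chain}: reverted {existing[0]}"
    elif existing:
        raise VariantNotApplicableError(variant, position, expected, observed)
    else:
        subs.append(Substitution(observed, position, new_res))
        audit = f"variant {variant}@{chain}: added {observed}{position}{new_res}"
    subs = tuple(sorted(subs, key=lambda s: s.position))

    seq = list(target.sequence)
    seq[target.position_map[position]] = new_res
    new_chain = replace(target, sequence="".join(seq))

    kw = {"rules_applied": pair.rules_applied + (audit,),
          "design_name": f"{pair.design_name} {variant}({chain})"}
    if chain == "A":
        return replace(pair, chain_a=new_chain, subs_a=subs, **kw)
    return replace(pair, chain_b=new_chain, subs_b=subs, **kw)


_PA_SUBS = (Substitution.parse("R115H"), Substitution.parse("V116Y"))


def add_protein_a_binding(domain: NumberedDomain) -> NumberedDomain:
    """Engineer Protein A binding into a CH4 domain (R115H + V116Y).

    CH4 domains do not bind Protein A; the two FG-loop substitutions
    install the binding determinants found in IgG1 CH3 (His 115, Tyr
    116).  Errors on a non-CH4 class or when the wild-type residues at
    115/116 are not Arg/Val (e.g. the domain is already engineered).
    """
    if not domain.domain_class.endswith("CH4"):
        raise ValueError(
            f"Protein A engineering applies to CH4 domains, not {domain.domain_class}"
        )
    for s in _PA_SUBS:
        if not domain.has_position(s.position):
            raise MissingPositionError(domain.name or domain.domain_class, s.position)
        observed = domain.residue_at(s.position)
        if observed != s.wt:
            raise VariantNotApplicableError("pA", s.position, s.wt, observed)
    return apply_substitutions(
        domain, _PA_SUBS, name=(domain.name or domain.domain_class) + " pA"
    )


def with_protein_a(pair: EngineeredPair) -> EngineeredPair:
    """Apply Protein A engineering to both CH4 chains of a pair."""
    chain_a = add_protein_a_binding(pair.chain_a)
    chain_b = add_protein_a_binding(pair.chain_b)
    subs_a = tuple(sorted(pair.subs_a + _PA_SUBS, key=lambda s: s.position))
    subs_b = tuple(sorted(pair.subs_b + _PA_SUBS, key=lambda s: s.position))
    return replace(
        pair,
        chain_a=chain_a,
        chain_b=chain_b,
        subs_a=subs_a,
        subs_b=subs_b,
        design_name=pair.design_name + " pA",
        rules_applied=pair.rules_applied + ("pA: R115H + V116Y on both chains",),
    )


# -- packaged designs ---------------------------------------------------------


def beat() -> EngineeredPair:
    """TCR Ca-Cb interface grafted onto the IgG1 CH3 homodimer (BEAT)."""
    return full_interface_graft(
        get_reference("IgG1-CH3"),
        get_reference("TCR-Ca"),
        get_reference("TCR-Cb"),
        design_name="BEAT",
    )


def beat_min() -> EngineeredPair:
    """Reduced-substitution redesign of the TCR Ca-Cb graft (BEAT min).

    Chain A keeps the key/supporting substitutions at 20, 22, 26, 79,
    88 and 90; chain B keeps only the 85.1/86 exchanges.
    """
    return full_interface_graft(
        get_reference("IgG1-CH3"),
        get_reference("TCR-Ca"),
        get_reference("TCR-Cb"),
        positions_a=("20", "22", "26", "79", "88", "90"),
        positions_b=("85.1", "86"),
        design_name="BEAT min",
    )


def beat_gd() -> EngineeredPair:
    """TCR Cg-Cd interface grafted onto IgG1 CH3 (BEAT G/D), same position set."""
    return full_interface_graft(
        get_reference("IgG1-CH3"),
        get_reference("TCR-Cg"),
        get_reference("TCR-Cd"),
        design_name="BEAT G/D",
    )


def beat_ch4() -> EngineeredPair:
    """TCR Ca-Cb interface grafted onto the IgM CH4 homodimer (BEAT CH4)."""
    return full_interface_graft(
        get_reference("IgM-CH4"),
        get_reference("TCR-Ca"),
        get_reference("TCR-Cb"),
        design_name="BEAT CH4",
    )


def mixed_interface(acceptor_class: str, donor_class: str) -> EngineeredPair:
    """MI design from two packaged homodimer references."""
    return half_interface_graft(
        get_reference(acceptor_class), get_reference(donor_class)
    )
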