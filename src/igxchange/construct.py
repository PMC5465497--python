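"""Sequence-level construct assembly and design reporting.

Engineered CH3/CH4 pairs become Fc-like proteins by fusing each chain
downstream of the IgG1 hinge (DKTHTCPPCP) and CH2 domain; a VL
domain-antibody fused to one chain gives the two species distinct
molecular weights, and an scFv x Fab arrangement avoids light-chain
mispairing in full bispecifics.  The Protein-A-site annotation is a
static isotype tag (an IgG3-derived CH3 does not bind Protein A, a CH4
only binds after the pA engineering); it is not a binding predictor.
Masses are average polypeptide masses without glycans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .design import EngineeredPair
from .errors import UnknownResidueError
from .structure import render_interface_diagram

#: Average residue (amino acid minus water) masses, Da.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.01528

DEFAULT_HINGE = "DKTHTCPPCP"

_segment_cache: dict[str, str] | None = None


def load_segments() -> dict[str, str]:
    """Packaged construct segments (hinge, CH2, CH1, CL, V placeholders)."""
    global _segment_cache
    if _segment_cache is None:
        text = resources.files("igxchange.data").joinpath("segments.fasta").read_text()
        segs, name, chunks = {}, None, []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name:
                    segs[name] = "".join(chunks)
                name, chunks = line[1:].split(None, 1)[0], []
            else:
                chunks.append(line)
        if name:
            segs[name] = "".join(chunks)
        _segment_cache = segs
    return _segment_cache


def chain_mass(sequence: str) -> float:
    """Average polypeptide mass in kDa (no glycans or other PTMs).

    Residue masses plus one water; the empty chain returns the mass of
    water by convention.  Unknown letters raise.
    """
    total = WATER_MASS
    for aa in sequence:
        try:
            total += AVERAGE_RESIDUE_MASS[aa]
        except KeyError:
            raise UnknownResidueError(f"unknown amino acid letter {aa!r}") from None
    return total / 1000.0


@dataclass(frozen=True)
class ConstructTemplate:
    """Ordered segment plan for one Fc-like chain (before the engineered
    domain, which is always the final segment)."""

    name: str = "fc-like"
    segments: tuple[str, ...] = ("hinge_igg1", "ch2_igg1")
    isotype_tags: dict = field(default_factory=dict)  # e.g. {"A": "IgG3-CH3"}

    def resolve(self) -> tuple[str, ...]:
        segs = load_segments()
        missing = [s for s in self.segments if s not in segs]
        if missing:
            raise KeyError(f"missing segment sequence(s): {missing}")
        return tuple(segs[s] for s in self.segments)


DEFAULT_FC_TEMPLATE = ConstructTemplate()


def _protein_a_sites(domain_class_tag: str, rules_applied: tuple[str, ...]) -> int:
    """Binding-competent Protein-A sites contributed by one CH3/CH4 tag."""
    if domain_class_tag.endswith("CH4"):
        return 1 if any(r.startswith("pA") for r in rules_applied) else 0
    if domain_class_tag == "IgG3-CH3":
        return 0
    return 1


@dataclass(frozen=True)
class ChainSet:
    """Named chains of an assembled design with Protein-A annotation."""

    design_name: str
    chains: dict
    protein_a_sites: dict

    @property
    def protein_a_label(self) -> str:
        n = sum(self.protein_a_sites.values())
        return {0: "A(0)", 1: "A(+)", 2: "A(2+)"}.get(n, f"A({n}+)")

    def masses_kda(self) -> dict:
        return {name: chain_mass(seq) for name, seq in self.chains.items()}


def assemble_fc_like(
    pair: EngineeredPair,
    template: ConstructTemplate = DEFAULT_FC_TEMPLATE,
    fusion_chain: str | None = None,
    fusion_segment: str = "vl_dab_synthetic",
) -> ChainSet:
    """Fc-like protein from an engineered pair: [VL-dAb +] hinge + CH2 +
    engineered domain per chain.

    ``fusion_chain`` ("A" or "B") N-terminally fuses the VL domain
    antibody to exactly one chain so homo- and heterodimers separate by
    molecular weight.
    """
    stem = "".join(template.resolve())
    segs = load_segments()
    if fusion_chain not in (None, "A", "B"):
        raise ValueError("fusion_chain must be None, 'A' or 'B'")
    fusion = segs[fusion_segment] if fusion_chain else ""
    chains, sites = {}, {}
    for side, dom in (("A", pair.chain_a), ("B", pair.chain_b)):
        seq = stem + dom.sequence
        if side == fusion_chain:
            seq = fusion + seq
        label = f"Fc({side})" if side != fusion_chain else f"VL-Fc({side})"
        chains[label] = seq
        tag = template.isotype_tags.get(side, dom.domain_class)
        sites[label] = _protein_a_sites(tag, pair.rules_applied)
    return ChainSet(pair.design_name, chains, sites)


def assemble_scfv_fab(
    pair: EngineeredPair,
    template: ConstructTemplate = DEFAULT_FC_TEMPLATE,
) -> ChainSet:
    """scFv x Fab bispecific chain set (sequence level, placeholder V domains).

    Chain A carries the scFv arm (VH-linker-VL), chain B the Fab heavy
    chain (VH-CH1), plus the common light chain; the two arms differ in
    format so light-chain mispairing cannot occur.
    """
    segs = load_segments()
    stem = "".join(template.resolve())
    scfv = segs["vh_synthetic"] + segs["linker_scfv"] + segs["vl_synthetic"]
    chains = {
        "scFv-Fc(A)": scfv + stem + pair.chain_a.sequence,
        "Fab-Hc(B)": segs["vh_synthetic"] + segs["ch1_igg1"] + stem + pair.chain_b.sequence,
        "Lc": segs["vl_synthetic"] + segs["cl_kappa"],
    }
    sites = {
        "scFv-Fc(A)": _protein_a_sites(
            template.isotype_tags.get("A", pair.chain_a.domain_class),
            pair.rules_applied,
        ),
        "Fab-Hc(B)": _protein_a_sites(
            template.isotype_tags.get("B", pair.chain_b.domain_class),
            pair.rules_applied,
        ),
        "Lc": 0,
    }
    return ChainSet(pair.design_name + " scFv x Fab", chains, sites)


def design_report(pair: EngineeredPair, maps=None) -> str:
    """Deterministic plain-text report of a design."""
    lines = [
        f"design: {pair.design_name}",
        f"acceptor: {pair.acceptor}  donors: {pair.donor_a} / {pair.donor_b}",
        "",
    ]
    for side, subs in (("A", pair.subs_a), ("B", pair.subs_b)):
        compact = ", ".join(str(s) for s in subs) if subs else "(none)"
        lines.append(f"chain ({side}): {len(subs)} substitution(s): {compact}")
        lines.append("  chain\twt\timgt_position\tmut")
        for s in subs:
            lines.append(f"  {side}\t{s.wt}\t{s.position}\t{s.mut}")
        lines.append("")
    lines.append("rules applied:")
    for rule in pair.rules_applied:
        lines.append(f"  - {rule}")
    if not pair.rules_applied:
        lines.append("  (none)")
    if maps:
        for cmap in maps:
            lines.append("")
            lines.append(render_interface_diagram(cmap).rstrip("\n"))
    return "\n".join(lines) + "\n"
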