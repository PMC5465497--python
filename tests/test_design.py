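"""Interface-exchange design engine: grafts, variants, invariants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igxchange import (
    CATALOG,
    Substitution,
    add_protein_a_binding,
    apply_variant,
    beat,
    beat_ch4,
    beat_gd,
    beat_min,
    full_interface_graft,
    get_reference,
    half_interface_graft,
    mixed_interface,
    with_protein_a,
)
from igxchange.design import apply_substitutions
from igxchange.errors import MissingPositionError, VariantNotApplicableError

HOMODIMERS = ["IgG1-CH3", "IgG3-CH3", "IgA-CH3", "IgD-CH3", "IgM-CH4"]
ALL_CLASSES = HOMODIMERS + ["TCR-Ca", "TCR-Cb", "TCR-Cg", "TCR-Cd"]


def oracle_graft(acceptor, donor, positions):
    """Per-position lookup in the packaged numbered references."""
    out = []
    for p in sorted(positions):
        a, d = acceptor.residue_at(p), donor.residue_at(p)
        if d == "C":
            d = "A"
        if a != d:
            out.append(f"{a}{p}{d}")
    return out


# -- substitution notation ----------------------------------------------------


@pytest.mark.parametrize("text", ["S20K", "F85.1A", "D84.4Q", "R115H"])
def test_substitution_roundtrip(text):
    assert str(Substitution.parse(text)) == text


def test_substitution_rejects_silent():
    with pytest.raises(ValueError):
        Substitution.parse("S20S")


# -- full-interface grafting --------------------------------------------------


def test_tcr_ab_graft_onto_igg1_ch3(refs):
    """The TCR Ca-Cb graft emits the canonical chain A/B lists."""
    pair = beat()
    assert pair.compact("A") == (
        "S20K", "T22V", "K26T", "K79Y", "F85.1S", "Y86V", "K88W", "T90N"
    )
    assert pair.compact("B") == (
        "Q3E", "Y5A", "L7F", "S20T", "T22V", "K26T", "T81D",
        "V84L", "D84.2E", "F85.1A", "Y86S", "K88R", "T90R"
    )
    assert any("cys-avoidance" in r and "85.1" in r for r in pair.rules_applied)


def test_self_graft_is_empty(igg1):
    pair = full_interface_graft(igg1, igg1, igg1)
    assert pair.subs_a == () and pair.subs_b == ()
    assert pair.chain_a.sequence == igg1.sequence


def test_ch4_graft_matches_reference_lookup(refs):
    """TCR Ca-Cb onto IgM CH4: generated lists equal the manual lookup."""
    pair = beat_ch4()
    acc = refs["IgM-CH4"]
    assert list(pair.compact("A")) == oracle_graft(acc, refs["TCR-Ca"], CATALOG.graft_positions)
    assert list(pair.compact("B")) == oracle_graft(acc, refs["TCR-Cb"], CATALOG.graft_positions)


def test_gd_graft_uses_the_same_position_set(refs):
    """TCR Cg-Cd graft touches the same grafted positions as the Ca-Cb one."""
    gd = beat_gd()
    allowed = set(CATALOG.graft_positions)
    touched = {s.position for s in gd.subs_a + gd.subs_b}
    assert touched <= allowed
    assert gd.subs_a and gd.subs_b
    assert gd.compact("A") != gd.compact("B")
    acc = refs["IgG1-CH3"]
    assert list(gd.compact("A")) == oracle_graft(acc, refs["TCR-Cg"], CATALOG.graft_positions)
    assert list(gd.compact("B")) == oracle_graft(acc, refs["TCR-Cd"], CATALOG.graft_positions)


def test_missing_position_error_names_the_party(igg1, refs):
    from igxchange import assign_imgt_numbering

    truncated = assign_imgt_numbering(igg1.sequence[2:-4], igg1, name="truncated CH3")
    with pytest.raises(MissingPositionError) as err:
        full_interface_graft(truncated, refs["TCR-Ca"], refs["TCR-Cb"], positions=["2"])
    assert err.value.position == __import__("igxchange").pos(2)
    assert "truncated CH3" in str(err.value)


# -- reduced design -----------------------------------------------------------


def test_reduced_graft_lists():
    pair = beat_min()
    assert pair.compact("A") == ("S20K", "T22V", "K26T", "K79Y", "K88W", "T90N")
    assert pair.compact("B") == ("F85.1A", "Y86S")


def test_reduced_design_is_contained_in_the_full_graft():
    full, mini = beat(), beat_min()
    assert set(mini.compact("A")) < set(full.compact("A"))
    assert set(mini.compact("B")) < set(full.compact("B"))


# -- half-interface mixing ----------------------------------------------------


def test_mixed_interface_dg_gd(refs):
    pair = mixed_interface("IgG1-CH3", "IgD-CH3")
    assert pair.design_name == "MI (CH3) DG/GD"
    side1 = {str(p) for p in CATALOG.half_side_1}
    side2 = {str(p) for p in CATALOG.half_side_2}
    assert {str(s.position) for s in pair.subs_a} <= side1
    assert {str(s.position) for s in pair.subs_b} <= side2
    acc, don = refs["IgG1-CH3"], refs["IgD-CH3"]
    assert list(pair.compact("A")) == oracle_graft(acc, don, CATALOG.half_side_1)
    assert list(pair.compact("B")) == oracle_graft(acc, don, CATALOG.half_side_2)


def test_mixed_interface_ch4_naming():
    assert mixed_interface("IgM-CH4", "IgG1-CH3").design_name == "MI (CH4) GM/MG"
    assert mixed_interface("IgG1-CH3", "IgA-CH3").design_name == "MI (CH3) AG/GA"
    assert mixed_interface("IgG1-CH3", "IgM-CH4").design_name == "MI (CH3) MG/GM"


def test_self_mix_is_empty(igg1):
    pair = half_interface_graft(igg1, igg1)
    assert pair.subs_a == () and pair.subs_b == ()


def test_half_graft_requires_homodimer_classes(igg1, refs):
    with pytest.raises(ValueError):
        half_interface_graft(igg1, refs["TCR-Ca"])


# -- named variants -----------------------------------------------------------


def test_variant_d84_4q_appends():
    pair = apply_variant(beat(), "D84.4Q@B")
    assert "D84.4Q" in pair.compact("B")
    assert pair.chain_b.residue_at("84.4") == "Q"


def test_variant_q3a_appends_on_chain_a():
    pair = apply_variant(beat(), "Q3A@A")
    assert "Q3A" in pair.compact("A")


def test_variant_r90t_reverts_t90r():
    pair = apply_variant(beat(), "R90T@B")
    assert "T90R" not in pair.compact("B")
    assert pair.chain_b.residue_at(90) == "T"
    assert len(pair.subs_b) == 12


def test_variant_reapplication_errors():
    pair = apply_variant(beat(), "R90T@B")
    with pytest.raises(VariantNotApplicableError) as err:
        apply_variant(pair, "R90T@B")
    assert err.value.observed == "T"


def test_variant_w81t_probes_the_mixed_ag_interface():
    pair = mixed_interface("IgG1-CH3", "IgA-CH3")
    assert pair.chain_a.residue_at(81) == "W"
    back = apply_variant(pair, "W81T@A")
    assert pair.compact("A") != back.compact("A")
    assert back.chain_a.residue_at(81) == "T"
    assert all(str(s.position) != "81" for s in back.subs_a)


def test_unknown_variant_rejected():
    with pytest.raises(ValueError):
        apply_variant(beat(), "K409R@B")


# -- Protein A engineering ----------------------------------------------------


def test_protein_a_binding_on_ch4(refs):
    dom = add_protein_a_binding(refs["IgM-CH4"])
    assert dom.residue_at(115) == "H"
    assert dom.residue_at(116) == "Y"


def test_protein_a_twice_is_wt_mismatch(refs):
    dom = add_protein_a_binding(refs["IgM-CH4"])
    with pytest.raises(VariantNotApplicableError):
        add_protein_a_binding(dom)


def test_protein_a_rejected_on_ch3(igg1):
    with pytest.raises(ValueError):
        add_protein_a_binding(igg1)


def test_protein_a_composes_with_the_ch4_graft():
    pair = with_protein_a(beat_ch4())
    assert pair.design_name == "BEAT CH4 pA"
    for chain in ("A", "B"):
        assert "R115H" in pair.compact(chain)
        assert "V116Y" in pair.compact(chain)


# -- engine invariants --------------------------------------------------------


ALL_PAIRS = [beat, beat_min, beat_gd, beat_ch4,
             lambda: mixed_interface("IgG1-CH3", "IgA-CH3"),
             lambda: mixed_interface("IgG1-CH3", "IgD-CH3"),
             lambda: mixed_interface("IgG1-CH3", "IgM-CH4"),
             lambda: mixed_interface("IgM-CH4", "IgG1-CH3")]


@pytest.mark.parametrize("factory", ALL_PAIRS)
def test_substitution_round_trip(factory, refs):
    """Applying the emitted lists to the acceptor reproduces each chain."""
    pair = factory()
    acc = refs[pair.acceptor]
    assert apply_substitutions(acc, pair.subs_a).sequence == pair.chain_a.sequence
    assert apply_substitutions(acc, pair.subs_b).sequence == pair.chain_b.sequence


@pytest.mark.parametrize("factory", ALL_PAIRS)
def test_determinism(factory):
    a, b = factory(), factory()
    assert a == b


def test_regrafting_is_idempotent(refs):
    """Grafting an engineered chain with the same donor adds nothing."""
    pair = beat()
    again = full_interface_graft(pair.chain_a, refs["TCR-Ca"], refs["TCR-Ca"])
    assert again.subs_a == ()


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    acceptor=st.sampled_from(HOMODIMERS),
    donor_a=st.sampled_from(ALL_CLASSES),
    donor_b=st.sampled_from(ALL_CLASSES),
    subset=st.sets(st.sampled_from([str(p) for p in CATALOG.graft_positions])),
)
def test_graft_properties(acceptor, donor_a, donor_b, subset):
    """Locality, no silent substitutions, no imported cysteines."""
    acc = get_reference(acceptor)
    pair = full_interface_graft(
        acc, get_reference(donor_a), get_reference(donor_b), positions=subset
    )
    requested = {str(p) for p in sorted({__import__('igxchange').pos(s) for s in subset})}
    for chain, subs in ((pair.chain_a, pair.subs_a), (pair.chain_b, pair.subs_b)):
        for s in subs:
            assert s.wt != s.mut
            assert str(s.position) in requested
            assert s.mut != "C"
        # locality: untouched positions keep the acceptor residue
        for p in acc.positions():
            if str(p) not in requested:
                assert chain.residue_at(p) == acc.residue_at(p)
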