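"""Contact kernel, superposition, chi1 conservation, annotation, rendering."""

import numpy as np
import pytest

from igxchange import (
    ContactPairSpec,
    FixtureSpec,
    annotate_structure,
    compute_contacts,
    get_reference,
    interface_positions,
    make_contact_fixture,
    make_rotamer_fixture,
    read_structure,
    render_interface_diagram,
    sidechain_conservation,
    superpose_calpha,
    write_pdb,
)
from igxchange.structure import (
    DEFAULT_CRITERIA,
    Atom,
    ChainModel,
    ContactMap,
    ONE_TO_THREE,
    Residue,
    StructureModel,
    chi1,
)

from oracles import brute_force_contacts, grid_search_rmsd

# -- contacts -----------------------------------------------------------------


def test_ionic_pair_within_cutoff():
    model = make_contact_fixture(
        FixtureSpec(seed=1, pairs=(ContactPairSpec("LYS", "GLU", 3.5),))
    )
    cmap = compute_contacts(model, ("A", "B"))
    assert len(cmap) == 1
    (c,) = cmap.contacts
    assert c.kind == "ionic"
    assert c.min_distance == pytest.approx(3.5, abs=0.01)


def test_pair_beyond_cutoff_is_empty():
    model = make_contact_fixture(
        FixtureSpec(seed=1, pairs=(ContactPairSpec("LYS", "GLU", 7.0),))
    )
    assert len(compute_contacts(model, ("A", "B"))) == 0


def test_hydrophobic_pair():
    model = make_contact_fixture(
        FixtureSpec(seed=2, pairs=(ContactPairSpec("LEU", "LEU", 4.5),))
    )
    cmap = compute_contacts(model, ("A", "B"))
    assert [c.kind for c in cmap.contacts] == ["hydrophobic"]


def test_chain_order_invariance():
    model = make_contact_fixture(
        FixtureSpec(
            seed=5,
            pairs=(
                ContactPairSpec("LYS", "GLU", 3.0),
                ContactPairSpec("PHE", "VAL", 4.0),
            ),
        )
    )
    assert compute_contacts(model, ("A", "B")) == compute_contacts(model, ("B", "A"))


def test_no_duplicate_residue_pairs_per_kind():
    model = make_contact_fixture(
        FixtureSpec(seed=6, pairs=(ContactPairSpec("TYR", "TYR", 4.0),))
    )
    cmap = compute_contacts(model, ("A", "B"))
    keys = [(c.kind, c.res_i.number, c.res_j.number) for c in cmap.contacts]
    assert len(keys) == len(set(keys))


RES_POOL = ["LYS", "ARG", "HIS", "ASP", "GLU", "LEU", "ILE", "VAL", "PHE",
            "TRP", "TYR", "MET", "ALA", "PRO", "SER", "THR", "ASN", "GLN"]


def test_contact_kernel_equals_brute_force_scan():
    """Kernel output == exhaustive all-atom-pairs scan on 120 random fixtures."""
    rng = np.random.default_rng(20260930)
    for trial in range(120):
        n = int(rng.integers(1, 6))
        pairs = tuple(
            ContactPairSpec(
                str(rng.choice(RES_POOL)),
                str(rng.choice(RES_POOL)),
                float(rng.uniform(2.5, 9.0)),
            )
            for _ in range(n)
        )
        model = make_contact_fixture(FixtureSpec(seed=trial, pairs=pairs))
        cmap = compute_contacts(model, ("A", "B"))
        got = {
            (c.kind, c.res_i.number, c.res_j.number): c.min_distance
            for c in cmap.contacts
        }
        expected = brute_force_contacts(model, ("A", "B"), DEFAULT_CRITERIA)
        assert set(got) == set(expected)
        for key in got:
            assert got[key] == pytest.approx(expected[key], abs=1e-9)


def test_missing_chain_raises():
    model = make_contact_fixture(
        FixtureSpec(seed=1, pairs=(ContactPairSpec("LYS", "GLU", 3.5),))
    )
    with pytest.raises(KeyError):
        compute_contacts(model, ("A", "Z"))


# -- superposition ------------------------------------------------------------


def _cloud(seed, n=10):
    return np.random.default_rng(seed).normal(scale=5.0, size=(n, 3))


def _random_rotation(seed):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()


def test_self_superposition_is_zero():
    x = _cloud(0)
    assert superpose_calpha(x, x).rmsd == pytest.approx(0.0, abs=1e-9)


def test_rigid_motion_invariance():
    x = _cloud(1)
    y = x @ _random_rotation(7).T + np.array([10.0, -3.0, 2.5])
    sup = superpose_calpha(x, y)
    assert sup.rmsd <= 1e-6
    assert np.allclose(sup.apply(x), y, atol=1e-6)


def test_rmsd_matches_rotation_grid_oracle():
    """Least-squares RMSD equals an independent Euler-grid minimiser."""
    for seed in range(4):
        x = _cloud(seed)
        y = _cloud(seed + 100) * 0.5 + x  # correlated but not congruent
        impl = superpose_calpha(x, y).rmsd
        oracle = grid_search_rmsd(x, y)
        assert impl == pytest.approx(oracle, abs=1e-3)
        assert impl <= oracle + 1e-9  # the solver is the true minimum


def test_rmsd_symmetry_and_nonnegativity():
    x, y = _cloud(3), _cloud(4)
    a = superpose_calpha(x, y).rmsd
    b = superpose_calpha(y, x).rmsd
    assert a >= 0
    assert a == pytest.approx(b, abs=1e-6)


def test_reflection_is_not_a_rigid_match():
    """A mirrored cloud must not superpose to zero (proper rotations only)."""
    x = _cloud(5)
    mirrored = x * np.array([-1.0, 1.0, 1.0])
    sup = superpose_calpha(x, mirrored)
    assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
    assert sup.rmsd > 0.1


def test_too_few_atoms_rejected():
    with pytest.raises(ValueError):
        superpose_calpha(_cloud(0, n=2), _cloud(1, n=2))


# -- chi1 conservation --------------------------------------------------------


def test_rotamer_fixture_reproduces_requested_chi1():
    model = make_rotamer_fixture(["SER", "LEU", "THR"], [60.0, -60.0, 175.0])
    measured = [chi1(r) for r in model.chains[0].residues]
    assert measured == pytest.approx([60.0, -60.0, 175.0], abs=1e-6)


def test_conservation_of_identical_structures_is_one():
    m = make_rotamer_fixture(["SER", "LEU"], [55.0, -60.0], imgt=["20", "22"])
    assert sidechain_conservation(m, m, ["20", "22"]).fraction == 1.0


def test_one_of_two_rotated_gives_half():
    a = make_rotamer_fixture(["SER", "LEU"], [60.0, -60.0], imgt=["20", "22"])
    b = make_rotamer_fixture(["SER", "LEU"], [60.0, 60.0], imgt=["20", "22"])
    res = sidechain_conservation(a, b, ["20", "22"])
    assert res.fraction == 0.5
    assert [str(p) for p in res.changed] == ["22"]


def test_conservation_monotone_in_tolerance():
    rng = np.random.default_rng(11)
    chis_a = rng.uniform(-180, 180, size=8)
    chis_b = chis_a + rng.normal(scale=45.0, size=8)
    labels = [str(i) for i in range(1, 9)]
    a = make_rotamer_fixture(["LEU"] * 8, chis_a, imgt=labels)
    b = make_rotamer_fixture(["LEU"] * 8, chis_b, imgt=labels)
    fractions = [
        sidechain_conservation(a, b, labels, tolerance_deg=t).fraction
        for t in (150.0, 120.0, 90.0, 60.0, 30.0, 10.0, 1.0)
    ]
    assert fractions == sorted(fractions, reverse=True)


def test_unresolved_positions_reported_not_dropped():
    a = make_rotamer_fixture(["SER"], [60.0], imgt=["20"])
    b = make_rotamer_fixture(["SER"], [60.0], imgt=["20"])
    res = sidechain_conservation(a, b, ["20", "88"])
    assert res.fraction == 1.0
    assert [str(p) for (p, _) in res.excluded] == ["88"]


# -- annotation ---------------------------------------------------------------


def _ca_only_model(sequence, chain_id="A", drop_termini=0):
    seq = sequence[drop_termini: len(sequence) - drop_termini or None]
    residues = tuple(
        Residue(ONE_TO_THREE[aa], i + 1, (Atom("CA", "C", (3.8 * i, 0.0, 0.0)),))
        for i, aa in enumerate(seq)
    )
    return StructureModel("toy", (ChainModel(chain_id, residues),))


def test_annotate_structure_labels_every_interface_position(igg1):
    model = annotate_structure(_ca_only_model(igg1.sequence), igg1, "A")
    chain = model.chain("A")
    for p in interface_positions():
        res = chain.residue_at(p)
        assert res is not None
        assert res.one_letter == igg1.residue_at(p)


def test_annotate_structure_with_unmodelled_termini(igg1):
    model = annotate_structure(_ca_only_model(igg1.sequence, drop_termini=2), igg1, "A")
    chain = model.chain("A")
    assert chain.residue_at("1") is None
    assert chain.residue_at("88") is not None


# -- rendering ----------------------------------------------------------------


def test_empty_map_renders_header_only():
    text = render_interface_diagram(ContactMap(()))
    assert "contact map" in text
    assert "ionic (0)" in text and "hydrophobic (0)" in text


def _map_with(pairs):
    spec = FixtureSpec(seed=9, pairs=tuple(pairs))
    return compute_contacts(make_contact_fixture(spec), ("A", "B"))


def test_symmetric_pair_flagged():
    cmap = _map_with(
        [
            ContactPairSpec("LYS", "GLU", 3.2, imgt_a="26", imgt_b="13"),
            ContactPairSpec("GLU", "LYS", 3.2, imgt_a="13", imgt_b="26"),
        ]
    )
    text = render_interface_diagram(cmap)
    assert text.count("symmetric") >= 2
    assert "asymmetric" not in text


def test_single_sided_contact_flagged_asymmetric():
    cmap = _map_with([ContactPairSpec("GLU", "LYS", 3.4, imgt_a="3", imgt_b="16")])
    assert "asymmetric" in render_interface_diagram(cmap)


def test_rendering_is_deterministic():
    cmap = _map_with(
        [
            ContactPairSpec("LYS", "GLU", 3.2, imgt_a="26", imgt_b="13"),
            ContactPairSpec("TYR", "TYR", 4.4, imgt_a="86", imgt_b="86"),
        ]
    )
    assert render_interface_diagram(cmap) == render_interface_diagram(cmap)


# -- PDB round trip -----------------------------------------------------------


def test_pdb_roundtrip_preserves_contacts(tmp_path):
    model = make_contact_fixture(
        FixtureSpec(
            seed=12,
            pairs=(
                ContactPairSpec("LYS", "GLU", 3.5),
                ContactPairSpec("LEU", "LEU", 4.5),
            ),
        )
    )
    path = tmp_path / "fixture.pdb"
    write_pdb(model, path)
    reread = read_structure(path)
    a = {(c.kind, c.res_i.number, round(c.min_distance, 2)) for c in compute_contacts(model, ("A", "B")).contacts}
    b = {(c.kind, c.res_i.number, round(c.min_distance, 2)) for c in compute_contacts(reread, ("A", "B")).contacts}
    assert a == b
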