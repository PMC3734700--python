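import numpy as np
import pytest

from conftest import TOY_PROTONATION, standard_recipe
from qmcluster.builder import (
    ClusterRecipe,
    TruncationRule,
    VariantSpec,
    add_hydrogens,
    apply_variant,
    build_cluster,
    mutate_residue,
    place_cap_hydrogen,
)
from qmcluster.geometry import angle, distance
from qmcluster.structure import Atom, Residue, Structure
from qmcluster.templates import expected_hydrogen_count


def _atom(serial, name, element, pos, **kw):
    return Atom(serial, name, element, np.array(pos, dtype=float), **kw)


class TestPlaceCapHydrogen:
    def test_collinear_example(self):
        kept = _atom(1, "CB", "C", (0, 0, 0))
        removed = _atom(2, "CA", "C", (0, 0, 1.5))
        cap = place_cap_hydrogen(kept, removed, bond_length=1.10)
        np.testing.assert_allclose(cap.position, [0, 0, 1.10], atol=1e-12)
        assert cap.is_cap and cap.is_frozen and cap.element == "H"

    def test_bond_length_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            kept = _atom(1, "CB", "C", rng.normal(size=3))
            removed = _atom(2, "CA", "C", kept.position + rng.normal(size=3))
            cap = place_cap_hydrogen(kept, removed, bond_length=1.10)
            assert distance(cap.position, kept.position) == pytest.approx(1.10, abs=1e-10)
            cross = np.cross(removed.position - kept.position, cap.position - kept.position)
            assert np.linalg.norm(cross) < 1e-10  # cap on the severed bond

    def test_default_length_by_element(self):
        kept = _atom(1, "N", "N", (0, 0, 0))
        removed = _atom(2, "CA", "C", (0, 0, 1.46))
        cap = place_cap_hydrogen(kept, removed)
        assert distance(cap.position, kept.position) == pytest.approx(1.01)

    def test_coincident_rejected(self):
        kept = _atom(1, "CB", "C", (0, 0, 0))
        removed = _atom(2, "CA", "C", (0, 0, 0))
        with pytest.raises(ValueError, match="coincident"):
            place_cap_hydrogen(kept, removed)


class TestBuildCluster:
    def test_hand_counted_toy_model(self, toy_site):
        structure, _ = toy_site
        recipe = ClusterRecipe(
            include=[("A", 1, ""), ("A", 3, ""), ("A", 5, ""), ("A", 101, "")],
            truncations=[
                TruncationRule(("A", 1, ""), ("CB", "CA")),
                TruncationRule(("A", 5, ""), ("CB", "CA")),
            ],
            ligand_key=("A", 201, ""),
        )
        model = build_cluster(structure, recipe)
        # hand count: ASP keeps CB,CG,OD1,OD2 + cap = 5; TYR full = 12;
        # LEU keeps CB,CG,CD1,CD2 + cap = 5; water = 1; ligand = 6
        assert model.structure.n_atoms == 5 + 12 + 5 + 1 + 6
        assert len(model.cap_atoms) == 2

    def test_zero_truncations_is_identity_selection(self, toy_site):
        structure, _ = toy_site
        recipe = ClusterRecipe(include=[("A", 1, ""), ("A", 2, "")])
        model = build_cluster(structure, recipe)
        assert model.structure.n_atoms == 16
        assert model.cap_atoms == []

    def test_absent_residue_named_in_error(self, toy_site):
        structure, _ = toy_site
        recipe = ClusterRecipe(include=[("B", 99, "")])
        with pytest.raises(ValueError, match="B:99"):
            build_cluster(structure, recipe)

    def test_missing_cut_bond_atom_rejected(self, toy_site):
        structure, _ = toy_site
        recipe = ClusterRecipe(
            include=[("A", 101, "")],
            truncations=[TruncationRule(("A", 101, ""), ("O", "CA"))],
        )
        with pytest.raises(ValueError, match="CA"):
            build_cluster(structure, recipe)

    def test_rule_for_unincluded_residue_rejected(self):
        with pytest.raises(ValueError, match="not an included"):
            ClusterRecipe(include=[], truncations=[TruncationRule(("A", 1, ""), ("CB", "CA"))])

    def test_valence_closure(self, wt_model):
        # exactly one cap per truncation rule, all caps frozen hydrogens
        assert len(wt_model.cap_atoms) == len(wt_model.recipe.truncations)
        for cap in wt_model.cap_atoms:
            assert cap.element == "H" and cap.is_frozen

    def test_default_frozen_set_is_caps_plus_attachments(self, wt_model):
        frozen = {(a.residue_key, a.name) for a in wt_model.frozen_atoms}
        expected = set()
        for i, rule in enumerate(wt_model.recipe.truncations, start=1):
            expected.add((rule.residue_key, rule.cut_bond[0]))
            expected.add((rule.residue_key, f"HCP{i}"))
        assert frozen == expected

    def test_explicit_frozen_override(self, toy_site):
        structure, _ = toy_site
        recipe = standard_recipe(frozen_atoms=[(("A", 5, ""), "CA")])
        model = build_cluster(structure, recipe)
        frozen = {(a.residue_key, a.name) for a in model.frozen_atoms}
        # caps are always frozen; explicit list replaces the attachment default
        assert (("A", 5, ""), "CA") in frozen
        assert all(name.startswith("HCP") or name == "CA" for _, name in frozen)


class TestAddHydrogens:
    def test_water_geometry(self, toy_site):
        structure, _ = toy_site
        recipe = ClusterRecipe(include=[("A", 101, "")])
        model = add_hydrogens(build_cluster(structure, recipe), {})
        water = model.structure.residue(("A", 101, ""))
        assert len(water.atoms) == 3
        o = water.atom("O")
        h1, h2 = (a for a in water.atoms if a.element == "H")
        assert distance(h1.position, o.position) == pytest.approx(0.96, abs=1e-9)
        assert distance(h2.position, o.position) == pytest.approx(0.96, abs=1e-9)
        assert angle(h1.position, o.position, h2.position) == pytest.approx(104.5, abs=1e-6)

    def test_idempotent(self, toy_site):
        structure, _ = toy_site
        model = build_cluster(structure, standard_recipe())
        once = add_hydrogens(model, TOY_PROTONATION)
        twice = add_hydrogens(once, TOY_PROTONATION)
        assert twice.structure.n_atoms == once.structure.n_atoms
        np.testing.assert_array_equal(twice.structure.positions(), once.structure.positions())

    def test_hand_counted_hydrogen_total(self, toy_site):
        # untruncated full site, anionic Asp, neutral Tyr:
        #   ASP 4+4, TYR 9, ASN 6, LEU 11, ILE 11, MET 9, HOH 2, EPX 8 = 64
        structure, _ = toy_site
        recipe = standard_recipe(truncations=[])
        model = add_hydrogens(build_cluster(structure, recipe), TOY_PROTONATION)
        n_h = sum(1 for a in model.structure.atoms() if a.element == "H")
        assert n_h == 64

    def test_template_prediction_matches(self, wt_model):
        model = add_hydrogens(wt_model, TOY_PROTONATION)
        from qmcluster.templates import TITRATABLE

        for res in model.structure.all_residues():
            state = TOY_PROTONATION.get(res.key) if res.name in TITRATABLE else None
            heavy = [a.name for a in res.atoms if a.element != "H"]
            predicted = expected_hydrogen_count(res.name, heavy, state)
            got = sum(1 for a in res.atoms if a.element == "H" and not a.is_cap)
            assert got == predicted, res.key

    def test_undeclared_titratable_rejected(self, toy_site):
        structure, _ = toy_site
        model = build_cluster(structure, standard_recipe())
        incomplete = {k: v for k, v in TOY_PROTONATION.items() if k != ("A", 2, "")}
        with pytest.raises(ValueError, match="ASP A:2"):
            add_hydrogens(model, incomplete)

    def test_protonated_asp_gains_one(self, toy_site):
        structure, _ = toy_site
        recipe = ClusterRecipe(include=[("A", 1, "")])
        model = build_cluster(structure, recipe)
        anionic = add_hydrogens(model, {("A", 1, ""): "anionic"})
        neutral = add_hydrogens(model, {("A", 1, ""): "neutral"})
        assert neutral.structure.n_atoms - anionic.structure.n_atoms == 1

    def test_frozen_atoms_unmoved(self, wt_model):
        before = {a.serial: a.position.copy() for a in wt_model.structure.atoms() if a.is_frozen}
        after = add_hydrogens(wt_model, TOY_PROTONATION)
        frozen_after = {
            (a.residue_key, a.name): a.position for a in after.structure.atoms() if a.is_frozen and not a.element == "H"
        }
        orig = {
            (a.residue_key, a.name): a.position for a in wt_model.structure.atoms() if a.is_frozen and not a.element == "H"
        }
        for key, pos in orig.items():
            np.testing.assert_array_equal(frozen_after[key], pos)
        assert len(before) > 0


R1_ANALOGUE = VariantSpec.parse("R1", ["A:5:LEU>ILE", "A:6:ILE>CYS"])
S1_ANALOGUE = VariantSpec.parse("S1", ["A:5:LEU>CYS", "A:6:ILE>VAL"])
S2_ANALOGUE = VariantSpec.parse("S2", ["A:5:LEU>CYS", "A:6:ILE>VAL", "A:7:MET>PHE"])


def _residue_signature(model, key):
    res = model.structure.residue(key)
    return (res.name, tuple(sorted(a.name for a in res.atoms)))


def _differing_residues(m1, m2):
    keys = [r.key for r in m1.structure.all_residues()]
    diff = []
    for key in keys:
        if _residue_signature(m1, key) != _residue_signature(m2, key):
            diff.append(key)
            continue
        p1 = np.array([a.position for a in m1.structure.residue(key).atoms])
        p2 = np.array([a.position for a in m2.structure.residue(key).atoms])
        if not np.array_equal(p1, p2):
            diff.append(key)
    return diff


class TestMutation:
    def test_self_mutation_is_identity(self, wt_model):
        out = mutate_residue(wt_model, (("A", 5, ""), "LEU", "LEU"))
        assert _differing_residues(wt_model, out) == []

    def test_ile_to_val_drops_one_heavy_atom(self, wt_model):
        out = mutate_residue(wt_model, (("A", 6, ""), "ILE", "VAL"))
        before = len(wt_model.structure.residue(("A", 6, "")).heavy_atoms())
        after = len(out.structure.residue(("A", 6, "")).heavy_atoms())
        assert before - after == 1  # CD1 removed

    def test_from_code_mismatch_rejected(self, wt_model):
        with pytest.raises(ValueError, match="residue is LEU"):
            mutate_residue(wt_model, (("A", 5, ""), "ILE", "VAL"))

    def test_unknown_target_rejected(self, wt_model):
        with pytest.raises(ValueError, match="template"):
            mutate_residue(wt_model, (("A", 5, ""), "LEU", "XXX"))

    def test_backbone_and_cb_preserved_exactly(self, wt_model):
        out = mutate_residue(wt_model, (("A", 5, ""), "LEU", "ILE"))
        for name in ("N", "CA", "C", "O", "CB"):
            np.testing.assert_array_equal(
                out.structure.residue(("A", 5, "")).atom(name).position,
                wt_model.structure.residue(("A", 5, "")).atom(name).position,
            )

    def test_chi1_inherited(self, wt_model):
        from qmcluster.geometry import dihedral

        parent = wt_model.structure.residue(("A", 5, ""))
        chi_parent = dihedral(*(parent.atom(n).position for n in ("N", "CA", "CB", "CG")))
        out = mutate_residue(wt_model, (("A", 5, ""), "LEU", "ILE"))
        child = out.structure.residue(("A", 5, ""))
        chi_child = dihedral(*(child.atom(n).position for n in ("N", "CA", "CB", "CG1")))
        assert chi_child == pytest.approx(chi_parent, abs=1e-6)

    def test_mutation_locality(self, wt_model):
        out = mutate_residue(wt_model, (("A", 6, ""), "ILE", "VAL"))
        diff = _differing_residues(wt_model, out)
        assert diff == [("A", 6, "")]

    def test_clash_reported_not_silent(self, wt_model):
        probe = mutate_residue(wt_model, (("A", 5, ""), "LEU", "MET"))
        sd_pos = probe.structure.residue(("A", 5, "")).atom("SD").position
        # plant an atom exactly where the new side chain will land
        crowded = wt_model.copy()
        crowded.structure.ligands.append(
            Residue("HOH", ("A", 102, ""), [_atom(999, "O", "O", sd_pos)])
        )
        crowded.structure.renumber()
        with pytest.warns(UserWarning, match="within 1.0 A"):
            out = mutate_residue(crowded, (("A", 5, ""), "LEU", "MET"))
        assert any("within 1.0 A" in w for w in out.report["warnings"])


class TestVariants:
    def test_empty_variant_identity(self, wt_model):
        out = apply_variant(wt_model, VariantSpec("null", ()))
        assert _differing_residues(wt_model, out) == []
        assert out.variant_label == "null"

    def test_r1_analogue_differs_at_two_residues(self, wt_model):
        out = apply_variant(wt_model, R1_ANALOGUE)
        assert sorted(_differing_residues(wt_model, out)) == [("A", 5, ""), ("A", 6, "")]
        assert out.variant_label == "R1"

    def test_s2_extends_s1_by_one_residue(self, wt_model):
        s1 = apply_variant(wt_model, S1_ANALOGUE)
        s2 = apply_variant(wt_model, S2_ANALOGUE)
        assert _differing_residues(s1, s2) == [("A", 7, "")]

    def test_mutation_order_independence(self, wt_model):
        fwd = apply_variant(wt_model, VariantSpec("x", tuple(R1_ANALOGUE.mutations)))
        rev = apply_variant(wt_model, VariantSpec("x", tuple(reversed(R1_ANALOGUE.mutations))))
        for a, b in zip(fwd.structure.atoms(), rev.structure.atoms()):
            assert (a.residue_key, a.name, a.element) == (b.residue_key, b.name, b.element)
            np.testing.assert_array_equal(a.position, b.position)

    def test_frozen_atoms_never_move_through_builder_ops(self, wt_model):
        ref = {
            (a.residue_key, a.name): a.position.copy()
            for a in wt_model.structure.atoms()
            if a.is_frozen
        }
        for model in (
            apply_variant(wt_model, R1_ANALOGUE),
            add_hydrogens(wt_model, TOY_PROTONATION),
            add_hydrogens(apply_variant(wt_model, S2_ANALOGUE), TOY_PROTONATION),
        ):
            for a in model.structure.atoms():
                if (a.residue_key, a.name) in ref:
                    np.testing.assert_array_equal(a.position, ref[(a.residue_key, a.name)])

    def test_parse_roundtrip(self):
        spec = VariantSpec.parse("R2", ["A:5:LEU>ILE", "A:6:ILE>CYS", "A:7:MET>CYS"])
        assert spec.mutations[2] == (("A", 7, ""), "MET", "CYS")

    def test_bad_mutation_string_rejected(self):
        with pytest.raises(ValueError, match="parse"):
            VariantSpec.parse("bad", ["A5LEUILE"])
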