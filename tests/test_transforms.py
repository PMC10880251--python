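"""Unit tests for the rule engine and the non-rule graph transforms."""

from __future__ import annotations

import pytest
from rdkit import Chem

from qsarready.transforms import (
    RuleLoadError,
    StandardizationError,
    apply_rule,
    fix_crossed_double_bonds,
    flatten_stereo,
    load_rule_file,
    neutralize,
    reapply_stereo,
    sanitize_coordinates,
    set_ring_mode,
    standardize_mesomers_tautomers,
    virtualize_hydrogens,
)


def _std(smiles, library):
    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToSmiles(standardize_mesomers_tautomers(mol, library))


class TestRuleFile:
    def test_builtin_loads(self, library):
        assert len(library) >= 100
        assert any(not r.enabled for r in library.rules)  # toggles are real

    def test_every_rule_is_toggleable(self, library):
        lib = load_rule_file()
        first = lib.rules[0].rule_id
        n_before = len(lib.enabled())
        lib.disable([first])
        assert len(lib.enabled()) == n_before - 1

    def test_order_is_sorted_and_unique(self, library):
        orders = [r.order_index for r in library.rules]
        assert orders == sorted(orders)
        assert len(orders) == len(set(orders))

    def test_families_are_known(self, library):
        assert {r.family for r in library.rules} <= {
            "mesomer", "tautomer", "neutralization", "other"
        }

    def test_duplicate_order_index_rejected(self, tmp_path):
        p = tmp_path / "rules.tsv"
        p.write_text(
            "A-1\t10\t1\ttautomer\t[OH:1][C:2]=[C:3]>>[O:1]=[C:2][CH:3]\ta\n"
            "A-2\t10\t1\ttautomer\t[SH:1][C:2]=[C:3]>>[S:1]=[C:2][CH:3]\tb\n"
        )
        with pytest.raises(RuleLoadError, match="duplicate order_index"):
            load_rule_file(str(p))

    def test_malformed_line_names_rule(self, tmp_path):
        p = tmp_path / "rules.tsv"
        p.write_text("A-1\t10\t1\ttautomer\tnot-a-reaction\ta\n")
        with pytest.raises(RuleLoadError, match="A-1"):
            load_rule_file(str(p))

    def test_bad_field_count_reports_line(self, tmp_path):
        p = tmp_path / "rules.tsv"
        p.write_text("A-1\t10\t1\ttautomer\n")
        with pytest.raises(RuleLoadError, match="line 1"):
            load_rule_file(str(p))

    def test_comments_and_blanks_ignored(self, tmp_path):
        p = tmp_path / "rules.tsv"
        p.write_text(
            "# comment\n\n"
            "A-1\t10\t1\ttautomer\t[OH:1][C:2]=[C:3]>>[O:1]=[C:2][CH:3]\ta\n"
        )
        assert len(load_rule_file(str(p))) == 1


class TestApplyRule:
    def test_enol_to_keto(self, library):
        rule = next(r for r in library.rules if r.rule_id == "TAUT-KE-01")
        mol = Chem.MolFromSmiles("CC(O)=C")
        assert Chem.MolToSmiles(apply_rule(mol, rule)) == "CC(C)=O"

    def test_non_matching_structure_untouched(self, library):
        rule = next(r for r in library.rules if r.rule_id == "TAUT-KE-01")
        mol = Chem.MolFromSmiles("c1ccccc1")
        assert Chem.MolToSmiles(apply_rule(mol, rule)) == "c1ccccc1"

    def test_fixed_point_on_multiple_sites(self, library):
        rule = next(r for r in library.rules if r.rule_id == "TAUT-KE-01")
        # two enol sites, both must be converted in one apply_rule call
        mol = Chem.MolFromSmiles("C(=C)(O)CCC(O)=C")
        out = Chem.MolToSmiles(apply_rule(mol, rule))
        assert "O)=C" not in out and out == Chem.CanonSmiles("CC(=O)CCC(C)=O")

    def test_application_is_logged(self, library):
        rule = next(r for r in library.rules if r.rule_id == "TAUT-KE-01")
        log: list[str] = []
        apply_rule(Chem.MolFromSmiles("CC(O)=C"), rule, log=log)
        assert any("TAUT-KE-01: applied" in line for line in log)


class TestRuleLibraryChemistry:
    @pytest.mark.parametrize(
        "drawn, canonical",
        [
            ("C[N-][N+]#N", "CN=[N+]=[N-]"),  # azide mesomer
            ("CC(O)=C", "CC(C)=O"),  # keto-enol
            ("CC(S)=C", "CC(C)=S"),  # thioketo-enol
            ("C=C(C)N", "CC(C)=N"),  # enamine-imine
            ("CC(O)=N", "CC(N)=O"),  # imidic acid -> amide
            ("Oc1ccccn1", "O=c1cccc[nH]1"),  # 2-hydroxypyridine -> 2-pyridone
            ("OC1=CC(=O)CCC1", "O=C1CCCC(=O)C1"),  # dione enol
        ],
    )
    def test_canonical_direction(self, library, drawn, canonical):
        assert _std(drawn, library) == Chem.CanonSmiles(canonical)

    @pytest.mark.parametrize(
        "stable",
        [
            "Oc1ccccc1",  # phenol: aromatic enol must survive
            "CC(N)=O",  # amide: no amide "tautomerization"
            "Nc1ccccn1",  # 2-aminopyridine stays amino
            "CC(C)=O",  # ketones are already canonical
            "c1ccccc1",
            "CN=[N+]=[N-]",
            "C[N+](=O)[O-]",
        ],
    )
    def test_canonical_forms_are_fixed_points(self, library, stable):
        assert _std(stable, library) == Chem.CanonSmiles(stable)

    def test_library_pass_is_idempotent_on_corpus(self, library, corpus):
        for case in corpus:
            mol = Chem.MolFromSmiles(case.smiles)
            if mol is None:
                continue
            once = standardize_mesomers_tautomers(mol, library)
            twice = standardize_mesomers_tautomers(once, library)
            assert Chem.MolToSmiles(once) == Chem.MolToSmiles(twice), case.name

    def test_heavy_atoms_never_change(self, library, corpus):
        for case in corpus:
            mol = Chem.MolFromSmiles(case.smiles)
            if mol is None:
                continue
            out = standardize_mesomers_tautomers(mol, library)
            assert out.GetNumHeavyAtoms() == mol.GetNumHeavyAtoms(), case.name


class TestNeutralize:
    @pytest.mark.parametrize(
        "charged, neutral",
        [
            ("C[NH3+]", "CN"),
            ("[O-]c1ccccc1", "Oc1ccccc1"),
            ("[NH3+]CC([O-])=O", "NCC(=O)O"),  # zwitterion via paired transfer
            ("CC(=O)[O-]", "CC(=O)O"),
        ],
    )
    def test_neutralized(self, charged, neutral):
        out = neutralize(Chem.MolFromSmiles(charged))
        assert Chem.MolToSmiles(out) == Chem.CanonSmiles(neutral)
        assert Chem.GetFormalCharge(out) == 0

    @pytest.mark.parametrize(
        "permanent",
        ["C[N+](C)(C)C", "C[N+](=O)[O-]", "[O-][n+]1ccccc1"],
    )
    def test_permanent_charges_untouched(self, permanent):
        out = neutralize(Chem.MolFromSmiles(permanent))
        assert Chem.MolToSmiles(out) == Chem.CanonSmiles(permanent)

    def test_net_charge_magnitude_never_increases(self):
        for smi in ["C[NH3+]", "CC(=O)[O-]", "[NH3+]CC([O-])=O", "C[N+](C)(C)C"]:
            before = abs(Chem.GetFormalCharge(Chem.MolFromSmiles(smi)))
            after = abs(Chem.GetFormalCharge(neutralize(Chem.MolFromSmiles(smi))))
            assert after <= before


class TestStereo:
    def test_flatten_removes_all_stereo(self):
        mol = Chem.MolFromSmiles("C[C@H](N)/C=C/C")
        flat, payload = flatten_stereo(mol)
        assert "@" not in Chem.MolToSmiles(flat)
        assert "/" not in Chem.MolToSmiles(flat)
        assert len(payload["atoms"]) == 1
        assert len(payload["bonds"]) == 1

    def test_payload_round_trip(self):
        mol = Chem.MolFromSmiles("C[C@H](N)C(=O)O")
        flat, payload = flatten_stereo(mol)
        back = reapply_stereo(flat, payload)
        Chem.AssignStereochemistry(back, cleanIt=True, force=True)
        assert Chem.MolToSmiles(back) == Chem.MolToSmiles(mol)

    def test_achiral_payload_empty(self):
        _, payload = flatten_stereo(Chem.MolFromSmiles("CCO"))
        assert payload == {"atoms": {}, "bonds": {}}


class TestHydrogens:
    def test_explicit_h_folded(self):
        mol = Chem.MolFromSmiles("[H]OC([H])([H])[H]", sanitize=False)
        Chem.SanitizeMol(mol)
        assert Chem.MolToSmiles(virtualize_hydrogens(mol)) == "CO"

    def test_isotopic_h_kept(self):
        mol = Chem.MolFromSmiles("[2H]OC")
        assert Chem.MolToSmiles(virtualize_hydrogens(mol)) == "[2H]OC"


class TestRingMode:
    def test_aromatic_mode(self):
        mol = Chem.MolFromSmiles("C1=CC=CC=C1")
        out = set_ring_mode(mol, "aromatic")
        assert Chem.MolToSmiles(out) == "c1ccccc1"

    def test_kekule_mode(self):
        mol = Chem.MolFromSmiles("c1ccccc1")
        out = set_ring_mode(mol, "kekule")
        assert not any(b.GetIsAromatic() for b in out.GetBonds())

    def test_modes_share_inchi(self):
        for smi in ["c1ccccc1", "c1ccc2ccccc2c1", "O=c1cccc[nH]1"]:
            a = set_ring_mode(Chem.MolFromSmiles(smi), "aromatic")
            k = set_ring_mode(Chem.MolFromSmiles(smi), "kekule")
            assert Chem.MolToInchi(a) == Chem.MolToInchi(k)

    def test_antiaromatic_ring_unchanged(self):
        mol = Chem.MolFromSmiles("C1=CC=C1")  # cyclobutadiene: 4n, not aromatic
        out = set_ring_mode(mol, "aromatic")
        assert not any(a.GetIsAromatic() for a in out.GetAtoms())

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError):
            set_ring_mode(Chem.MolFromSmiles("CCO"), "hybrid")


class TestCrossedBonds:
    def test_stereogenic_double_bond_flagged(self):
        mol = Chem.MolFromSmiles("CC=CC")
        out = fix_crossed_double_bonds(mol)
        flags = [b.GetStereo() for b in out.GetBonds()
                 if b.GetBondType() == Chem.BondType.DOUBLE]
        assert flags == [Chem.BondStereo.STEREOANY]

    @pytest.mark.parametrize("smiles", ["C=C", "CC(C)=C", "c1ccccc1"])
    def test_non_stereogenic_not_flagged(self, smiles):
        out = fix_crossed_double_bonds(Chem.MolFromSmiles(smiles))
        assert all(b.GetStereo() != Chem.BondStereo.STEREOANY for b in out.GetBonds())


class TestCoordinates:
    def test_layout_generated_when_absent(self):
        mol = Chem.MolFromSmiles("CCO")
        out = sanitize_coordinates(mol)
        assert out.GetNumConformers() == 1

    def test_degenerate_all_zero_layout_replaced(self):
        mol = Chem.MolFromSmiles("CCO")
        conf = Chem.Conformer(mol.GetNumAtoms())  # all atoms at the origin
        mol.AddConformer(conf)
        out = sanitize_coordinates(mol)
        conf = out.GetConformer()
        pts = [conf.GetAtomPosition(i) for i in range(out.GetNumAtoms())]
        assert any(abs(p.x) > 1e-3 or abs(p.y) > 1e-3 for p in pts)

    def test_good_layout_kept(self):
        from rdkit.Chem import rdDepictor

        mol = Chem.MolFromSmiles("CCO")
        rdDepictor.Compute2DCoords(mol)
        before = [tuple(mol.GetConformer().GetAtomPosition(i))
                  for i in range(mol.GetNumAtoms())]
        out = sanitize_coordinates(mol)
        after = [tuple(out.GetConformer().GetAtomPosition(i))
                 for i in range(out.GetNumAtoms())]
        assert before == after
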