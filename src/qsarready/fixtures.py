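"""Deterministic toy-structure corpus exercising every pipeline branch.

Every discard reason, every transform family and the salt/charge handling
paths are covered by hand-picked structures whose expected outcomes were
derived independently (charge bookkeeping, fragment counting, bond/atom
ratio arithmetic, InChI equality of tautomer pairs) and frozen here.  The
corpus involves no randomness and downloads nothing.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

from rdkit import Chem

from .transforms import RuleLibrary, apply_rule
from .validation import ReasonTag

# icosahedral C60 fullerene: 60 heavy atoms, 90 bonds, bond/atom ratio 1.5
C60_SMILES = (
    "C12=C3C4=C5C6=C1C7=C8C9=C1C%10=C%11C(=C29)C3=C2C3=C4C4=C5C5=C9C6=C7C6=C7"
    "C8=C1C1=C8C%10=C%10C%11=C2C2=C3C3=C4C4=C5C5=C%11C%12=C(C6=C95)C7=C1C1="
    "C%12C5=C%11C4=C3C3=C5C(=C81)C%10=C23"
)


@dataclass(frozen=True)
class FixtureCase:
    name: str
    smiles: str
    expected: str  # "pass" or a ReasonTag value
    expected_smiles: str | None = None  # canonical output in aromatic mode
    requires_size_filter: bool = False
    tautomer_group: str | None = None  # members collapse to one InChI
    expected_salt_ids: tuple[str, ...] = ()
    notes: str = ""


def fixture_corpus() -> list[FixtureCase]:
    """The full deterministic corpus (> 40 cases)."""
    P = "pass"
    return [
        # --- plain organics that pass unchanged -------------------------------
        FixtureCase("ethanol", "CCO", P, "CCO"),
        FixtureCase("benzene_aromatic", "c1ccccc1", P, "c1ccccc1"),
        FixtureCase("benzene_kekule", "C1=CC=CC=C1", P, "c1ccccc1"),
        FixtureCase("naphthalene", "c1ccc2ccccc2c1", P, "c1ccc2ccccc2c1"),
        FixtureCase("aspirin", "CC(=O)Oc1ccccc1C(=O)O", P, "CC(=O)Oc1ccccc1C(=O)O"),
        FixtureCase("phenol", "Oc1ccccc1", P, "Oc1ccccc1",
                    notes="aromatic enol must NOT be ketonized"),
        FixtureCase("methane_unfiltered", "C", P, "C"),
        FixtureCase("adamantane", "C1C2CC3CC1CC(C2)C3", P, "C1C2CC3CC1CC(C2)C3",
                    notes="ratio 12/10 = 1.2 passes the nano filter"),
        # --- valence remediation ---------------------------------------------
        FixtureCase("nitromethane_hypervalent", "CN(=O)=O", P, "C[N+](=O)[O-]",
                    tautomer_group="nitro"),
        FixtureCase("nitromethane_charge_sep", "C[N+](=O)[O-]", P, "C[N+](=O)[O-]",
                    tautomer_group="nitro"),
        FixtureCase("pyridine_noxide_hypervalent", "O=n1ccccc1", P, "[O-][n+]1ccccc1"),
        FixtureCase("nitrobenzene_hypervalent", "O=N(=O)c1ccccc1", P,
                    "O=[N+]([O-])c1ccccc1"),
        # --- mesomer / tautomer pairs ----------------------------------------
        FixtureCase("azide_cumulated", "CN=[N+]=[N-]", P, "CN=[N+]=[N-]",
                    tautomer_group="azide"),
        FixtureCase("azide_anionic_drawing", "C[N-][N+]#N", P, "CN=[N+]=[N-]",
                    tautomer_group="azide"),
        FixtureCase("enol_of_acetone", "CC(O)=C", P, "CC(C)=O",
                    tautomer_group="keto_enol"),
        FixtureCase("acetone", "CC(C)=O", P, "CC(C)=O", tautomer_group="keto_enol"),
        FixtureCase("enamine_of_acetone_imine", "C=C(C)N", P, "CC(C)=N",
                    tautomer_group="enamine_imine"),
        FixtureCase("acetone_imine", "CC(C)=N", P, "CC(C)=N",
                    tautomer_group="enamine_imine"),
        FixtureCase("2_hydroxypyridine", "Oc1ccccn1", P, "O=c1cccc[nH]1",
                    tautomer_group="pyridone"),
        FixtureCase("2_pyridone", "O=c1cccc[nH]1", P, "O=c1cccc[nH]1",
                    tautomer_group="pyridone"),
        FixtureCase("acetimidic_acid", "CC(O)=N", P, "CC(N)=O"),
        FixtureCase("thioenol", "CC(S)=C", P, "CC(C)=S"),
        FixtureCase("diazomethane", "C=[N+]=[N-]", P, "C=[N+]=[N-]"),
        FixtureCase("diethyl_phosphite", "CCOP(O)OCC", P, "CCO[PH](=O)OCC"),
        FixtureCase("dione_enol", "OC1=CC(=O)CCC1", P, "O=C1CCCC(=O)C1"),
        # --- charges and zwitterions -----------------------------------------
        FixtureCase("glycine_zwitterion", "[NH3+]CC([O-])=O", P, "NCC(=O)O"),
        FixtureCase("methylammonium", "C[NH3+]", P, "CN"),
        FixtureCase("phenolate", "[O-]c1ccccc1", P, "Oc1ccccc1"),
        FixtureCase("tetramethylammonium_chloride", "C[N+](C)(C)C.[Cl-]", P,
                    "C[N+](C)(C)C", expected_salt_ids=("SS-0017",),
                    notes="permanent cation keeps its charge"),
        # --- salts, solvates, mixtures ---------------------------------------
        FixtureCase("sodium_acetate", "CC(=O)[O-].[Na+]", P, "CC(=O)O",
                    expected_salt_ids=("SS-0001",)),
        FixtureCase("acetamide_hydrate", "CC(N)=O.O", P, "CC(N)=O",
                    expected_salt_ids=("SS-0049",)),
        FixtureCase("ethylamine_tosylate", "CC[NH3+].Cc1ccc(cc1)S([O-])(=O)=O", P,
                    "CCN", expected_salt_ids=("SS-0044",)),
        FixtureCase("aniline_hydrochloride", "Cl.Nc1ccccc1", P, "Nc1ccccc1",
                    expected_salt_ids=("SS-0017",),
                    notes="HCl matches the chloride entry (protonation-blind)"),
        FixtureCase("ethanol_ethylamine_mixture", "CCO.CCN", ReasonTag.mixture.value),
        FixtureCase("benzene_ethylamine_mixture", "c1ccccc1.CCN",
                    ReasonTag.mixture.value),
        FixtureCase("sodium_chloride", "[Na+].[Cl-]", ReasonTag.inorganic.value),
        FixtureCase("water_alone", "O", ReasonTag.inorganic.value),
        FixtureCase("silica", "O=[Si]=O", ReasonTag.inorganic.value),
        # --- organometallics --------------------------------------------------
        FixtureCase("tetraethyllead", "CC[Pb](CC)(CC)CC",
                    ReasonTag.organometallic.value),
        FixtureCase("ethylmagnesium_bromide", "CC[Mg]Br",
                    ReasonTag.organometallic.value),
        # --- parse failures ---------------------------------------------------
        FixtureCase("unclosed_ring", "C1CC", ReasonTag.failed_parsing.value),
        FixtureCase("not_smiles", "this-is-not-a-structure",
                    ReasonTag.failed_parsing.value),
        FixtureCase("pentavalent_carbon", "CC(C)(C)(C)C",
                    ReasonTag.failed_parsing.value),
        # --- Markush / query --------------------------------------------------
        FixtureCase("wildcard_attachment", "*CC", ReasonTag.ambiguous_structure.value),
        FixtureCase("wildcard_on_ring", "*c1ccccc1",
                    ReasonTag.ambiguous_structure.value),
        # --- stereo ----------------------------------------------------------
        FixtureCase("l_alanine", "C[C@H](N)C(=O)O", P, "CC(N)C(=O)O"),
        FixtureCase("trans_2_butene", "C/C=C/C", P, "CC=CC",
                    notes="flattened; C=C gets the crossed flag in SDF"),
        # --- explicit / isotopic hydrogens -----------------------------------
        FixtureCase("methanol_explicit_h", "[H]OC([H])([H])[H]", P, "CO"),
        FixtureCase("deuteromethanol", "[2H]OC", P, "[2H]OC",
                    notes="isotopic hydrogen stays explicit"),
        # --- size / shape (only with the filter enabled) ----------------------
        FixtureCase("fullerene_c60", C60_SMILES, ReasonTag.nano_shape.value,
                    requires_size_filter=True,
                    notes="90 bonds / 60 atoms = 1.5 > 1.3"),
        FixtureCase("cage_hydrocarbon", "C1C2C3C1C1C2C3C1",
                    ReasonTag.nano_shape.value, requires_size_filter=True,
                    notes="11 bonds / 8 atoms = 1.375 > 1.3"),
        FixtureCase("methane_too_small", "C", ReasonTag.size.value,
                    requires_size_filter=True, notes="below heavy_min=2"),
        FixtureCase("heptacontane_too_big", "C" * 70, ReasonTag.size.value,
                    requires_size_filter=True, notes="above heavy_max=60"),
    ]


def tautomer_pairs() -> dict[str, list[FixtureCase]]:
    """Corpus cases grouped by tautomer/mesomer family (>= 2 members each)."""
    groups: dict[str, list[FixtureCase]] = {}
    for case in fixture_corpus():
        if case.tautomer_group:
            groups.setdefault(case.tautomer_group, []).append(case)
    return {k: v for k, v in groups.items() if len(v) >= 2}


def rule_order_probe(
    library: RuleLibrary,
) -> tuple[str, str, str, str, str]:
    """A concrete non-commuting rule pair.

    1-aminoethenol carries both an enol and an enamine motif on the same
    carbon skeleton: ketonizing first yields acetamide, iminating first
    yields acetimidic acid — different molecules.  Returns (structure SMILES,
    rule A id, rule B id, canonical result of A-then-B, canonical result of
    B-then-A); the library's documented order applies A (keto-enol) first.
    """
    structure = "OC(=C)N"
    rule_a = next(r for r in library.rules if r.rule_id == "TAUT-KE-01")
    rule_b = next(r for r in library.rules if r.rule_id == "TAUT-EI-01")
    mol = Chem.MolFromSmiles(structure)
    ab = apply_rule(apply_rule(mol, rule_a), rule_b)
    ba = apply_rule(apply_rule(mol, rule_b), rule_a)
    return (
        structure,
        rule_a.rule_id,
        rule_b.rule_id,
        Chem.MolToSmiles(ab),
        Chem.MolToSmiles(ba),
    )


def write_corpus(out_dir: str) -> tuple[str, str]:
    """Export the corpus as a .smi file plus an expected-outcome CSV."""
    os.makedirs(out_dir, exist_ok=True)
    smi_path = os.path.join(out_dir, "fixture_corpus.smi")
    csv_path = os.path.join(out_dir, "fixture_expected.csv")
    corpus = fixture_corpus()
    with open(smi_path, "w", encoding="utf-8") as fh:
        for case in corpus:
            fh.write(f"{case.smiles} {case.name}\n")
    with open(csv_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["name", "smiles", "expected", "expected_smiles",
             "requires_size_filter", "notes"]
        )
        for case in corpus:
            writer.writerow(
                [case.name, case.smiles, case.expected,
                 case.expected_smiles or "", int(case.requires_size_filter),
                 case.notes]
            )
    return smi_path, csv_path
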