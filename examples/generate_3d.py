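"""Seeded 3D conformer generation for standardized structures.

The same seed gives bit-identical coordinates run to run; the force-field
optimization always lowers the energy.
"""

from rdkit import Chem

from qsarready import embed_3d, load_blocklist, load_rule_file
from qsarready.pipeline import DEFAULT_3D_SEED, StandardizationConfig, standardize_record
from qsarready.chem_io import ChemicalRecord
from qsarready.validation import parse_structure

library = load_rule_file()
blocklist = load_blocklist()
config = StandardizationConfig()

for smiles in ("CCO", "CC(=O)Oc1ccccc1C(=O)O"):
    record = ChemicalRecord(identifier=smiles, raw_input=smiles,
                            source_format="smi", graph=parse_structure(smiles, "smi"),
                            original_smiles=smiles)
    result = standardize_record(record, config, library, blocklist)
    out = embed_3d(result.graph, result.stereo_payload, seed=DEFAULT_3D_SEED)
    mol3d, e_initial, e_final = out
    conf = mol3d.GetConformer()
    print(f"{smiles}: {mol3d.GetNumAtoms()} atoms with hydrogens, "
          f"energy {e_initial:.3f} -> {e_final:.3f} kcal/mol")
    for i in range(min(4, mol3d.GetNumAtoms())):
        p = conf.GetAtomPosition(i)
        sym = mol3d.GetAtomWithIdx(i).GetSymbol()
        print(f"  {sym:2s} {p.x:8.4f} {p.y:8.4f} {p.z:8.4f}")
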