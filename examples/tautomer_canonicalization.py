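"""Tautomer and mesomer canonicalization with the transformation rule library.

Different drawings of the same compound — keto/enol pairs, hypervalent vs
charge-separated nitro groups, azide resonance forms, hydroxypyridine vs
pyridone — all converge to one canonical structure and one InChI.
"""

from rdkit import Chem

from qsarready import load_rule_file
from qsarready.transforms import standardize_mesomers_tautomers
from qsarready.validation import correct_valence

library = load_rule_file()

pairs = [
    ("keto-enol", ["CC(O)=C", "CC(C)=O"]),
    ("nitro mesomers", ["CN(=O)=O", "C[N+](=O)[O-]"]),
    ("azide mesomers", ["C[N-][N+]#N", "CN=[N+]=[N-]"]),
    ("enamine-imine", ["C=C(C)N", "CC(C)=N"]),
    ("2-pyridone", ["Oc1ccccn1", "O=c1cccc[nH]1"]),
]

for label, drawings in pairs:
    print(label)
    canon = set()
    for smiles in drawings:
        mol = Chem.MolFromSmiles(smiles, sanitize=False)
        mol.UpdatePropertyCache(strict=False)
        mol, _ = correct_valence(mol)  # fixes hypervalent drawings first
        out = standardize_mesomers_tautomers(mol, library)
        out_smiles = Chem.MolToSmiles(out)
        canon.add(Chem.MolToInchi(out))
        print(f"  {smiles:18s} -> {out_smiles}")
    print(f"  distinct InChI after standardization: {len(canon)}\n")
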