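"""Salt and solvent stripping on multi-fragment records.

Shows how blocklisted counterions and solvents are removed, how the parent's
formal charge is rebalanced afterwards, and why a single-component solvent
record survives as its own parent.
"""

from rdkit import Chem

from qsarready import load_blocklist, strip_and_rebalance
from qsarready.fragments import StripResult

blocklist = load_blocklist()

cases = [
    "CC(=O)[O-].[Na+]",                       # sodium acetate
    "Cl.Nc1ccccc1",                           # aniline hydrochloride
    "CC[NH3+].Cc1ccc(cc1)S([O-])(=O)=O",      # ethylamine tosylate
    "CC(N)=O.O",                              # acetamide monohydrate
    "CS(C)=O",                                # DMSO alone: its own parent
    "CCO.CCN",                                # a true mixture
    "[Na+].[Cl-]",                            # nothing organic at all
]

for smiles in cases:
    result = strip_and_rebalance(Chem.MolFromSmiles(smiles), blocklist)
    print(f"input   {smiles}")
    if isinstance(result, StripResult):
        print(f"  parent  {Chem.MolToSmiles(result.parent)}")
        for frag, salt_id in result.stripped:
            print(f"  removed {Chem.MolToSmiles(frag)}  "
                  f"(blocklist id: {salt_id or 'none'})")
        for op in result.charge_ops:
            print(f"  charge  {op}")
    else:
        print(f"  discarded: {result}")
    print()
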