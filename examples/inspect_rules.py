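"""Browse and toggle the transformation rule library.

The library is an ordered, tab-separated rule file; every rule can be turned
on or off individually, and order matters because some rules do not commute.
"""

from collections import Counter

from rdkit import Chem

from qsarready import load_rule_file
from qsarready.fixtures import rule_order_probe
from qsarready.transforms import standardize_mesomers_tautomers

library = load_rule_file()

print(f"{len(library)} rules, {len(library.enabled())} enabled")
by_family = Counter(r.family for r in library.rules)
for family, n in sorted(by_family.items()):
    enabled = sum(1 for r in library.rules if r.family == family and r.enabled)
    print(f"  {family:15s} {n:3d} rules ({enabled} enabled)")

print("\nfirst five rules in application order:")
for rule in library.rules[:5]:
    print(f"  {rule.order_index:5d} {rule.rule_id:15s} {rule.name}")

# order sensitivity: a structure where two rules both match
structure, rule_a, rule_b, result_ab, result_ba = rule_order_probe(library)
print(f"\norder probe on {structure}:")
print(f"  {rule_a} then {rule_b}: {result_ab}")
print(f"  {rule_b} then {rule_a}: {result_ba}")
engine = Chem.MolToSmiles(
    standardize_mesomers_tautomers(Chem.MolFromSmiles(structure), library)
)
print(f"  library order gives:  {engine}")

# toggling: disable the keto-enol rule and watch the enol survive
library.disable(["TAUT-KE-01"])
enol = Chem.MolFromSmiles("CC(O)=C")
print(f"\nwith TAUT-KE-01 disabled, CC(O)=C -> "
      f"{Chem.MolToSmiles(standardize_mesomers_tautomers(enol, library))}")
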