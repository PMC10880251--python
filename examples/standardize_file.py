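"""Standardize a small SMILES file end to end and inspect the five outputs.

Writes a demo input, runs the full workflow with deduplication, and prints
the run report plus the summary and discarded CSVs.
"""

import csv
import os
import tempfile

from qsarready import StandardizationConfig, run

demo = """\
CCO ethanol
C1=CC=CC=C1 benzene_kekule
c1ccccc1 benzene_aromatic
CC(=O)[O-].[Na+] sodium_acetate
CN(=O)=O nitromethane_drawn_pentavalent
Oc1ccccn1 2-hydroxypyridine
O=c1cccc[nH]1 2-pyridone
CCO.CCN ethanol_ethylamine_mixture
[Na+].[Cl-] table_salt
not-a-structure corrupt_entry
"""

workdir = tempfile.mkdtemp(prefix="qsarready_demo_")
input_path = os.path.join(workdir, "demo.smi")
with open(input_path, "w", encoding="utf-8") as fh:
    fh.write(demo)

config = StandardizationConfig(
    input_path=input_path, output_dir=workdir, dedup=True
)
report = run(config)

print(f"{report.n_input} read, {report.n_standardized} standardized, "
      f"{report.n_discarded} discarded")
for reason, n in sorted(report.reason_counts.items()):
    print(f"  {reason}: {n}")

print("\nsummary file:")
with open(report.output_files["summary"], newline="") as fh:
    for row in csv.DictReader(fh):
        print(f"  {row['ID']:34s} {row['Canonical_QSARr']:20s} "
              f"{row['InChIKey']}")

print("\ndiscarded structures:")
with open(report.output_files["discarded"], newline="") as fh:
    for row in csv.DictReader(fh):
        print(f"  {row['ID']:34s} {row['Reason']}")
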