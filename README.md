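# qsarready

QSAR-ready chemical structure standardization: turn heterogeneous, messy
structure collections into one clean, deduplicated, model-ready structure per
substance — and account for every record that didn't make it.

## The problem

Structure–activity datasets assembled from registries, vendor catalogs and
literature mix representations that are chemically equivalent but textually
different: salts and solvates of the same parent compound, tautomeric and
mesomeric drawings (keto/enol, hypervalent vs. charge-separated nitro,
2-hydroxypyridine vs. 2-pyridone), protonation states, aromatic vs. Kekulé
ring notation, explicit vs. implicit hydrogens. Descriptor calculators treat
each variant as a different molecule, so the same compound can appear several
times with conflicting activity values, silently corrupting a QSAR model.
At the other extreme, some records cannot be modeled at all — mixtures,
inorganics, organometallics, Markush structures, corrupt entries — and must
be removed, but removed *traceably*.

## The method

Each input record flows through a fixed sequence of stages; the first failing
stage discards the record with one tag from a closed vocabulary
(`failed_parsing`, `mixture`, `inorganic`, `organometallic`,
`ambiguous_structure`, `size`, `nano_shape`, `duplicate`):

1. **Parse** SMILES/CSV/MOL/SDF input (RDKit), keeping unparseable records
   for the report instead of dropping them.
2. **Valence remediation** — hypervalent neutral drawings (pentavalent nitro,
   N-oxides, azides) are rewritten to their charge-separated equivalents.
3. **Ambiguity filter** — Markush / R-group / query structures are rejected.
4. **Salt & solvent stripping** — blocklisted counterions and solvents are
   removed (matched by the protonation-insensitive InChIKey skeleton block),
   the parent charge is rebalanced by proton moves, true mixtures are
   rejected.
5. **Composition filter** — inorganic and organometallic parents are tagged.
6. **Mesomer/tautomer canonicalization** — an ordered library of 102
   individually toggleable `pattern>>product` transformation rules, applied
   once in a documented order (some rule pairs do not commute), each rule to
   a fixed point.
7. **Neutralization, stereo flattening, hydrogen virtualization, ring-mode
   normalization (aromatic or Kekulé), crossed-bond marking for unknown
   double-bond geometry, 2D coordinate sanitization.**
8. **Optional size/shape filter** (molecular weight, heavy-atom count, and a
   bonds-per-heavy-atom nano-structure ratio) and **optional seeded 3D
   conformer generation** (ETKDG + force-field minimization,
   bit-reproducible for a fixed seed).
9. **InChI-based deduplication** (optional; first occurrence wins) and the
   five-file output contract: QSAR-ready SDF, QSAR-ready SMILES, summary
   CSV, discarded-structures CSV, stripped-salts CSV.

Record conservation is a hard invariant: every input lands in exactly one of
the summary or discarded files, and heavy atoms are conserved through salt
stripping.

See [docs/methods.md](docs/methods.md) for the model, parameter defaults and
limitations.

## Worked example

`examples/standardize_file.py` builds a ten-record demo file and runs the
full workflow with deduplication:

```
$ python examples/standardize_file.py
10 read, 5 standardized, 5 discarded
  duplicate: 2
  failed_parsing: 1
  inorganic: 1
  mixture: 1

summary file:
  ethanol                            CCO                  LFQSCWFLJHTTHZ-UHFFFAOYSA-N
  benzene_kekule                     c1ccccc1             UHOVQNZJYSORNB-UHFFFAOYSA-N
  sodium_acetate                     CC(=O)O              QTBSBXVTEAMEQO-UHFFFAOYSA-N
  nitromethane_drawn_pentavalent     C[N+](=O)[O-]        LYGJENNIWJXYER-UHFFFAOYSA-N
  2-hydroxypyridine                  O=c1cccc[nH]1        UBQKCCHYAOITMY-UHFFFAOYSA-N

discarded structures:
  ethanol_ethylamine_mixture         mixture
  table_salt                         inorganic
  corrupt_entry                      failed_parsing
  benzene_aromatic                   duplicate
  2-pyridone                         duplicate
```

Note the chemistry: Kekulé and aromatic benzene collapse to one record, the
pentavalent nitro drawing is remediated to `C[N+](=O)[O-]`, sodium acetate is
desalted and protonated to acetic acid, and 2-hydroxypyridine is
canonicalized to 2-pyridone — which then makes the separately-entered
2-pyridone a duplicate.

The same workflow is available on the command line:

```bash
qsar-ready-std run input.smi --dedup --out results/
qsar-ready-std run input.csv --smiles-col structure --id-col compound_id --3d
```

The other example scripts each demonstrate one capability:
`salt_stripping.py`, `tautomer_canonicalization.py`, `inspect_rules.py`
(browsing/toggling the rule library and the order-sensitivity probe),
`generate_3d.py`.

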