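# Methods

## Model

A substance record is modeled as raw structure text plus an identifier. The
molecular graph container is `rdkit.Chem.Mol` throughout; parsing is done
with sanitization deferred (`sanitize=False` + property-cache update), so
records whose only defect is an illegal valence reach the remediation stage
instead of failing at the parser. Standardization is a pure function of
(record, configuration, rule library, blocklist): no stage consults global
state, no randomness is used outside seeded 3D embedding, and rerunning a
pipeline on its own output is a no-op (idempotence is enforced by tests).

### Stage order

```
parse → valence remediation → ambiguous filter → fragment split /
salt stripping / mixture filter → composition filter → mesomer/tautomer
rules → neutralization → stereo flattening → hydrogen virtualization →
ring mode → crossed double bonds → coordinate sanitization → size/shape
filter → InChI / canonical SMILES → (set-level) deduplication → (optional) 3D
```

The first failing stage short-circuits with one reason tag from the closed
vocabulary `failed_parsing, mixture, inorganic, organometallic,
ambiguous_structure, size, nano_shape, duplicate`. Order rationale: valence
remediation precedes everything because later SMARTS matching assumes legal
valences; stripping precedes the composition filter so that an organic parent
with an inorganic counterion is not misclassified; the rule library runs
before neutralization so rules see remediated, desalted parents; stereo and
hydrogen normalization precede ring mode and InChI so the identifiers hash
the final graph.

### Valence remediation

A small ordered table, not the rule library, because these inputs cannot be
sanitized and therefore cannot be SMARTS-matched: (1) neutral nitrogen with
explicit valence > 3 and a terminal double-bonded oxygen — one N=O becomes
N(+)–O(−), repeated while hypervalent (handles nitro, nitrate, N-oxides);
(2) cumulated neutral azide drawings — central N becomes N(+), terminal N(−).
Remediation never changes the heavy-atom multiset or connectivity, only bond
orders, charges and hydrogen counts. Anything still illegal afterwards
(e.g. pentavalent carbon) is irreparable → `failed_parsing`.

### Composition

"Organic" means carbon-containing with no covalent carbon–metal bond;
"organometallic" means at least one carbon–metal bond; "inorganic" means no
carbon. The non-metal element set is {H, B, C, N, O, Si, P, S, Se, halogens,
noble gases}; every other element counts as a metal. Ionic association
(disconnected `[Na+]`) is not a carbon–metal bond.

### Salt/solvent stripping

The shipped blocklist has 60 entries (counterions, common salt anions,
solvents), each reduced at load time to the first (skeleton) block of its
standard InChIKey. Matching on the skeleton block makes lookup insensitive
to protonation state — one acetate entry matches both acetate and acetic
acid — but sensitive to composition, so HCl and chloride share one entry.
Consequences of this design: hydroxide and water would collide (hydroxide is
deliberately absent), and protonated/deprotonated forms of an entry are all
stripped.

After removing blocklisted fragments: identical copies of the surviving
organic fragment collapse to one parent; two or more *distinct* surviving
organic fragments → `mixture`; surviving non-blocklisted inorganic fragments
are stripped with an empty blocklist id. If stripping would remove
everything, the largest carbon-containing blocklisted fragment is reinstated
as the parent — a record consisting only of DMSO is the compound DMSO, not a
solvent to strip — and only if nothing carbon-containing exists at all is the
record `inorganic`. The parent's formal charge is then driven toward zero by
proton addition/removal at N, O, S, P, Se only (never carbon); anions whose
neighbor carries a positive charge (nitro oxygen, N-oxide oxygen) are
permanent and never protonated, as are hydrogen-free cations (quaternary
ammonium).

Heavy atoms are conserved: parent + stripped fragments always carry exactly
the input's heavy atoms.

### Transformation rule library

`src/qsarready/data/transform_rules.tsv`: 102 rules, 77 enabled by default,
in six tab-separated fields (`rule_id`, `order_index`, `enabled`, `family`,
`pattern>>product`, `name`). Families: `mesomer` (charge/bond-order
normalization without H movement: azide, diazo, N-oxide, nitrone, azoxy,
sulfoxide, phosphoryl, ylides), `tautomer` (H-moving canonicalization:
keto-enol, imine-enamine, thio and seleno analogues, imidic acid → amide,
lactam rules for 2-/4-hydroxyazines, nitroso/oxime, phosphonate, vinylogous
variants), plus disabled `neutralization`-family and expert rules that users
can switch on.

Conventions: each chemical transformation is split into hydrogen-count
variants (`[CH2:]`, `[CH1:]`, `[CH0:]`) so product hydrogen bookkeeping is
explicit and safe; product atoms carry explicit formal charges (reaction
products inherit reactant charges otherwise); exclusion patterns keep rules
off aromatic and amide-like sites (e.g. enamine rules exclude `N–C=O`
neighborhoods so amides are fixed points; phenol is never "ketonized"
because the keto-enol patterns require a non-aromatic enol carbon, and
aromatic lactam rules are written with explicit ring-bond Kekulé product
templates that re-aromatize on sanitization).

Engine semantics: rules are applied **once through the library in
`order_index` order**; each rule iterates to a fixed point (cap: 10 passes)
before the next rule runs. Candidate products that fail sanitization or
change the heavy-atom multiset are rolled back; among multiple valid
products of one pass, the lexicographically smallest canonical SMILES is
chosen, which makes the engine deterministic and independent of atom
ordering. Order is authoritative because some rule pairs do not commute:
`rule_order_probe` exhibits 1-aminoethenol (`OC(=C)N`), where
keto-enol-then-enamine gives acetamide but the reverse order gives acetimidic
acid; the shipped order applies keto-enol first. One library pass is
idempotent on the whole fixture corpus (tested); a fixed-point outer loop was
deliberately not used, so a pathological user rule set cannot cycle.

### Other transforms

- **Neutralization**: zwitterions first resolve by paired proton transfer
  (cation hydrogen moved to an anion), then leftover cations are
  deprotonated, leftover anions protonated. Net |charge| never increases.
- **Stereo**: tetrahedral and double-bond descriptors are removed for the 2D
  deliverable (QSAR descriptors are overwhelmingly 2D and registry stereo
  is unreliable), but saved as a payload and reinstated before 3D embedding.
- **Hydrogens**: explicit hydrogens fold into implicit counts; isotopic
  hydrogens (D/T) stay explicit because folding would erase the label.
- **Ring mode**: `aromatic` (RDKit 4n+2 perception) or `kekule` rendering.
  Both denote the same structure; their InChI strings are identical (tested
  corpus-wide), so the choice only affects SDF/SMILES text.
- **Crossed bonds**: stereogenic double bonds of unspecified geometry are
  marked `STEREOANY`, which RDKit's V2000 writer renders as a crossed bond.
- **Coordinates**: a 2D layout is generated when absent or degenerate
  (all-zero or coincident atoms within 1e-4 Å).

## Parameters and defaults

| parameter | default | rationale |
|---|---|---|
| `ring_mode` | `aromatic` | smaller, more conventional SMILES; Kekulé available for tools that need it |
| `dedup` | off | deduplication is a set-level decision the user should opt into |
| `size_filter.enabled` | off | a filtering policy, not a chemistry correction |
| `size_filter.heavy_min` | 2 | single-atom records carry no meaningful 2D descriptors |
| `size_filter.mw_min/mw_max`, `heavy_max` | unset | dataset-specific; no defensible universal value |
| `size_filter.nano_ratio_max` | 1.3 | bonds/heavy-atoms for a connected graph is `1 + (rings − 1)/atoms`; 1.3 separates fused cages (C60: 1.5, cubane-like cage: 1.375) from ordinary polycyclics (adamantane: 1.2). A tunable engineering threshold, not a literature constant |
| `seed_3d` | 20809 | arbitrary fixed integer; the *fixity* is what matters — same seed, bit-identical ETKDG coordinates |
| rule iteration cap | 10 passes/rule | termination guard against oscillating user rules; hitting it is logged |
| coordinate tolerance | 1e-4 Å | below drawing precision; only flags truly degenerate layouts |

## Fixture corpus scope

The built-in corpus (53 structures) is a coverage instrument, not a chemical
survey: every discard reason has ≥ 2 cases, every transform family and salt
path is exercised, and five tautomer/mesomer groups have ≥ 2 drawings each.
It deliberately contains borderline cases (DMSO alone, duplicated organic
fragments, skeleton-block salt collisions). It does **not** emulate the
scale, element distribution, or error profile of real registry data, and
timing/throughput claims cannot be derived from it.

## Numerical choices

InChI (standard, no nonstandard options) is the deduplication key because it
canonicalizes tautomer-irrelevant detail (protonation layers) consistently
and is generator-independent. 3D embedding uses ETKDGv3 with a fixed seed,
then MMFF94 minimization (UFF fallback when MMFF parameters are missing,
e.g. for unusual elements); energies are force-field values used only for
the monotonic-decrease contract, never as physical predictions. Floating
point enters only in coordinates and energies; all structure-level decisions
are made on discrete graphs, so results are platform-stable.

## Limitations

- Tautomer canonicalization is rule-based, not energy-based: the canonical
  form is the conventional drawing, not necessarily the dominant solution
  species, and rules cover common functional groups rather than exotica.
- The blocklist is a starting set (60 entries); real projects extend it via
  `--blocklist`. Skeleton-block matching cannot distinguish protonation
  states of the same skeleton, by design.
- Neutralization is structural, not pKa-aware; it will protonate weakly
  acidic anions that a pKa model might leave charged.
- Mixture detection treats any two distinct surviving organic fragments as a
  mixture; deliberate co-crystals or defined mixtures need upstream handling.
- Stereochemistry is discarded in the 2D deliverable; enantiomers collapse
  to one record by construction.
- The nano-shape ratio flags dense polycyclic cages, not nanomaterials in a
  physical sense (no size, composition or surface model).
- 3D output is a single conformer for geometry-requiring descriptor codes,
  not a conformational ensemble.
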