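"""Reaction-format standardization rule engine and graph-level transforms.

The heart of the standardizer: an ordered library of toggleable
pattern>>product transformation rules for mesomer and tautomer
canonicalization, plus the non-rule transforms — neutralization,
stereochemistry flattening, hydrogen virtualization, crossed double bonds,
aromatic/Kekulé ring mode and 2D coordinate sanitization.

Rule order is authoritative: some rule pairs do not commute, so the library
is applied exactly once, in ``order_index`` order, each rule iterated to a
fixed point (capped) before the next one runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from rdkit import Chem
from rdkit.Chem import AllChem, rdDepictor


class RuleLoadError(ValueError):
    """Raised when a rule file cannot be parsed."""


class StandardizationError(RuntimeError):
    """Raised for graph states that signal upstream corruption."""


@dataclass
class TransformRule:
    rule_id: str
    order_index: int
    enabled: bool
    family: str  # mesomer | tautomer | neutralization | other
    smirks: str
    name: str
    _rxn: AllChem.ChemicalReaction | None = field(default=None, repr=False)

    @property
    def reaction(self) -> AllChem.ChemicalReaction:
        if self._rxn is None:
            self._rxn = AllChem.ReactionFromSmarts(self.smirks)
        return self._rxn


@dataclass
class RuleLibrary:
    rules: list[TransformRule]
    source: str = "<builtin>"
    version: str = "1"

    def __post_init__(self) -> None:
        self.rules.sort(key=lambda r: r.order_index)

    def enabled(self, families: tuple[str, ...] | None = None) -> list[TransformRule]:
        out = [r for r in self.rules if r.enabled]
        if families is not None:
            out = [r for r in out if r.family in families]
        return out

    def disable(self, rule_ids: list[str]) -> None:
        wanted = set(rule_ids)
        for r in self.rules:
            if r.rule_id in wanted:
                r.enabled = False

    def __len__(self) -> int:
        return len(self.rules)


def load_rule_file(path: str | None = None) -> RuleLibrary:
    """Parse a tab-separated rule file into a :class:`RuleLibrary`.

    Line format: ``rule_id  order_index  enabled  family  pattern>>product
    name``; lines starting with ``#`` are comments.  Malformed lines,
    unparseable reaction expressions and duplicate order indices all raise
    :class:`RuleLoadError` naming the offending rule/line.
    """
    if path is None:
        ref = resources.files("qsarready.data").joinpath("transform_rules.tsv")
        text = ref.read_text(encoding="utf-8")
        source = "<builtin>"
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        source = str(path)
    rules: list[TransformRule] = []
    errors: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 6:
            errors.append(f"line {lineno}: expected 6 tab-separated fields, got {len(parts)}")
            continue
        rule_id, order_s, enabled_s, family, smirks, name = parts
        try:
            order = int(order_s)
        except ValueError:
            errors.append(f"line {lineno} ({rule_id}): bad order_index {order_s!r}")
            continue
        if ">>" not in smirks:
            errors.append(f"line {lineno} ({rule_id}): not a pattern>>product expression")
            continue
        try:
            rxn = AllChem.ReactionFromSmarts(smirks)
        except Exception as exc:
            errors.append(f"line {lineno} ({rule_id}): unparseable reaction: {exc}")
            continue
        if rxn is None:
            errors.append(f"line {lineno} ({rule_id}): unparseable reaction")
            continue
        rules.append(
            TransformRule(
                rule_id=rule_id.strip(),
                order_index=order,
                enabled=enabled_s.strip() == "1",
                family=family.strip(),
                smirks=smirks,
                name=name.strip(),
                _rxn=rxn,
            )
        )
    if errors:
        raise RuleLoadError("; ".join(errors))
    orders = [r.order_index for r in rules]
    if len(orders) != len(set(orders)):
        dupes = sorted({o for o in orders if orders.count(o) > 1})
        raise RuleLoadError(f"duplicate order_index values: {dupes}")
    return RuleLibrary(rules=rules, source=source)


MAX_RULE_PASSES = 10


def apply_rule(
    mol: Chem.Mol, rule: TransformRule, log: list[str] | None = None
) -> Chem.Mol:
    """Apply one rule repeatedly until no match changes the structure.

    Each pass transforms one match site; candidate products that fail
    sanitization or change the heavy-atom multiset are rolled back (rules may
    only move hydrogens, charges and bond orders).  A pass cap guarantees
    termination against oscillating patterns; hitting it is logged.
    """
    current = mol
    cur_smi = Chem.MolToSmiles(current)
    heavy_counts = _heavy_formula(current)
    for _ in range(MAX_RULE_PASSES):
        try:
            products = rule.reaction.RunReactants((current,))
        except Exception:
            break
        candidates = []
        for (prod,) in products:
            cand = Chem.Mol(prod)
            try:
                Chem.SanitizeMol(cand)
            except Exception:
                continue
            if _heavy_formula(cand) != heavy_counts:
                if log is not None:
                    log.append(f"{rule.rule_id}: rolled back heavy-atom-changing product")
                continue
            candidates.append((Chem.MolToSmiles(cand), cand))
        if not candidates:
            break
        candidates.sort(key=lambda t: t[0])
        new_smi, new_mol = candidates[0]
        if new_smi == cur_smi:
            break
        current, cur_smi = new_mol, new_smi
        if log is not None:
            log.append(f"{rule.rule_id}: applied -> {new_smi}")
    else:
        if log is not None:
            log.append(f"{rule.rule_id}: iteration cap reached ({MAX_RULE_PASSES} passes)")
    return current


def _heavy_formula(mol: Chem.Mol) -> tuple:
    counts: dict[int, int] = {}
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() > 1:
            counts[atom.GetAtomicNum()] = counts.get(atom.GetAtomicNum(), 0) + 1
    return tuple(sorted(counts.items()))


def standardize_mesomers_tautomers(
    mol: Chem.Mol, library: RuleLibrary, log: list[str] | None = None
) -> Chem.Mol:
    """One ordered pass of all enabled mesomer/tautomer rules."""
    current = mol
    for rule in library.enabled(families=("mesomer", "tautomer")):
        current = apply_rule(current, rule, log=log)
    return current


_PROTON_DONORS = {7, 8, 16, 15, 34}


def neutralize(mol: Chem.Mol, log: list[str] | None = None) -> Chem.Mol:
    """Best-effort charge neutralization; net |charge| never increases.

    Zwitterions are resolved first by paired proton transfer (cation hydrogen
    moved to an anion), then leftover cations are deprotonated and leftover
    anions protonated.  Permanent charges (quaternary ammonium, the anionic
    oxygen of a nitro group) are untouchable by construction: cations without
    hydrogens cannot donate, anions adjacent to a cation never accept.
    """
    out = Chem.Mol(mol)
    # paired transfer: zwitterion to covalent form
    while True:
        cat = _donor_cation(out)
        an = _acceptor_anion(out)
        if cat is None or an is None:
            break
        _move_proton(out, cat, an)
        if log is not None:
            log.append(
                f"neutralize: proton moved {cat.GetSymbol()}{cat.GetIdx()} -> "
                f"{an.GetSymbol()}{an.GetIdx()}"
            )
    net = Chem.GetFormalCharge(out)
    while net > 0:
        cat = _donor_cation(out)
        if cat is None:
            break
        cat.SetNumExplicitHs(max(0, cat.GetTotalNumHs() - 1))
        cat.SetNoImplicit(True)
        cat.SetFormalCharge(cat.GetFormalCharge() - 1)
        Chem.SanitizeMol(out)
        if log is not None:
            log.append(f"neutralize: deprotonated {cat.GetSymbol()}{cat.GetIdx()}")
        net = Chem.GetFormalCharge(out)
    while net < 0:
        an = _acceptor_anion(out)
        if an is None:
            break
        an.SetNumExplicitHs(an.GetTotalNumHs() + 1)
        an.SetNoImplicit(True)
        an.SetFormalCharge(an.GetFormalCharge() + 1)
        Chem.SanitizeMol(out)
        if log is not None:
            log.append(f"neutralize: protonated {an.GetSymbol()}{an.GetIdx()}")
        net = Chem.GetFormalCharge(out)
    return out


def _donor_cation(mol: Chem.Mol):
    for atom in mol.GetAtoms():
        if (
            atom.GetFormalCharge() > 0
            and atom.GetTotalNumHs() > 0
            and atom.GetAtomicNum() in _PROTON_DONORS
        ):
            return atom
    return None


def _acceptor_anion(mol: Chem.Mol):
    for atom in mol.GetAtoms():
        if atom.GetFormalCharge() < 0 and atom.GetAtomicNum() in _PROTON_DONORS:
            if any(n.GetFormalCharge() > 0 for n in atom.GetNeighbors()):
                continue  # charge-separated group (nitro, N-oxide): permanent
            return atom
    return None


def _move_proton(mol: Chem.Mol, cation, anion) -> None:
    cation.SetNumExplicitHs(max(0, cation.GetTotalNumHs() - 1))
    cation.SetNoImplicit(True)
    cation.SetFormalCharge(cation.GetFormalCharge() - 1)
    anion.SetNumExplicitHs(anion.GetTotalNumHs() + 1)
    anion.SetNoImplicit(True)
    anion.SetFormalCharge(anion.GetFormalCharge() + 1)
    Chem.SanitizeMol(mol)


def flatten_stereo(mol: Chem.Mol) -> tuple[Chem.Mol, dict]:
    """Strip tetrahedral and double-bond stereo, returning it as a payload.

    The payload maps atom indices to chiral tags and bond index pairs to
    (stereo descriptor, reference-atom indices) so 3D generation can
    reinstate configuration when requested.
    """
    out = Chem.Mol(mol)
    payload: dict = {"atoms": {}, "bonds": {}}
    for atom in out.GetAtoms():
        if atom.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED:
            payload["atoms"][atom.GetIdx()] = atom.GetChiralTag()
    for bond in out.GetBonds():
        if bond.GetStereo() not in (
            Chem.BondStereo.STEREONONE,
            Chem.BondStereo.STEREOANY,
        ):
            payload["bonds"][(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())] = (
                bond.GetStereo(),
                tuple(bond.GetStereoAtoms()),
            )
    Chem.RemoveStereochemistry(out)
    return out, payload


def reapply_stereo(mol: Chem.Mol, payload: dict) -> Chem.Mol:
    """Reinstate a stereo payload captured by :func:`flatten_stereo`."""
    out = Chem.Mol(mol)
    for idx, tag in payload.get("atoms", {}).items():
        if idx < out.GetNumAtoms():
            out.GetAtomWithIdx(idx).SetChiralTag(tag)
    for (i, j), (stereo, ref_atoms) in payload.get("bonds", {}).items():
        bond = out.GetBondBetweenAtoms(i, j)
        if bond is not None and len(ref_atoms) == 2:
            bond.SetStereoAtoms(*ref_atoms)
            bond.SetStereo(stereo)
    return out


def virtualize_hydrogens(mol: Chem.Mol) -> Chem.Mol:
    """Fold explicit hydrogen atoms into implicit counts.

    Isotopic hydrogens (D/T) stay explicit — folding them would erase the
    isotope label.
    """
    return Chem.RemoveHs(Chem.Mol(mol))  # RemoveHs keeps isotopes by default


def set_ring_mode(mol: Chem.Mol, mode: str) -> Chem.Mol:
    """Switch ring representation: ``aromatic`` (4n+2 perception) or ``kekule``.

    Both representations denote the same structure — their InChI strings are
    identical — so this only affects the SDF/SMILES rendering.
    """
    out = Chem.Mol(mol)
    if mode == "aromatic":
        Chem.SanitizeMol(out)
        Chem.SetAromaticity(out)
    elif mode == "kekule":
        try:
            Chem.Kekulize(out, clearAromaticFlags=True)
        except Chem.KekulizeException as exc:
            raise StandardizationError(f"cannot kekulize: {exc}") from exc
    else:
        raise ValueError(f"unknown ring mode {mode!r}")
    return out


def fix_crossed_double_bonds(mol: Chem.Mol) -> Chem.Mol:
    """Mark stereo-capable double bonds of unknown configuration as crossed.

    The crossed-bond flag surfaces in V2000 SDF output (stereo field 3 on the
    double bond); terminal alkenes and aromatic bonds are never flagged.
    """
    out = Chem.Mol(mol)
    Chem.FindPotentialStereoBonds(out)
    # FindPotentialStereoBonds marks candidates STEREOANY, which is exactly
    # the crossed-bond depiction contract for the SDF writer.
    return out


COORD_TOLERANCE = 1e-4


def sanitize_coordinates(mol: Chem.Mol) -> Chem.Mol:
    """Ensure a usable 2D layout: generate one when absent or degenerate."""
    out = Chem.Mol(mol)
    if out.GetNumConformers() == 0 or _degenerate_coords(out):
        rdDepictor.Compute2DCoords(out)
    return out


def _degenerate_coords(mol: Chem.Mol) -> bool:
    conf = mol.GetConformer()
    pts = [conf.GetAtomPosition(i) for i in range(mol.GetNumAtoms())]
    if mol.GetNumAtoms() > 1 and all(
        abs(p.x) < COORD_TOLERANCE and abs(p.y) < COORD_TOLERANCE for p in pts
    ):
        return True
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d2 = (
                (pts[i].x - pts[j].x) ** 2
                + (pts[i].y - pts[j].y) ** 2
                + (pts[i].z - pts[j].z) ** 2
            )
            if d2 < COORD_TOLERANCE**2:
                return True
    return False
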