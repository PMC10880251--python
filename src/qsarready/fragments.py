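"""Multi-fragment handling: salt/solvent stripping and mixture rejection.

A substance drawn as several disconnected fragments is resolved to a single
parent structure by removing every fragment found on the salt/solvent
blocklist, then rebalancing the parent's formal charge by adding or removing
protons.  Records where two or more distinct organic fragments survive
stripping are true mixtures and fail standardization; records where nothing
organic ever existed are inorganic.

Blocklist matching uses the first (skeleton) block of the standard InChIKey,
which is insensitive to protonation state, so one acetate entry matches both
acetate and acetic acid fragments.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

from rdkit import Chem

from .validation import ReasonTag, classify_composition


@dataclass(frozen=True)
class BlocklistEntry:
    salt_id: str
    smiles: str
    cls: str  # salt | solvent | counterion
    name: str
    inchikey_block: str


@dataclass
class Blocklist:
    entries: list[BlocklistEntry]
    _by_block: dict[str, BlocklistEntry] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        ids = [e.salt_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate salt_id in blocklist")
        for e in self.entries:
            self._by_block.setdefault(e.inchikey_block, e)

    def match(self, block: str) -> BlocklistEntry | None:
        return self._by_block.get(block)


@dataclass
class StripResult:
    """Outcome of fragment resolution for one record."""

    parent: Chem.Mol
    stripped: list[tuple[Chem.Mol, str | None]] = field(default_factory=list)
    charge_ops: list[str] = field(default_factory=list)


def _first_key_block(mol: Chem.Mol) -> str | None:
    try:
        inchi = Chem.MolToInchi(mol, treatWarningAsError=False)
        if not inchi:
            return None
        key = Chem.InchiToInchiKey(inchi)
        return key.split("-")[0] if key else None
    except Exception:
        return None


def load_blocklist(path: str | None = None) -> Blocklist:
    """Load and compile a blocklist CSV (salt_id, smiles, class, name).

    SMILES are parsed and reduced to InChIKey skeleton blocks at load time;
    unparseable rows raise, so a broken user-edited list fails fast.
    """
    if path is None:
        ref = resources.files("qsarready.data").joinpath("salt_blocklist.csv")
        text = ref.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    entries: list[BlocklistEntry] = []
    reader = csv.DictReader(text.splitlines())
    for i, row in enumerate(reader, start=2):
        smi = row["smiles"].strip()
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"blocklist line {i}: unparseable SMILES {smi!r}")
        block = _first_key_block(mol)
        if block is None:
            raise ValueError(f"blocklist line {i}: InChIKey failed for {smi!r}")
        entries.append(
            BlocklistEntry(
                salt_id=row["salt_id"].strip(),
                smiles=smi,
                cls=row["class"].strip(),
                name=row["name"].strip(),
                inchikey_block=block,
            )
        )
    return Blocklist(entries)


def split_fragments(mol: Chem.Mol) -> list[Chem.Mol]:
    """Connected components, largest heavy-atom count first.

    Ties break on canonical SMILES so fragment order in the input string
    never influences downstream decisions.
    """
    frags = list(Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False))
    for f in frags:
        try:
            Chem.SanitizeMol(f)
        except Exception:
            pass
    return sorted(
        frags, key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f))
    )


def lookup_blocklist(fragment: Chem.Mol, blocklist: Blocklist) -> str | None:
    """salt_id of the blocklist entry matching this fragment, or None."""
    block = _first_key_block(fragment)
    if block is None:
        return None
    entry = blocklist.match(block)
    return entry.salt_id if entry else None


def mixture_decision(remaining: list[Chem.Mol]) -> str:
    """``"pass"`` iff at most one distinct organic fragment remains."""
    organic = {
        Chem.MolToSmiles(f)
        for f in remaining
        if classify_composition(f) == "organic"
    }
    return "mixture" if len(organic) > 1 else "pass"


def strip_and_rebalance(
    mol: Chem.Mol, blocklist: Blocklist
) -> StripResult | ReasonTag:
    """Resolve a possibly multi-fragment graph to a single neutral parent.

    Steps: split into fragments; remove all blocklisted fragments; collapse
    identical copies of the surviving organic fragment; reject >= 2 distinct
    surviving organic fragments as a mixture; strip surviving non-blocklisted
    inorganic fragments (logged with no salt_id); finally protonate or
    deprotonate the parent toward net charge zero.

    When stripping would remove everything, the largest organic blocklisted
    fragment is reinstated as the parent — a single-component solvent such as
    DMSO is its own parent structure, not a stripped solvent.  If nothing
    organic exists at all the record is inorganic.
    """
    frags = split_fragments(mol)
    matched: list[tuple[Chem.Mol, str]] = []
    remaining: list[Chem.Mol] = []
    for f in frags:
        sid = lookup_blocklist(f, blocklist)
        if sid is not None:
            matched.append((f, sid))
        else:
            remaining.append(f)

    stripped: list[tuple[Chem.Mol, str | None]] = []

    if not remaining:
        organic_matched = [
            (f, sid) for f, sid in matched if classify_composition(f) != "inorganic"
        ]
        if not organic_matched:
            return ReasonTag.inorganic
        # keep the largest organic blocklisted fragment as the parent itself
        parent_frag, _ = organic_matched[0]
        parent_smi = Chem.MolToSmiles(parent_frag)
        reinstated = False
        for f, sid in matched:
            if not reinstated and Chem.MolToSmiles(f) == parent_smi:
                reinstated = True
                continue
            stripped.append((f, sid))
        remaining = [parent_frag]
    else:
        stripped.extend(matched)

    # "carbon-containing" here, so organometallic parents reach the
    # composition filter and get their own reason tag instead of "inorganic"
    organic = [f for f in remaining if classify_composition(f) != "inorganic"]
    inorganic_left = [f for f in remaining if classify_composition(f) == "inorganic"]

    if not organic:
        return ReasonTag.inorganic
    distinct = {}
    for f in organic:
        distinct.setdefault(Chem.MolToSmiles(f), []).append(f)
    if len(distinct) > 1:
        return ReasonTag.mixture
    # identical organic copies collapse onto one parent; extras are logged
    copies = next(iter(distinct.values()))
    parent = copies[0]
    stripped.extend((f, None) for f in copies[1:])
    stripped.extend((f, None) for f in inorganic_left)

    parent = Chem.Mol(parent)
    ops = _rebalance_charge(parent)
    return StripResult(parent=parent, stripped=stripped, charge_ops=ops)


_PROTONATABLE = {7, 8, 16, 15, 34}  # N, O, S, P, Se — never carbon


def _rebalance_charge(mol: Chem.Mol) -> list[str]:
    """Drive net formal charge toward zero by proton moves, in place."""
    ops: list[str] = []
    rw = mol
    net = Chem.GetFormalCharge(rw)
    while net > 0:
        atom = _find_deprotonatable_cation(rw)
        if atom is None:
            break
        atom.SetNumExplicitHs(max(0, atom.GetTotalNumHs() - 1))
        atom.SetNoImplicit(True)
        atom.SetFormalCharge(atom.GetFormalCharge() - 1)
        ops.append(f"deprotonated {atom.GetSymbol()}{atom.GetIdx()}")
        Chem.SanitizeMol(rw)
        net = Chem.GetFormalCharge(rw)
    while net < 0:
        atom = _find_protonatable_anion(rw)
        if atom is None:
            break
        atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
        atom.SetNoImplicit(True)
        atom.SetFormalCharge(atom.GetFormalCharge() + 1)
        ops.append(f"protonated {atom.GetSymbol()}{atom.GetIdx()}")
        Chem.SanitizeMol(rw)
        net = Chem.GetFormalCharge(rw)
    return ops


def _find_deprotonatable_cation(mol: Chem.Mol):
    for atom in mol.GetAtoms():
        if (
            atom.GetFormalCharge() > 0
            and atom.GetTotalNumHs() > 0
            and atom.GetAtomicNum() in _PROTONATABLE
        ):
            return atom
    return None


def _find_protonatable_anion(mol: Chem.Mol):
    for atom in mol.GetAtoms():
        if atom.GetFormalCharge() < 0 and atom.GetAtomicNum() in _PROTONATABLE:
            # charge-separated groups like nitro keep their anionic oxygen
            if any(n.GetFormalCharge() > 0 for n in atom.GetNeighbors()):
                continue
            return atom
    return None
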