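"""Structural integrity checks and remediation.

Covers the gatekeeping stages of the standardization pipeline: parsing raw
structure text into a molecular graph, remediating illegal valences
(hypervalent nitrogen drawings such as pentavalent nitro groups, N-oxides and
azides), classifying records as organic / inorganic / organometallic,
rejecting ambiguous (Markush / R-group / query) structures, and the optional
size & shape filter.

The molecular graph container is :class:`rdkit.Chem.Mol` throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")


class ReasonTag(str, enum.Enum):
    """Closed vocabulary of discard reasons.

    Every record that does not survive standardization carries exactly one of
    these tags in the discarded-structures CSV.
    """

    failed_parsing = "failed_parsing"
    mixture = "mixture"
    inorganic = "inorganic"
    organometallic = "organometallic"
    ambiguous_structure = "ambiguous_structure"
    size = "size"
    nano_shape = "nano_shape"
    duplicate = "duplicate"

    def __str__(self) -> str:  # writes bare value into CSVs
        return self.value


@dataclass
class ParseFailure:
    """Structured parse/remediation failure; never raised, always returned."""

    message: str
    reason: ReasonTag = ReasonTag.failed_parsing


@dataclass
class SizeShapeLimits:
    """Bounds for the optional size & shape filter.

    ``nano_ratio_max`` bounds the bonds-per-heavy-atom ratio used to flag
    cage-like nano structures (for a connected graph the ratio equals
    ``1 + (rings - 1)/heavy_atoms``, so acyclic molecules always pass any
    threshold >= 1).  The default threshold of 1.3 separates fused cages such
    as fullerenes (C60: 90/60 = 1.5) from ordinary polycyclics; it is a
    configurable artifact choice, not a literature constant.
    """

    enabled: bool = False
    mw_min: float | None = None
    mw_max: float | None = None
    heavy_min: int | None = 2
    heavy_max: int | None = None
    nano_ratio_max: float | None = 1.3

    def __post_init__(self) -> None:
        if self.mw_min is not None and self.mw_max is not None and self.mw_min > self.mw_max:
            raise ValueError("mw_min > mw_max")
        if (
            self.heavy_min is not None
            and self.heavy_max is not None
            and self.heavy_min > self.heavy_max
        ):
            raise ValueError("heavy_min > heavy_max")


# Elements treated as non-metals when deciding organometallic character:
# H, B, C, N, O, Si, P, S, Se, the halogens and the noble gases.
_NONMETALS = frozenset(
    [1, 2, 5, 6, 7, 8, 9, 10, 14, 15, 16, 17, 18, 34, 35, 36, 53, 54, 85, 86]
)


def is_metal(atomic_num: int) -> bool:
    return atomic_num not in _NONMETALS and atomic_num > 0


def parse_structure(raw: str, fmt: str) -> Chem.Mol | ParseFailure:
    """Parse SMILES or MOL-block text into a sanitized molecular graph.

    Returns a :class:`ParseFailure` on syntactic corruption.  Inputs whose
    only defect is an illegal valence are parsed without sanitization and
    handed to :func:`correct_valence`, which performs the remediation and the
    final legality check; the returned graph from this function is therefore
    sanitized only when sanitization succeeds directly.
    """
    if not raw or not raw.strip():
        return ParseFailure("empty structure input")
    if fmt in ("smi", "csv", "smiles"):
        mol = Chem.MolFromSmiles(raw, sanitize=False)
        if mol is None:
            msg = "SMILES syntax error"
            if _looks_like_open_ring(raw):
                msg = "SMILES syntax error: unclosed ring closure bond"
            return ParseFailure(msg)
    elif fmt in ("mol", "sdf"):
        mol = Chem.MolFromMolBlock(raw, sanitize=False, removeHs=False)
        if mol is None:
            return ParseFailure("MOL block parse error (corrupt connection table)")
    else:
        return ParseFailure(f"unsupported format {fmt!r}")
    try:
        mol.UpdatePropertyCache(strict=False)
    except Exception as exc:  # pragma: no cover - extremely corrupt graphs
        return ParseFailure(f"property perception failed: {exc}")
    return mol


def _looks_like_open_ring(smiles: str) -> bool:
    """Heuristic message improvement: unmatched ring-closure digits."""
    import re

    counts: dict[str, int] = {}
    for m in re.finditer(r"%\d{2}|\d", re.sub(r"\[[^\]]*\]", "", smiles)):
        counts[m.group()] = counts.get(m.group(), 0) + 1
    return any(c % 2 for c in counts.values())


def correct_valence(mol: Chem.Mol) -> tuple[Chem.Mol, list[str]] | ParseFailure:
    """Remediate illegal valences, then sanitize.

    The remediation table converts hypervalent neutral drawings into their
    charge-separated equivalents without touching heavy-atom connectivity:

    1. neutral N with explicit valence > 3 and a double-bonded terminal O
       (nitro ``N(=O)=O``, N-oxides, nitrates): one N=O becomes N(+)-O(-);
    2. cumulated hypervalent azide drawings ``N=N=N`` / ``N(=N)#N``: the
       central nitrogen becomes N(+), the terminal one N(-).

    Anything still illegal afterwards (e.g. five-coordinate carbon) is
    irreparable and reported as a ``failed_parsing`` failure.
    """
    log: list[str] = []
    rw = Chem.RWMol(mol)
    rw.UpdatePropertyCache(strict=False)

    for atom in rw.GetAtoms():
        if atom.GetAtomicNum() != 7 or atom.GetFormalCharge() != 0:
            continue
        # pass 1: hypervalent N with terminal =O neighbours
        # (legal N valence is 3 + positive formal charge)
        while (
            atom.GetExplicitValence() + atom.GetNumImplicitHs()
            > 3 + max(0, atom.GetFormalCharge())
        ):
            target = None
            for nbr in atom.GetNeighbors():
                bond = rw.GetBondBetweenAtoms(atom.GetIdx(), nbr.GetIdx())
                if (
                    nbr.GetAtomicNum() == 8
                    and nbr.GetDegree() == 1
                    and nbr.GetFormalCharge() == 0
                    and bond.GetBondType() == Chem.BondType.DOUBLE
                ):
                    target = (nbr, bond)
                    break
            if target is None:
                break
            nbr, bond = target
            bond.SetBondType(Chem.BondType.SINGLE)
            atom.SetFormalCharge(1)
            nbr.SetFormalCharge(-1)
            rw.UpdatePropertyCache(strict=False)
            log.append(
                f"hypervalent N{atom.GetIdx()}: N=O rewritten as N(+)-O(-)"
            )
        # pass 2: hypervalent central azide nitrogen N=N=N or N(=N)#N
        if (
            atom.GetExplicitValence() + atom.GetNumImplicitHs()
            > 3 + max(0, atom.GetFormalCharge())
        ):
            nnbrs = [
                n
                for n in atom.GetNeighbors()
                if n.GetAtomicNum() == 7 and n.GetFormalCharge() == 0
            ]
            terminal = [n for n in nnbrs if n.GetDegree() == 1]
            if len(nnbrs) == 2 and terminal:
                t = terminal[0]
                bond = rw.GetBondBetweenAtoms(atom.GetIdx(), t.GetIdx())
                if bond.GetBondType() == Chem.BondType.TRIPLE:
                    bond.SetBondType(Chem.BondType.DOUBLE)
                atom.SetFormalCharge(1)
                t.SetFormalCharge(-1)
                rw.UpdatePropertyCache(strict=False)
                log.append(
                    f"hypervalent azide N{atom.GetIdx()}: rewritten charge-separated"
                )

    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception as exc:
        return ParseFailure(f"irreparable valence: {exc}")
    return out, log


def classify_composition(mol: Chem.Mol) -> str:
    """Classify a (single- or multi-fragment) graph by elemental makeup.

    Returns ``"organic"`` (contains carbon, no carbon-metal bond),
    ``"organometallic"`` (at least one covalent carbon-metal bond) or
    ``"inorganic"`` (no carbon at all).
    """
    has_carbon = False
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 6:
            has_carbon = True
            break
    if not has_carbon:
        return "inorganic"
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        nums = {a.GetAtomicNum(), b.GetAtomicNum()}
        if 6 in nums and any(is_metal(n) for n in nums):
            return "organometallic"
    return "organic"


def detect_ambiguous(mol: Chem.Mol) -> bool:
    """True for Markush / query structures that cannot denote one molecule.

    Wildcard atoms (``*``), R-group placeholders from MOL files (parsed by
    RDKit as dummy atoms, atomic number 0) and query atoms/bonds all count.
    """
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0 or atom.HasQuery():
            return True
    for bond in mol.GetBonds():
        if bond.HasQuery():
            return True
    return False


def size_shape_check(mol: Chem.Mol, limits: SizeShapeLimits) -> ReasonTag | None:
    """Apply the molecular-weight / heavy-atom / nano-shape filter.

    Returns ``None`` on pass, :attr:`ReasonTag.size` for weight or heavy-atom
    violations, :attr:`ReasonTag.nano_shape` when the bonds-to-heavy-atoms
    ratio exceeds ``nano_ratio_max``.  All checks are skipped when the filter
    is disabled.
    """
    if not limits.enabled:
        return None
    heavy = mol.GetNumHeavyAtoms()
    if limits.heavy_min is not None and heavy < limits.heavy_min:
        return ReasonTag.size
    if limits.heavy_max is not None and heavy > limits.heavy_max:
        return ReasonTag.size
    mw = Descriptors.MolWt(mol)
    if limits.mw_min is not None and mw < limits.mw_min:
        return ReasonTag.size
    if limits.mw_max is not None and mw > limits.mw_max:
        return ReasonTag.size
    if limits.nano_ratio_max is not None and heavy > 0:
        heavy_bonds = sum(
            1
            for b in mol.GetBonds()
            if b.GetBeginAtom().GetAtomicNum() > 1 and b.GetEndAtom().GetAtomicNum() > 1
        )
        if heavy_bonds / heavy > limits.nano_ratio_max:
            return ReasonTag.nano_shape
    return None
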