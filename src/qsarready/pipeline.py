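"""Pipeline orchestration: from raw records to the QSAR-ready output file set.

Stage order for each record (first failing stage short-circuits with its
reason tag):

  parse -> valence remediation -> ambiguous filter -> fragment split / salt
  stripping / mixture filter -> composition filter -> mesomer/tautomer rules
  -> neutralization -> stereo flattening -> hydrogen virtualization -> ring
  mode -> crossed double bonds -> coordinate sanitization -> size/shape
  filter -> InChI / canonical SMILES

Deduplication (by standard InChI, first occurrence kept) and optional 3D
embedding happen across the whole result set before writing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import yaml
from rdkit import Chem
from rdkit.Chem import AllChem

from . import chem_io, fragments, transforms, validation
from .chem_io import ChemicalRecord
from .fragments import Blocklist, load_blocklist, strip_and_rebalance, StripResult
from .transforms import RuleLibrary, load_rule_file, StandardizationError
from .validation import ParseFailure, ReasonTag, SizeShapeLimits

DEFAULT_3D_SEED = 20809  # fixed for bit-reproducible conformers


@dataclass
class ProcessingOutcome:
    """A record that did not survive standardization."""

    identifier: str
    raw_input: str
    reason: ReasonTag
    log: list[str] = field(default_factory=list)


@dataclass
class QsarReadyResult:
    """A standardized, model-ready structure with its identifiers."""

    identifier: str
    graph: Chem.Mol
    canonical_smiles: str
    inchi: str
    inchikey: str
    original_smiles: str = ""
    salt_solvent: str = ""
    salt_id: str = ""
    stripped_fragments: list[tuple[str, str | None]] = field(default_factory=list)
    stereo_payload: dict = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


@dataclass
class StandardizationConfig:
    """Every user-facing choice, serializable to/from YAML."""

    input_path: str = ""
    input_format: str | None = None  # auto-detected when None
    smiles_column: str | None = None
    id_column: str | None = None
    output_dir: str = "."
    ring_mode: str = "aromatic"  # aromatic | kekule
    dedup: bool = False
    make_3d: bool = False
    seed_3d: int = DEFAULT_3D_SEED
    size_limits: SizeShapeLimits = field(default_factory=SizeShapeLimits)
    rules_path: str | None = None
    blocklist_path: str | None = None
    disable_rules: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str) -> "StandardizationConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        limits = data.pop("size_filter", None)
        cfg = cls(**data)
        if limits:
            cfg.size_limits = SizeShapeLimits(**limits)
        return cfg

    def to_yaml(self, path: str) -> None:
        data = asdict(self)
        data["size_filter"] = data.pop("size_limits")
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def standardize_record(
    record: ChemicalRecord,
    config: StandardizationConfig,
    library: RuleLibrary,
    blocklist: Blocklist,
) -> QsarReadyResult | ProcessingOutcome:
    """Run one record through every per-structure stage.

    Never raises for chemistry problems: every failure becomes a
    :class:`ProcessingOutcome` carrying a reason tag and the per-record log.
    """
    log: list[str] = list(record.parse_messages)

    def discard(reason: ReasonTag) -> ProcessingOutcome:
        return ProcessingOutcome(
            identifier=record.identifier,
            raw_input=record.original_smiles or record.raw_input.strip(),
            reason=reason,
            log=log,
        )

    if record.parse_status == "failed" or record.graph is None:
        return discard(ReasonTag.failed_parsing)

    corrected = validation.correct_valence(record.graph)
    if isinstance(corrected, ParseFailure):
        log.append(corrected.message)
        return discard(ReasonTag.failed_parsing)
    mol, valence_log = corrected
    log.extend(valence_log)

    if validation.detect_ambiguous(mol):
        log.append("query/Markush feature detected")
        return discard(ReasonTag.ambiguous_structure)

    stripped = strip_and_rebalance(mol, blocklist)
    if isinstance(stripped, ReasonTag):
        return discard(stripped)
    assert isinstance(stripped, StripResult)
    log.extend(stripped.charge_ops)
    mol = stripped.parent
    stripped_frags = [
        (Chem.MolToSmiles(f), sid) for f, sid in stripped.stripped
    ]
    for smi, sid in stripped_frags:
        log.append(f"stripped fragment {smi} (blocklist {sid or 'n/a'})")

    composition = validation.classify_composition(mol)
    if composition != "organic":
        log.append(f"composition: {composition}")
        return discard(ReasonTag(composition))

    mol = transforms.standardize_mesomers_tautomers(mol, library, log=log)
    mol = transforms.neutralize(mol, log=log)
    mol, payload = transforms.flatten_stereo(mol)
    if payload["atoms"] or payload["bonds"]:
        log.append(
            f"stereo flattened: {len(payload['atoms'])} centres, "
            f"{len(payload['bonds'])} bonds"
        )
    mol = transforms.virtualize_hydrogens(mol)
    try:
        mol = transforms.set_ring_mode(mol, config.ring_mode)
    except StandardizationError as exc:
        log.append(str(exc))
        return discard(ReasonTag.failed_parsing)
    mol = transforms.fix_crossed_double_bonds(mol)
    mol = transforms.sanitize_coordinates(mol)

    verdict = validation.size_shape_check(mol, config.size_limits)
    if verdict is not None:
        log.append(f"size/shape filter: {verdict}")
        return discard(verdict)

    ident = compute_inchi(mol)
    if ident is None:
        log.append("InChI generation failed")
        return discard(ReasonTag.failed_parsing)
    inchi, inchikey = ident
    smiles = Chem.MolToSmiles(mol, kekuleSmiles=(config.ring_mode == "kekule"))

    salt_smiles = ";".join(smi for smi, sid in stripped_frags if sid)
    salt_ids = ";".join(sid for _, sid in stripped_frags if sid)
    return QsarReadyResult(
        identifier=record.identifier,
        graph=mol,
        canonical_smiles=smiles,
        inchi=inchi,
        inchikey=inchikey,
        original_smiles=record.original_smiles or record.raw_input.strip(),
        salt_solvent=salt_smiles,
        salt_id=salt_ids,
        stripped_fragments=stripped_frags,
        stereo_payload=payload,
        log=log,
    )


def compute_inchi(mol: Chem.Mol) -> tuple[str, str] | None:
    """Standard InChI (no nonstandard options) and its hashed key."""
    if mol.GetNumAtoms() == 0:
        return None
    try:
        inchi = Chem.MolToInchi(mol, treatWarningAsError=False)
    except Exception:
        return None
    if not inchi:
        return None
    key = Chem.InchiToInchiKey(inchi)
    if not key:
        return None
    return inchi, key


def deduplicate(
    results: list[QsarReadyResult], enabled: bool = True
) -> tuple[list[QsarReadyResult], list[ProcessingOutcome]]:
    """Collapse records sharing a standard InChI; first occurrence survives."""
    if not enabled:
        return list(results), []
    seen: dict[str, str] = {}
    unique: list[QsarReadyResult] = []
    dupes: list[ProcessingOutcome] = []
    for res in results:
        keeper = seen.get(res.inchi)
        if keeper is None:
            seen[res.inchi] = res.identifier
            unique.append(res)
        else:
            dupes.append(
                ProcessingOutcome(
                    identifier=res.identifier,
                    raw_input=res.original_smiles,
                    reason=ReasonTag.duplicate,
                    log=res.log + [f"duplicate of {keeper} (same InChI)"],
                )
            )
    return unique, dupes


def embed_3d(
    mol: Chem.Mol, stereo_payload: dict | None = None, seed: int = DEFAULT_3D_SEED
) -> tuple[Chem.Mol, float, float] | None:
    """Generate one optimized 3D conformer with explicit hydrogens.

    Returns (molecule, initial energy, optimized energy) or ``None`` when
    embedding fails, in which case the caller falls back to 2D output.
    The fixed seed makes coordinates bit-reproducible run to run.
    """
    work = Chem.Mol(mol)
    if stereo_payload and (stereo_payload.get("atoms") or stereo_payload.get("bonds")):
        work = transforms.reapply_stereo(work, stereo_payload)
    work = Chem.AddHs(work)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(work, params) != 0:
        return None
    try:
        props = AllChem.MMFFGetMoleculeProperties(work)
        if props is not None:
            ff = AllChem.MMFFGetMoleculeForceField(work, props)
        else:
            ff = AllChem.UFFGetMoleculeForceField(work)
        e0 = ff.CalcEnergy()
        ff.Minimize(maxIts=500)
        e1 = ff.CalcEnergy()
    except Exception:
        return None
    return work, e0, e1


@dataclass
class RunReport:
    n_input: int = 0
    n_standardized: int = 0
    n_discarded: int = 0
    reason_counts: dict[str, int] = field(default_factory=dict)
    rule_applications: dict[str, int] = field(default_factory=dict)
    output_files: dict[str, str] = field(default_factory=dict)


def run(config: StandardizationConfig) -> RunReport:
    """Execute the full workflow and write the five output files.

    Discarded records are an expected outcome, not an error; only missing
    inputs or unusable configuration raise.
    """
    if not config.input_path or not os.path.exists(config.input_path):
        raise FileNotFoundError(f"input file not found: {config.input_path!r}")
    library = load_rule_file(config.rules_path)
    if config.disable_rules:
        library.disable(config.disable_rules)
    blocklist = load_blocklist(config.blocklist_path)

    fmt = config.input_format or chem_io.detect_format(config.input_path)
    if fmt == "unknown":
        raise ValueError(f"cannot determine format of {config.input_path!r}")
    records = chem_io.read_structures(
        config.input_path, fmt, config.smiles_column, config.id_column
    )

    results: list[QsarReadyResult] = []
    outcomes: list[ProcessingOutcome] = []
    for record in records:
        out = standardize_record(record, config, library, blocklist)
        if isinstance(out, QsarReadyResult):
            results.append(out)
        else:
            outcomes.append(out)

    unique, dupes = deduplicate(results, enabled=config.dedup)
    outcomes.extend(dupes)

    dimension = "2D"
    if config.make_3d:
        embedded = []
        for res in unique:
            out3d = embed_3d(res.graph, res.stereo_payload, seed=config.seed_3d)
            if out3d is None:
                res.log.append("3D embedding failed; falling back to 2D")
            else:
                res.graph = out3d[0]
            embedded.append(res)
        unique = embedded
        if all(r.graph.GetNumConformers() and r.graph.GetConformer().Is3D() for r in unique):
            dimension = "3D"

    os.makedirs(config.output_dir, exist_ok=True)
    paths = chem_io.output_paths(config.input_path, config.output_dir)
    chem_io.write_sdf(unique, paths["sdf"], dimension=dimension)
    chem_io.write_smiles(unique, paths["smiles"])
    chem_io.write_summary(unique, paths["summary"])
    chem_io.write_discarded(outcomes, paths["discarded"])
    chem_io.write_salt_map(unique, paths["salts"])

    report = RunReport(
        n_input=len(records),
        n_standardized=len(unique),
        n_discarded=len(outcomes),
        output_files=paths,
    )
    for out in outcomes:
        key = str(out.reason)
        report.reason_counts[key] = report.reason_counts.get(key, 0) + 1
    for res in unique:
        for line in res.log:
            if ": applied" in line:
                rule_id = line.split(":", 1)[0]
                report.rule_applications[rule_id] = (
                    report.rule_applications.get(rule_id, 0) + 1
                )
    return report
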