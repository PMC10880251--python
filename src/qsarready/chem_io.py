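"""Reading structure inputs and writing the five-file output contract.

Supported inputs: SMILES line files (``.smi``), delimited spreadsheets
(``.csv``, with a SMILES column and optional identifier column; ``.xlsx``
supported when openpyxl is installed), single-structure MOL files and
multi-structure SDF files.  Records that fail to parse are kept and reported,
never silently dropped.

Outputs, all named from the input stem: the QSAR-ready SDF (V2000) and SMILES
files, the summary CSV, the discarded-structures CSV, and the stripped
salt/solvent CSV.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

from rdkit import Chem

from .validation import ParseFailure, parse_structure


@dataclass
class ChemicalRecord:
    """One input entry, with the raw text preserved byte-for-byte."""

    identifier: str
    raw_input: str
    source_format: str  # smi | csv | mol | sdf
    graph: Chem.Mol | None = None
    parse_status: str = "ok"  # ok | warning | failed
    parse_messages: list[str] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)
    original_smiles: str = ""


def detect_format(path: str) -> str:
    """Classify an input file: extension first, then content sniffing.

    ``unknown`` is a returned value, never an exception; only an unreadable
    path raises.
    """
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("smi", "smiles"):
        return "smi"
    if ext == "csv":
        return "csv"
    if ext == "mol":
        return "mol"
    if ext == "sdf":
        return "sdf"
    try:
        with open(path, "r", encoding="utf-8", errors="replace") as fh:
            head = fh.read(65536)
    except OSError as exc:
        raise OSError(f"cannot read input file {path!r}: {exc}") from exc
    if "$$$$" in head:
        return "sdf"
    if "M  END" in head:
        return "mol"
    return "unknown"


def _unique_ids(records: list[ChemicalRecord]) -> None:
    seen: dict[str, int] = {}
    for rec in records:
        base = rec.identifier
        if base in seen:
            seen[base] += 1
            rec.identifier = f"{base}_{seen[base]}"
            seen[rec.identifier] = 0
        else:
            seen[base] = 0


def read_structures(
    path: str,
    fmt: str,
    smiles_column: str | None = None,
    id_column: str | None = None,
) -> list[ChemicalRecord]:
    """Read every entry of an input file into ChemicalRecords, in file order.

    Unparseable entries carry ``parse_status="failed"`` and survive into the
    discarded-structures report.  Identifiers are synthesized as ``ROW_<n>``
    when absent and disambiguated with ``_<k>`` suffixes on collision.
    """
    if fmt == "smi":
        records = _read_smi(path)
    elif fmt == "csv":
        records = _read_csv(path, smiles_column, id_column)
    elif fmt == "mol":
        records = _read_mol(path)
    elif fmt == "sdf":
        records = _read_sdf(path)
    else:
        raise ValueError(f"unsupported input format {fmt!r}")
    _unique_ids(records)
    return records


def _make_record(raw: str, identifier: str, fmt: str) -> ChemicalRecord:
    rec = ChemicalRecord(identifier=identifier, raw_input=raw, source_format=fmt)
    parsed = parse_structure(raw, fmt)
    if isinstance(parsed, ParseFailure):
        rec.parse_status = "failed"
        rec.parse_messages.append(parsed.message)
    else:
        rec.graph = parsed
        if fmt in ("mol", "sdf"):
            try:
                rec.original_smiles = Chem.MolToSmiles(Chem.Mol(parsed))
            except Exception:
                rec.original_smiles = ""
        else:
            rec.original_smiles = raw.strip().split()[0] if raw.strip() else ""
    return rec


def _read_smi(path: str) -> list[ChemicalRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        n = 0
        for line in fh:
            if not line.strip():
                continue
            n += 1
            parts = line.strip().split(None, 1)
            smiles = parts[0]
            ident = parts[1].strip() if len(parts) > 1 else f"ROW_{n}"
            records.append(_make_record(smiles, ident, "smi"))
    return records


def _read_csv(
    path: str, smiles_column: str | None, id_column: str | None
) -> list[ChemicalRecord]:
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        columns = reader.fieldnames or []
        if smiles_column is None or smiles_column not in columns:
            raise ValueError(
                f"CSV input needs a SMILES column; got {smiles_column!r}, "
                f"available columns: {columns}"
            )
        if id_column is not None and id_column not in columns:
            raise ValueError(
                f"identifier column {id_column!r} not found; available: {columns}"
            )
        records = []
        for n, row in enumerate(reader, start=1):
            smiles = (row.get(smiles_column) or "").strip()
            ident = (row.get(id_column) or "").strip() if id_column else ""
            rec = _make_record(smiles, ident or f"ROW_{n}", "csv")
            rec.metadata = {k: (v or "") for k, v in row.items()}
            records.append(rec)
    return records


def _read_mol(path: str) -> list[ChemicalRecord]:
    with open(path, encoding="utf-8") as fh:
        block = fh.read()
    if not block.strip():
        return []
    name = block.splitlines()[0].strip() if block.splitlines() else ""
    return [_make_record(block, name or "ROW_1", "mol")]


def _read_sdf(path: str) -> list[ChemicalRecord]:
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    records = []
    n = 0
    for chunk in text.split("$$$$"):
        if not chunk.strip():
            continue
        n += 1
        block = chunk.lstrip("\n") + ("\n" if not chunk.endswith("\n") else "")
        lines = block.splitlines()
        name = lines[0].strip() if lines else ""
        rec = _make_record(block, name or f"ROW_{n}", "sdf")
        rec.metadata = _sdf_data_fields(block)
        if not name and rec.metadata.get("ID", "").strip():
            rec.identifier = rec.metadata["ID"].strip()
        records.append(rec)
    return records


def _sdf_data_fields(block: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    lines = block.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith(">") and "<" in line and ">" in line[1:]:
            key = line[line.index("<") + 1 : line.rindex(">")]
            vals = []
            i += 1
            while i < len(lines) and lines[i].strip():
                vals.append(lines[i])
                i += 1
            fields[key] = "\n".join(vals)
        i += 1
    return fields


# ---------------------------------------------------------------------------
# writers


def write_sdf(results, path: str, dimension: str = "2D") -> None:
    """Write QSAR-ready results as a V2000 SDF.

    The identifier goes on the molecule name line and into an ``<ID>`` data
    field.  For 3D output every result must already carry 3D coordinates.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for res in results:
            mol = res.graph
            if dimension == "3D":
                if mol.GetNumConformers() == 0 or not mol.GetConformer().Is3D():
                    raise ValueError(
                        f"3D SDF requested but record {res.identifier!r} "
                        "has no 3D coordinates"
                    )
            mol.SetProp("_Name", res.identifier)
            block = Chem.MolToMolBlock(mol, kekulize=True)
            fh.write(block)
            fh.write(f">  <ID>\n{res.identifier}\n\n$$$$\n")


def write_smiles(results, path: str) -> None:
    """One line per result: ``<canonical SMILES>\\t<identifier>``."""
    with open(path, "w", encoding="utf-8") as fh:
        for res in results:
            fh.write(f"{res.canonical_smiles}\t{res.identifier}\n")


SUMMARY_COLUMNS = [
    "ID",
    "Original_SMILES",
    "Canonical_QSARr",
    "InChI",
    "InChIKey",
    "Salt_Solvent",
    "Salt_Solvent_ID",
]


def write_summary(results, path: str) -> None:
    """Summary CSV: one row per successfully standardized record."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SUMMARY_COLUMNS)
        for res in results:
            writer.writerow(
                [
                    res.identifier,
                    res.original_smiles,
                    res.canonical_smiles,
                    res.inchi,
                    res.inchikey,
                    res.salt_solvent,
                    res.salt_id,
                ]
            )


def write_discarded(outcomes, path: str) -> None:
    """Discarded-structures CSV with the controlled reason vocabulary."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ID", "Original_Structure", "Reason"])
        for out in outcomes:
            writer.writerow([out.identifier, out.raw_input, str(out.reason)])


def write_salt_map(results, path: str) -> None:
    """Stripped salt/solvent CSV; only records that lost fragments appear."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ID", "Salt_Solvent_SMILES", "Salt_Solvent_ID"])
        for res in results:
            for smi, sid in res.stripped_fragments:
                if sid:
                    writer.writerow([res.identifier, smi, sid])


def output_paths(input_path: str, out_dir: str) -> dict[str, str]:
    """The five output file paths derived from the input file stem."""
    stem = os.path.splitext(os.path.basename(input_path))[0]
    return {
        "sdf": os.path.join(out_dir, f"{stem}_QSAR-ready.sdf"),
        "smiles": os.path.join(out_dir, f"{stem}_QSAR-ready_smi.smi"),
        "summary": os.path.join(out_dir, f"{stem}_Summary_file.csv"),
        "discarded": os.path.join(out_dir, f"{stem}_DiscardedStructures.csv"),
        "salts": os.path.join(out_dir, f"{stem}_StrippedSalts.csv"),
    }
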