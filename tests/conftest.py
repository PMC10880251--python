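"""Shared fixtures for the qsarready test suite."""

from __future__ import annotations

import pytest

from qsarready import load_blocklist, load_rule_file
from qsarready.fixtures import fixture_corpus, write_corpus
from qsarready.pipeline import StandardizationConfig, standardize_record
from qsarready.chem_io import ChemicalRecord
from qsarready.validation import parse_structure, ParseFailure


@pytest.fixture(scope="session")
def library():
    return load_rule_file()


@pytest.fixture(scope="session")
def blocklist():
    return load_blocklist()


@pytest.fixture(scope="session")
def corpus():
    return fixture_corpus()


@pytest.fixture()
def config():
    return StandardizationConfig()


@pytest.fixture(scope="session")
def corpus_files(tmp_path_factory):
    out = tmp_path_factory.mktemp("corpus")
    smi_path, csv_path = write_corpus(str(out))
    return smi_path, csv_path


def make_record(smiles: str, identifier: str = "x") -> ChemicalRecord:
    """Build a ChemicalRecord from a SMILES string the way the readers do."""
    rec = ChemicalRecord(
        identifier=identifier, raw_input=smiles, source_format="smi"
    )
    parsed = parse_structure(smiles, "smi")
    if isinstance(parsed, ParseFailure):
        rec.parse_status = "failed"
        rec.parse_messages.append(parsed.message)
    else:
        rec.graph = parsed
        rec.original_smiles = smiles
    return rec


@pytest.fixture()
def standardize(library, blocklist, config):
    """Callable running one SMILES through the per-record pipeline."""

    def _run(smiles: str, cfg=None):
        return standardize_record(
            make_record(smiles), cfg or config, library, blocklist
        )

    return _run
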