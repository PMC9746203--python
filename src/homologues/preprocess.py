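"""Input reading and structure sanitisation.

The classifier consumes a plain CSV table with (at least) a SMILES column
and a name column.  Every row is parsed with RDKit and sanitised; rows whose
SMILES cannot be turned into a sanitised molecule are discarded with an
audit trail rather than aborting the run, so a single malformed database
entry never kills a batch classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import pandas as pd
from rdkit import Chem, rdBase

from .errors import ConfigurationError

logger = logging.getLogger(__name__)


class DiscardReason(Enum):
    NONE = "none"
    UNPARSEABLE = "unparseable"
    SANITISATION_FAILED = "sanitisation_failed"


@dataclass
class MoleculeRecord:
    """One input row.

    ``raw_smiles`` is preserved verbatim for output; ``structure`` is the
    sanitised RDKit molecule and is present exactly when ``discard_reason``
    is :attr:`DiscardReason.NONE`.
    """

    raw_smiles: str
    name: str
    structure: Optional[Chem.Mol] = None
    discard_reason: DiscardReason = DiscardReason.NONE

    @property
    def is_valid(self) -> bool:
        return self.discard_reason is DiscardReason.NONE


@dataclass
class PreprocessReport:
    n_input: int
    n_valid: int
    n_discarded: int
    discarded_names: list[str] = field(default_factory=list)


def read_input_table(
    path: str | Path,
    smiles_column: str = "SMILES",
    name_column: str = "Name",
) -> list[MoleculeRecord]:
    """Read the input CSV into records, in file order.

    Only the two named columns are used; any additional columns are ignored.
    The file must be comma-separated UTF-8 with a header row.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ConfigurationError
        If the file is empty, has no data rows, or lacks a named column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise ConfigurationError(f"input file is empty: {path}") from None
    for column in (smiles_column, name_column):
        if column not in df.columns:
            raise ConfigurationError(
                f"column {column!r} not found in {path} "
                f"(available: {', '.join(df.columns)})"
            )
    if len(df) == 0:
        raise ConfigurationError(f"input file has a header but no data rows: {path}")
    return [
        MoleculeRecord(raw_smiles=smiles, name=name)
        for smiles, name in zip(df[smiles_column], df[name_column])
    ]


def _sanitised_mol(smiles: str) -> tuple[Optional[Chem.Mol], DiscardReason]:
    """Parse and sanitise one SMILES, mapping failures to a discard reason."""
    if not smiles or not smiles.strip():
        return None, DiscardReason.UNPARSEABLE
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        return None, DiscardReason.UNPARSEABLE
    try:
        Chem.SanitizeMol(mol)
        # normalise any explicit hydrogens in the input to implicit ones so
        # that SMARTS H-count primitives see consistent totals downstream
        mol = Chem.RemoveHs(mol)
    except Exception:
        return None, DiscardReason.SANITISATION_FAILED
    return mol, DiscardReason.NONE


def parse_and_sanitise(
    records: list[MoleculeRecord],
) -> tuple[list[MoleculeRecord], PreprocessReport]:
    """Sanitise all records; return the valid ones plus a discard report.

    Failures never raise per record: a molecule that cannot be parsed or
    sanitised is flagged with its reason, logged at WARN level, and excluded
    from the returned valid list.  Input order is preserved.
    """
    valid: list[MoleculeRecord] = []
    discarded_names: list[str] = []
    with rdBase.BlockLogs():
        for record in records:
            mol, reason = _sanitised_mol(record.raw_smiles)
            record.structure = mol
            record.discard_reason = reason
            if reason is DiscardReason.NONE:
                valid.append(record)
            else:
                discarded_names.append(record.name)
                logger.warning(
                    "discarding %r (%s): %r",
                    record.name,
                    reason.value,
                    record.raw_smiles,
                )
    report = PreprocessReport(
        n_input=len(records),
        n_valid=len(valid),
        n_discarded=len(discarded_names),
        discarded_names=discarded_names,
    )
    if records and not valid:
        logger.warning("all %d input records were discarded", len(records))
    return valid, report
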