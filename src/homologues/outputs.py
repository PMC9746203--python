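"""Writers for the per-molecule CSV and the run-summary TXT."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import pandas as pd

from .classify import ClassificationSummary, SeriesAssignment
from .preprocess import MoleculeRecord

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for type checkers
    from .pipeline import RunConfig

logger = logging.getLogger(__name__)

SUMMARY_FILENAME = "classification-results.txt"


def write_series_csv(
    assignments: Sequence[SeriesAssignment],
    records: Sequence[MoleculeRecord],
    path: str | Path,
) -> Path:
    """Write the classification CSV: columns SMILES, Name, series_no.

    One row per sanitised input molecule, in input order.  The SMILES column
    echoes the input representation verbatim — it is never canonicalised, so
    user-facing identifiers round-trip.
    """
    if len(assignments) != len(records):
        raise ValueError(
            f"{len(assignments)} assignments for {len(records)} records"
        )
    if not records:
        logger.warning("no sanitised molecules: writing header-only CSV")
    path = Path(path)
    frame = pd.DataFrame(
        {
            "SMILES": [r.raw_smiles for r in records],
            "Name": [r.name for r in records],
            "series_no": [a.series_no for a in assignments],
        }
    )
    frame.to_csv(path, index=False)
    return path


def write_summary_txt(
    summary: ClassificationSummary,
    config: "RunConfig",
    path: str | Path,
) -> Path:
    """Write the human-readable run summary (classification-results.txt)."""
    path = Path(path)
    lines = [
        "Homologous series classification results",
        "========================================",
        "",
        f"No. of molecules in input:                       {summary.n_input}",
        f"No. of homologous series detected:               {summary.n_series}",
        f"No. of molecules classified as series members:   {summary.n_in_series}",
        f"No. of molecules consisting purely of repeating units: {summary.n_pure_ru}",
        f"No. of molecules with repeating units but unique cores: {summary.n_unique_core}",
        f"No. of molecules not containing repeating unit chains: {summary.n_no_match}",
        f"No. of molecules discarded (failed sanitisation): {summary.n_discarded}",
        "",
        "Run configuration",
        "-----------------",
        f"input:                 {config.input_path}",
        f"SMILES column:         {config.smiles_column}",
        f"name column:           {config.name_column}",
        f"repeating unit SMARTS: {config.ru_smarts}",
        f"min chain length:      {config.min_len}",
        f"max chain length:      {config.max_len}",
        f"fragmentation steps:   {config.n_steps}",
        "",
    ]
    path.write_text("\n".join(lines), encoding="utf-8")
    return path
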