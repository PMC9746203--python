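"""End-to-end classification pipeline.

read CSV -> sanitise -> validate repeating unit -> per-molecule core
detection -> series grouping -> CSV + TXT outputs.  Single-threaded and
fully deterministic: identical input and configuration give byte-identical
output files.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .classify import ClassificationSummary, SeriesAssignment, assign_series
from .core import CoreResult, detect_core
from .errors import ConfigurationError
from .outputs import SUMMARY_FILENAME, write_series_csv, write_summary_txt
from .preprocess import (
    MoleculeRecord,
    PreprocessReport,
    parse_and_sanitise,
    read_input_table,
)
from .repeating_unit import (
    DEFAULT_MAX_LEN,
    DEFAULT_MIN_LEN,
    DEFAULT_N_STEPS,
    DEFAULT_RU_SMARTS,
    validate_repeating_unit,
)

logger = logging.getLogger(__name__)

CSV_FILENAME = "classified-series.csv"


@dataclass
class RunConfig:
    """Configuration for one classification run."""

    input_path: str | Path
    smiles_column: str = "SMILES"
    name_column: str = "Name"
    ru_smarts: str = DEFAULT_RU_SMARTS
    min_len: int = DEFAULT_MIN_LEN
    max_len: int = DEFAULT_MAX_LEN
    n_steps: int = DEFAULT_N_STEPS
    output_dir: str | Path = "."

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ConfigurationError(
                f"minimum chain length must be >= 1, got {self.min_len}"
            )
        if self.min_len > self.max_len:
            raise ConfigurationError(
                f"minimum chain length {self.min_len} exceeds maximum {self.max_len}"
            )
        if self.n_steps < 1:
            raise ConfigurationError(
                f"number of fragmentation steps must be >= 1, got {self.n_steps}"
            )


@dataclass
class RunResult:
    records: list[MoleculeRecord]
    report: PreprocessReport
    core_results: list[CoreResult]
    assignments: list[SeriesAssignment]
    summary: ClassificationSummary
    csv_path: Optional[Path] = None
    txt_path: Optional[Path] = None
    elapsed_seconds: float = field(default=0.0)


def run(config: RunConfig, write_outputs: bool = True) -> RunResult:
    """Execute the full pipeline for one configuration."""
    start = time.perf_counter()
    ru = validate_repeating_unit(config.ru_smarts)

    records = read_input_table(
        config.input_path, config.smiles_column, config.name_column
    )
    valid, report = parse_and_sanitise(records)
    logger.info(
        "read %d records, %d sanitised, %d discarded",
        report.n_input,
        report.n_valid,
        report.n_discarded,
    )

    core_results = [
        detect_core(rec.structure, ru, config.min_len, config.max_len, config.n_steps)
        for rec in valid
    ]
    assignments, summary = assign_series(core_results, n_discarded=report.n_discarded)
    logger.info(
        "detected %d homologous series (%d members, %d unique cores, "
        "%d without repeating units, %d purely repeating units)",
        summary.n_series,
        summary.n_in_series,
        summary.n_unique_core,
        summary.n_no_match,
        summary.n_pure_ru,
    )

    result = RunResult(
        records=valid,
        report=report,
        core_results=core_results,
        assignments=assignments,
        summary=summary,
    )
    if write_outputs:
        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.csv_path = write_series_csv(assignments, valid, out_dir / CSV_FILENAME)
        result.txt_path = write_summary_txt(
            summary, config, out_dir / SUMMARY_FILENAME
        )
    result.elapsed_seconds = time.perf_counter() - start
    logger.info("classification finished in %.2f s", result.elapsed_seconds)
    return result
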