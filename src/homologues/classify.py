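"""Grouping of per-molecule cores into homologous series.

Two molecules belong to the same series exactly when their cores — the
canonical SMILES of everything left after chain removal — are string-equal.
The encoding of the per-molecule ``series_no`` label:

=========  ===========================================================
series_no  meaning
=========  ===========================================================
0…N        member of a homologous series (core shared by >= 2 molecules)
-1         no repeating-unit chain of the minimum length present
-2         molecule consists purely of repeating units
-3         chain present, but the core is unique in the dataset
=========  ===========================================================

Series are numbered by order of first appearance in the input, which makes
output stable and diffable; the partition itself is independent of input
order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .core import CoreResult, CoreStatus

SERIES_NO_MATCH = -1
SERIES_PURE_RU = -2
SERIES_UNIQUE_CORE = -3


@dataclass(frozen=True)
class SeriesAssignment:
    record_index: int
    series_no: int


@dataclass(frozen=True)
class ClassificationSummary:
    n_series: int
    n_in_series: int
    n_pure_ru: int
    n_unique_core: int
    n_no_match: int
    n_discarded: int

    @property
    def n_input(self) -> int:
        return (
            self.n_in_series
            + self.n_pure_ru
            + self.n_unique_core
            + self.n_no_match
            + self.n_discarded
        )


def assign_series(
    results: Sequence[CoreResult], n_discarded: int = 0
) -> tuple[list[SeriesAssignment], ClassificationSummary]:
    """Assign a series_no to every core result, plus dataset-level counts.

    ``results`` must be one CoreResult per surviving (sanitised) record, in
    input order; ``n_discarded`` feeds through to the summary so its counts
    add up to the original input size.
    """
    core_counts = Counter(
        r.core_canonical for r in results if r.status is CoreStatus.CORE
    )
    series_ids: dict[str, int] = {}
    assignments: list[SeriesAssignment] = []
    n_in_series = n_pure_ru = n_unique = n_no_match = 0

    for index, result in enumerate(results):
        if result.status is CoreStatus.NO_MATCH:
            series_no = SERIES_NO_MATCH
            n_no_match += 1
        elif result.status is CoreStatus.PURE_RU:
            series_no = SERIES_PURE_RU
            n_pure_ru += 1
        elif core_counts[result.core_canonical] == 1:
            series_no = SERIES_UNIQUE_CORE
            n_unique += 1
        else:
            if result.core_canonical not in series_ids:
                series_ids[result.core_canonical] = len(series_ids)
            series_no = series_ids[result.core_canonical]
            n_in_series += 1
        assignments.append(SeriesAssignment(record_index=index, series_no=series_no))

    summary = ClassificationSummary(
        n_series=len(series_ids),
        n_in_series=n_in_series,
        n_pure_ru=n_pure_ru,
        n_unique_core=n_unique,
        n_no_match=n_no_match,
        n_discarded=n_discarded,
    )
    return assignments, summary
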