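"""Repeating-unit validation and chain-query enumeration.

A homologous series is defined relative to a repeating unit given as a
SMARTS pattern whose first and last atoms have open valences, e.g.
``[#6&H2]`` for an alkyl (CH2) unit or ``[#6](-[#9])(-[#9])`` for a
perfluoroalkyl (CF2) unit.  Chains of n units are built by joining n copies
of the unit with explicit single bonds; the enumeration runs from the
configured maximum length down to the minimum so that the first matching
query is always the longest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from rdkit import Chem

from .errors import ConfigurationError, SmartsValidationError

#: Default alkyl (CH2) repeating unit.
DEFAULT_RU_SMARTS = "[#6&H2]"
#: Default chain-length bounds and fragmentation-step count.
DEFAULT_MIN_LEN = 3
DEFAULT_MAX_LEN = 30
DEFAULT_N_STEPS = 2


@dataclass(frozen=True)
class RepeatingUnit:
    """A validated repeating-unit pattern.

    ``atoms_per_unit`` is the number of atom expressions in the SMARTS, used
    for atom-count bookkeeping when chains are removed.
    """

    smarts: str
    atoms_per_unit: int


@dataclass(frozen=True)
class ChainQuery:
    """A compiled query for a chain of ``length_units`` repeating units."""

    length_units: int
    smarts: str
    query: Chem.Mol = field(compare=False, repr=False)


def chain_smarts(unit_smarts: str, n: int) -> str:
    """SMARTS for ``n`` copies of the unit joined by explicit single bonds."""
    return "-".join([unit_smarts] * n)


@lru_cache(maxsize=4096)
def _compile(smarts: str) -> Chem.Mol:
    query = Chem.MolFromSmarts(smarts)
    if query is None:
        raise SmartsValidationError(f"unparseable SMARTS: {smarts!r}")
    return query


def validate_repeating_unit(smarts: str) -> RepeatingUnit:
    """Validate a repeating-unit SMARTS and count its atoms.

    The pattern must parse on its own, must not contain recursive SMARTS
    (behaviour of recursive environments under concatenation is undefined),
    and two copies joined by a single bond must also parse — the proxy for
    the requirement that both terminal atoms have open valences so chains
    can be grown by concatenation.
    """
    if not smarts or not smarts.strip():
        raise SmartsValidationError("repeating-unit SMARTS must be non-empty")
    if "$(" in smarts:
        raise SmartsValidationError(
            f"recursive SMARTS are not supported in repeating units: {smarts!r}"
        )
    unit = Chem.MolFromSmarts(smarts)
    if unit is None:
        raise SmartsValidationError(f"unparseable repeating-unit SMARTS: {smarts!r}")
    if Chem.MolFromSmarts(chain_smarts(smarts, 2)) is None:
        raise SmartsValidationError(
            f"two concatenated copies of {smarts!r} do not parse; the first "
            "and last atoms of the repeating unit must have open valences"
        )
    return RepeatingUnit(smarts=smarts, atoms_per_unit=unit.GetNumAtoms())


def enumerate_chain_queries(
    ru: RepeatingUnit,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[ChainQuery]:
    """Compile chain queries for every length in [min_len, max_len].

    The result is ordered by descending length: longest-match-first search
    over this list is how a single fragmentation step picks the chain it
    removes.  Compiled patterns are cached across calls.
    """
    if min_len < 1:
        raise ConfigurationError(f"minimum chain length must be >= 1, got {min_len}")
    if min_len > max_len:
        raise ConfigurationError(
            f"minimum chain length {min_len} exceeds maximum {max_len}"
        )
    queries = []
    for n in range(max_len, min_len - 1, -1):
        smarts = chain_smarts(ru.smarts, n)
        queries.append(ChainQuery(length_units=n, smarts=smarts, query=_compile(smarts)))
    return queries
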