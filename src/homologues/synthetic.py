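"""Synthetic homologous-series datasets with known ground truth.

Series are built the way the chemistry defines them: a fixed core with one
or two attachment points, a repeating unit spliced in k times, and a
terminal cap.  Because the intended chain is an unbranched run and the
distractor pool contains no repeating-unit-bearing structures, the true
partition of a generated dataset is known exactly, which makes the whole
pipeline testable end to end without any external data.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from rdkit import Chem, rdBase

from .errors import HomologueError

ATTACHMENT = "[*]"

ChainLength = Union[int, tuple[int, ...]]


class GenerationError(HomologueError):
    """A series specification could not be realised as valid molecules."""


@dataclass(frozen=True)
class SeriesSpec:
    """Recipe for one synthetic homologous series.

    ``core_template`` is a SMILES fragment containing one or two ``[*]``
    attachment markers.  For each entry of ``chain_lengths`` one molecule is
    generated; an integer k splices a chain of k repeating units (plus the
    cap) at every attachment, while a tuple gives per-attachment lengths.
    """

    core_template: str
    ru_fragment: str = "C"
    chain_lengths: tuple[ChainLength, ...] = (3, 4, 5)
    cap: str = "C"
    name: str = "series"
    n_distractors: int = 0
    seed: int = 0


#: Repeating-unit-free molecules used as negative controls.  None of them
#: contains an aliphatic CH2 (nor any other common repeating unit), so under
#: the default alkyl unit they must all be classified as "no match".
DISTRACTOR_POOL: tuple[str, ...] = (
    "c1ccccc1",                # benzene
    "Cc1ccccc1",               # toluene
    "Cc1ccc(C)cc1",            # p-xylene
    "Cc1cc(C)cc(C)c1",         # mesitylene
    "c1ccncc1",                # pyridine
    "c1cnccn1",                # pyrazine
    "c1ccc2ccccc2c1",          # naphthalene
    "c1ccc2[nH]ccc2c1",        # indole
    "c1ccoc1",                 # furan
    "c1ccsc1",                 # thiophene
    "c1cc[nH]c1",              # pyrrole
    "c1cnc[nH]1",              # imidazole
    "Oc1ccccc1",               # phenol
    "Nc1ccccc1",               # aniline
    "COc1ccccc1",              # anisole
    "O=Cc1ccccc1",             # benzaldehyde
    "CC(=O)c1ccccc1",          # acetophenone
    "OC(=O)c1ccccc1",          # benzoic acid
    "N#Cc1ccccc1",             # benzonitrile
    "Clc1ccccc1",              # chlorobenzene
    "Fc1ccccc1",               # fluorobenzene
    "Brc1ccccc1",              # bromobenzene
    "O=[N+]([O-])c1ccccc1",    # nitrobenzene
    "c1ccc2ncccc2c1",          # quinoline
    "CC(C)C",                  # isobutane
    "CC(C)(C)C",               # neopentane
    "CC(C)C(C)C",              # 2,3-dimethylbutane
    "CC(C)=O",                 # acetone
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",  # caffeine
    "CC(C)(C)c1ccccc1",        # tert-butylbenzene
)

#: Single-attachment core templates with pairwise-distinct cores, used to
#: build benchmark datasets of many parallel series.
CORE_TEMPLATES: tuple[str, ...] = (
    "[*]Oc1ccccc1",
    "[*]Oc1ccc(F)cc1",
    "[*]Oc1ccc(Cl)cc1",
    "[*]Oc1ccc(Br)cc1",
    "[*]Oc1ccc(C)cc1",
    "[*]c1ccccc1",
    "[*]c1ccc(F)cc1",
    "[*]c1ccc(Cl)cc1",
    "[*]c1ccc(C)cc1",
    "[*]C(=O)c1ccccc1",
    "[*]C(=O)Oc1ccccc1",
    "[*]N(C)C",
    "[*]c1ccccn1",
    "[*]n1ccnc1",
    "[*]c1cccs1",
    "[*]c1ccco1",
    "[*]C#N",
    "[*]Br",
    "[*]Cl",
    "[*]I",
    "[*]O",
    "[*]N",
    "[*]S",
    "[*]C(C)=O",
)


def _splice(template: str, ru_fragment: str, cap: str, lengths: Sequence[int]) -> str:
    smiles = template
    for k in lengths:
        if k < 1:
            raise GenerationError(f"chain lengths must be >= 1, got {k}")
        smiles = smiles.replace(ATTACHMENT, ru_fragment * k + cap, 1)
    return smiles


def generate_homologues(spec: SeriesSpec) -> list[tuple[str, str]]:
    """Realise one series spec as a list of (smiles, name) pairs.

    Names encode the series name and the chain length(s), e.g.
    ``phenylether_n4``.  Every generated SMILES is checked to parse and
    sanitise; a template or repeating-unit fragment that cannot be realised
    raises :class:`GenerationError`.
    """
    n_attach = spec.core_template.count(ATTACHMENT)
    if n_attach not in (1, 2):
        raise GenerationError(
            f"core template must contain one or two {ATTACHMENT} markers, "
            f"found {n_attach}: {spec.core_template!r}"
        )
    if not spec.chain_lengths:
        raise GenerationError("chain_lengths must be non-empty")

    molecules: list[tuple[str, str]] = []
    for entry in spec.chain_lengths:
        lengths = (entry,) * n_attach if isinstance(entry, int) else tuple(entry)
        if len(lengths) != n_attach:
            raise GenerationError(
                f"chain-length entry {entry!r} does not fit a core with "
                f"{n_attach} attachment(s)"
            )
        smiles = _splice(spec.core_template, spec.ru_fragment, spec.cap, lengths)
        with rdBase.BlockLogs():
            parsed = Chem.MolFromSmiles(smiles)
        if parsed is None:
            raise GenerationError(
                f"spliced SMILES does not parse: {smiles!r} "
                f"(template {spec.core_template!r}, ru {spec.ru_fragment!r})"
            )
        label = "_".join(str(k) for k in lengths)
        molecules.append((smiles, f"{spec.name}_n{label}"))
    return molecules


def generate_mixed_dataset(
    specs: Sequence[SeriesSpec],
    seed: int = 0,
    n_distractors: Optional[int] = None,
) -> list[tuple[str, str]]:
    """Shuffled union of all series members plus distractor molecules.

    ``n_distractors`` defaults to the sum of the specs' own counts.
    Distractors are drawn (with replacement) from :data:`DISTRACTOR_POOL`
    and named ``distractor_<i>``.  Deterministic for a given seed.
    """
    if not specs:
        raise GenerationError("at least one series spec is required")
    rows: list[tuple[str, str]] = []
    for spec in specs:
        rows.extend(generate_homologues(spec))
    if n_distractors is None:
        n_distractors = sum(spec.n_distractors for spec in specs)
    rng = random.Random(seed)
    for i in range(n_distractors):
        rows.append((rng.choice(DISTRACTOR_POOL), f"distractor_{i}"))
    rng.shuffle(rows)
    return rows


def benchmark_dataset(
    n_series: int = 20,
    n_members: int = 4,
    n_distractors: int = 50,
    first_length: int = 3,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict[str, Optional[str]]]:
    """A standard ground-truth benchmark: many parallel CH2 series.

    Builds ``n_series`` single-chain series from :data:`CORE_TEMPLATES`
    (chain lengths ``first_length … first_length + n_members - 1``) plus
    ``n_distractors`` repeating-unit-free molecules.  Returns the shuffled
    (smiles, name) rows and the true partition: a mapping from molecule name
    to its series name, or None for distractors.
    """
    if n_series > len(CORE_TEMPLATES):
        raise GenerationError(
            f"at most {len(CORE_TEMPLATES)} benchmark series available, "
            f"requested {n_series}"
        )
    specs = [
        SeriesSpec(
            core_template=CORE_TEMPLATES[i],
            chain_lengths=tuple(range(first_length, first_length + n_members)),
            name=f"series{i:02d}",
        )
        for i in range(n_series)
    ]
    rows = generate_mixed_dataset(specs, seed=seed, n_distractors=n_distractors)
    truth: dict[str, Optional[str]] = {}
    for spec in specs:
        for _, name in generate_homologues(spec):
            truth[name] = spec.name
    for _, name in rows:
        if name.startswith("distractor_"):
            truth[name] = None
    return rows, truth
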