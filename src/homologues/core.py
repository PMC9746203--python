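"""Core detection by iterative removal of the longest repeating-unit chain.

For one molecule the procedure is: (1) decide whether any chain of at least
the minimum length is present at all; (2) for a fixed number of
fragmentation steps, locate the single longest matching chain and delete
exactly that one match, capping every broken bond with a hydrogen on the
surviving atom; (3) whatever remains — one fragment or several disconnected
ones — is the core, compared across molecules as one canonical SMILES
string.  Removing only one chain per step, even in symmetric molecules with
several equivalent longest matches, is essential: simultaneous removal of
all matches yields different cores for homologues of different chain counts
and breaks the series grouping.

Stereochemistry at a fragmentation site is neutralised (the cap is a plain
hydrogen); stereocentres and double-bond stereo away from the cut survive
and therefore distinguish cores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from rdkit import Chem

from .repeating_unit import (
    DEFAULT_MAX_LEN,
    DEFAULT_MIN_LEN,
    DEFAULT_N_STEPS,
    ChainQuery,
    RepeatingUnit,
    enumerate_chain_queries,
)


class CoreStatus(Enum):
    CORE = "core"
    PURE_RU = "pure_repeating_unit"
    NO_MATCH = "no_match"


@dataclass
class CoreResult:
    """Outcome of core detection for one molecule.

    ``core_canonical`` is the canonical SMILES of all remaining fragments in
    one dot-disconnected string (present iff status is CORE);
    ``removed_chain_lengths`` records, per fragmentation step, how many
    repeating units the removed chain contained.
    """

    status: CoreStatus
    core_canonical: Optional[str] = None
    n_fragments: int = 0
    removed_chain_lengths: list[int] = field(default_factory=list)


def _canonical_order(mol: Chem.Mol) -> Chem.Mol:
    """Renumber atoms into canonical rank order.

    Substructure match enumeration in RDKit depends on atom numbering;
    renumbering canonically before each search makes the chosen match — and
    hence the whole fragmentation trajectory — independent of how the input
    SMILES happened to be written.
    """
    if mol.GetNumAtoms() == 0:
        return mol
    ranks = list(Chem.CanonicalRankAtoms(mol, includeChirality=True))
    order = sorted(range(mol.GetNumAtoms()), key=ranks.__getitem__)
    return Chem.RenumberAtoms(mol, order)


def has_min_chain(mol: Chem.Mol, queries: Sequence[ChainQuery]) -> bool:
    """True iff any enumerated chain query matches as a substructure.

    By containment, a chain of length n+1 always contains one of length n,
    so this is decided by the shortest query; all queries are still honoured
    so the answer holds for any query list.
    """
    return any(mol.HasSubstructMatch(q.query) for q in reversed(queries))


def find_longest_chain(
    mol: Chem.Mol, queries: Sequence[ChainQuery]
) -> Optional[tuple[tuple[int, ...], int]]:
    """First (longest) matching chain query, as (matched atom indices, length).

    ``queries`` must be in descending length order.  A single match is
    returned even when several symmetric equivalents exist; matched atoms
    are pairwise distinct, so a unit is never reused within one chain.
    """
    for q in queries:
        match = mol.GetSubstructMatch(q.query)
        if match:
            return match, q.length_units
    return None


def remove_single_chain(mol: Chem.Mol, match: Sequence[int]) -> Chem.Mol:
    """Delete one matched chain, hydrogen-capping every broken bond.

    Every bond from a matched atom to an unmatched atom is replaced by one
    additional hydrogen on the surviving atom.  Stereo descriptors on capped
    atoms and on bonds touching them are cleared (a hydrogen cap carries no
    stereo information); the remainder is re-sanitised.  The result may be
    empty or contain several disconnected fragments.
    """
    n_atoms = mol.GetNumAtoms()
    match_set = set(match)
    if any(idx < 0 or idx >= n_atoms for idx in match_set):
        raise ValueError(f"match atom indices {sorted(match_set)} out of range")

    caps: dict[int, int] = {}
    for idx in match_set:
        for nbr in mol.GetAtomWithIdx(idx).GetNeighbors():
            j = nbr.GetIdx()
            if j not in match_set:
                caps[j] = caps.get(j, 0) + 1

    rw = Chem.RWMol(mol)
    for j, n_caps in caps.items():
        atom = rw.GetAtomWithIdx(j)
        atom.SetNumExplicitHs(atom.GetTotalNumHs() + n_caps)
        atom.SetNoImplicit(True)
        atom.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
    for j in caps:
        for bond in rw.GetAtomWithIdx(j).GetBonds():
            bond.SetStereo(Chem.BondStereo.STEREONONE)
            bond.SetBondDir(Chem.BondDir.NONE)
    for idx in sorted(match_set, reverse=True):
        rw.RemoveAtom(idx)

    remainder = rw.GetMol()
    if remainder.GetNumAtoms():
        Chem.SanitizeMol(remainder)
        Chem.AssignStereochemistry(remainder, cleanIt=True, force=True)
    return remainder


def detect_core(
    mol: Chem.Mol,
    ru: RepeatingUnit,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    n_steps: int = DEFAULT_N_STEPS,
) -> CoreResult:
    """Run the full per-molecule core detection.

    Returns NO_MATCH when no chain of at least ``min_len`` units is present;
    PURE_RU when chain removal empties the molecule at any step; otherwise
    CORE with the canonical SMILES of all remaining fragments.  Steps where
    no chain of minimum length remains are no-ops, so a generous ``n_steps``
    only costs time, never correctness.
    """
    if n_steps < 1:
        raise ValueError(f"number of fragmentation steps must be >= 1, got {n_steps}")
    queries = enumerate_chain_queries(ru, min_len, max_len)
    work = _canonical_order(mol)
    if not has_min_chain(work, queries):
        return CoreResult(status=CoreStatus.NO_MATCH)

    removed: list[int] = []
    for _ in range(n_steps):
        found = find_longest_chain(work, queries)
        if found is None:
            break
        match, length = found
        work = remove_single_chain(work, match)
        removed.append(length)
        if work.GetNumAtoms() == 0:
            return CoreResult(status=CoreStatus.PURE_RU, removed_chain_lengths=removed)
        work = _canonical_order(work)

    return CoreResult(
        status=CoreStatus.CORE,
        core_canonical=Chem.MolToSmiles(work),
        n_fragments=len(Chem.GetMolFrags(work)),
        removed_chain_lengths=removed,
    )
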