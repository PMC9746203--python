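import pytest
from rdkit import Chem

from homologues import (
    CoreStatus,
    detect_core,
    enumerate_chain_queries,
    find_longest_chain,
    has_min_chain,
    remove_single_chain,
    validate_repeating_unit,
)

from .conftest import as_mol


def brute_force_longest_ch2_run(mol: Chem.Mol) -> int:
    """Independent oracle: longest simple path over CH2 carbons.

    Enumerates every simple path in the subgraph induced by carbon atoms
    carrying exactly two hydrogens, connected by non-aromatic single bonds —
    exactly the atoms and bonds an alkyl chain query can match.
    """
    nodes = {
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 6 and a.GetTotalNumHs() == 2
    }
    adjacency = {i: set() for i in nodes}
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in nodes and j in nodes and bond.GetBondType() == Chem.BondType.SINGLE:
            adjacency[i].add(j)
            adjacency[j].add(i)

    best = 0

    def extend(vertex, visited):
        nonlocal best
        best = max(best, len(visited))
        for neighbour in adjacency[vertex]:
            if neighbour not in visited:
                extend(neighbour, visited | {neighbour})

    for vertex in nodes:
        extend(vertex, {vertex})
    return best


class TestHasMinChain:
    @pytest.mark.parametrize(
        "smiles, expected",
        [
            ("CCCC", False),  # butane: only 2 interior CH2
            ("CCCCC", True),  # pentane: 3 interior CH2
            ("c1ccccc1", False),  # benzene: no CH2 at all
        ],
    )
    def test_minimum_chain_presence(self, alkyl, smiles, expected):
        queries = enumerate_chain_queries(alkyl, 3, 30)
        assert has_min_chain(as_mol(smiles), queries) is expected


class TestFindLongestChain:
    def test_long_linear_alkane(self, alkyl):
        mol = as_mol("C" * 46)
        match, length = find_longest_chain(mol, enumerate_chain_queries(alkyl, 3, 50))
        assert length == 44
        assert len(set(match)) == 44  # matched atoms are distinct

    def test_truncated_at_configured_maximum(self, alkyl):
        mol = as_mol("C" * 46)
        _, length = find_longest_chain(mol, enumerate_chain_queries(alkyl, 3, 30))
        assert length == 30

    def test_chain_may_wrap_a_ring(self, alkyl):
        _, length = find_longest_chain(
            as_mol("C1CCCCC1"), enumerate_chain_queries(alkyl, 3, 30)
        )
        assert length == 6

    def test_no_chain_returns_none(self, alkyl):
        assert (
            find_longest_chain(as_mol("c1ccccc1"), enumerate_chain_queries(alkyl, 3, 30))
            is None
        )

    @pytest.mark.parametrize(
        "smiles",
        [
            "CCCCC",  # pentane
            "CCCCCC",  # hexane
            "CC(C)CCC",  # 2-methylpentane
            "CCC(C)C",  # isopentane
            "C1CCCCC1",  # cyclohexane
            "CC1CCCCC1",  # methylcyclohexane
            "C1CCCC1",  # cyclopentane
            "BrCCCCN1CCCC1",  # chain + ring through nitrogen
            "CCCCOCCCC",  # dibutyl ether
            "C1CCC2CCCCC2C1",  # decalin
            "C1CC2CCC1C2",  # norbornane
            "Cc1ccccc1",  # toluene: no CH2
            "C=CCCCC",  # 1-hexene: sp2 CH2 cannot join the chain
        ],
    )
    def test_matches_brute_force_path_search(self, alkyl, smiles):
        """Longest-match search agrees with exhaustive simple-path enumeration."""
        mol = as_mol(smiles)
        found = find_longest_chain(mol, enumerate_chain_queries(alkyl, 1, 12))
        length = found[1] if found else 0
        assert length == brute_force_longest_ch2_run(mol)


class TestRemoveSingleChain:
    def test_interior_removal_leaves_capped_termini(self, alkyl):
        mol = as_mol("CCCCC")
        match, _ = find_longest_chain(mol, enumerate_chain_queries(alkyl, 3, 30))
        remainder = remove_single_chain(mol, match)
        assert Chem.MolToSmiles(remainder) == "C.C"

    def test_only_one_of_two_symmetric_chains_removed(self, alkyl):
        mol = as_mol("CCCCCOCCCCC")  # dipentyl ether, 11 heavy atoms
        match, length = find_longest_chain(mol, enumerate_chain_queries(alkyl, 3, 30))
        assert length == 4
        remainder = remove_single_chain(mol, match)
        assert remainder.GetNumAtoms() == 7  # exactly one arm removed

    def test_full_removal_gives_empty_graph(self, alkyl):
        mol = as_mol("C1CCCCC1")
        match, _ = find_longest_chain(mol, enumerate_chain_queries(alkyl, 3, 30))
        assert remove_single_chain(mol, match).GetNumAtoms() == 0

    def test_out_of_range_match_rejected(self):
        with pytest.raises(ValueError):
            remove_single_chain(as_mol("CCCCC"), (2, 3, 99))


class TestDetectCore:
    @pytest.mark.parametrize(
        "smiles, ru_smarts, expected_core",
        [
            ("BrCCCCN1CCCC1", "[#6&H2]", "Br.N"),
            ("BrCCCCN1CCCC1", "[#6;!R&H2]", "Br.C1CCN(C1)"),
            ("CCCCC", "[#6&H2]", "C.C"),
        ],
    )
    def test_core_examples(self, smiles, ru_smarts, expected_core):
        result = detect_core(as_mol(smiles), validate_repeating_unit(ru_smarts))
        assert result.status is CoreStatus.CORE
        assert result.core_canonical == Chem.CanonSmiles(expected_core)

    def test_pure_repeating_unit_detected_before_step_budget_spent(self, alkyl):
        result = detect_core(as_mol("C1CCCCC1"), alkyl, n_steps=5)
        assert result.status is CoreStatus.PURE_RU
        assert result.removed_chain_lengths == [6]

    def test_below_minimum_is_no_match(self, alkyl):
        result = detect_core(as_mol("CCCC"), alkyl)
        assert result.status is CoreStatus.NO_MATCH
        assert result.removed_chain_lengths == []
        assert result.core_canonical is None

    def test_extra_steps_are_noops(self, alkyl):
        base = detect_core(as_mol("CCCCC"), alkyl, n_steps=2)
        more = detect_core(as_mol("CCCCC"), alkyl, n_steps=6)
        assert base.core_canonical == more.core_canonical
        assert base.removed_chain_lengths == more.removed_chain_lengths

    def test_chains_below_minimum_are_never_removed(self, alkyl):
        # one pentyl arm (run of 4) and one propyl arm (run of 2): the short
        # arm survives even though fragmentation steps remain
        result = detect_core(as_mol("c1cc(CCCCC)ccc1CCC"), alkyl, n_steps=3)
        assert result.status is CoreStatus.CORE
        assert result.core_canonical == Chem.CanonSmiles("C.CCCc1ccccc1")
        assert result.removed_chain_lengths == [4]

    def test_every_removed_chain_at_least_min_len(self, alkyl):
        result = detect_core(as_mol("C" * 46), alkyl)
        assert all(length >= 3 for length in result.removed_chain_lengths)

    def test_atom_conservation_on_examples(self, alkyl):
        for smiles in ["CCCCC", "CCCCCOCCCCC", "BrCCCCN1CCCC1", "C" * 46]:
            mol = as_mol(smiles)
            result = detect_core(mol, alkyl)
            core_atoms = Chem.MolFromSmiles(result.core_canonical).GetNumAtoms()
            removed = sum(result.removed_chain_lengths) * alkyl.atoms_per_unit
            assert core_atoms + removed == mol.GetNumAtoms()

    def test_stereo_at_fragmentation_site_is_erased(self, alkyl):
        with_stereo = detect_core(as_mol("C[C@H](Br)CCCCCC"), alkyl)
        without = detect_core(as_mol("CC(Br)CCCCCC"), alkyl)
        assert with_stereo.core_canonical == without.core_canonical
        assert "@" not in with_stereo.core_canonical

    def test_stereo_away_from_cut_distinguishes_cores(self, alkyl):
        with_stereo = detect_core(as_mol("C[C@H](Br)C(F)(F)OCCCCCC"), alkyl)
        without = detect_core(as_mol("CC(Br)C(F)(F)OCCCCCC"), alkyl)
        assert "@" in with_stereo.core_canonical
        assert with_stereo.core_canonical != without.core_canonical

    def test_perfluoroalkyl_terminal_fluorine_becomes_core_fragment(self):
        # in a CF3-terminated perfluoro chain the terminal carbon matches the
        # CF2 unit too, so its third fluorine is capped off into the core
        ru = validate_repeating_unit("[#6](-[#9])(-[#9])")
        mol = as_mol("OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F")
        result = detect_core(mol, ru)
        assert result.status is CoreStatus.CORE
        assert result.core_canonical == Chem.CanonSmiles("F.O=CO")

    def test_invariant_under_input_atom_ordering(self, alkyl):
        reference = detect_core(as_mol("BrCCCCN1CCCC1"), alkyl)
        rewritten = detect_core(as_mol("C1CCN(CCCCBr)C1"), alkyl)
        assert rewritten.status is reference.status
        assert rewritten.core_canonical == reference.core_canonical
        assert rewritten.removed_chain_lengths == reference.removed_chain_lengths
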