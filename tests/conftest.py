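import pytest
from rdkit import Chem

from homologues import validate_repeating_unit


@pytest.fixture(scope="session")
def alkyl():
    """The default alkyl (CH2) repeating unit."""
    return validate_repeating_unit("[#6&H2]")


@pytest.fixture()
def make_csv(tmp_path):
    """Write rows to a temporary CSV and return its path."""

    def _write(rows, header="SMILES,Name", name="input.csv"):
        path = tmp_path / name
        path.write_text("\n".join([header, *rows]) + "\n", encoding="utf-8")
        return path

    return _write


def as_mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, f"test molecule does not parse: {smiles!r}"
    return mol
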