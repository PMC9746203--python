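# homologues

Classify homologous series within compound datasets.

Homologous series — groups of compounds sharing the same core structure and
differing only in the number of attached repeating subunits (alkyl chains,
ethoxylate chains, CF₂ chains, …) — are ubiquitous in environmental
chemistry, natural products, surfactant formulations and PFAS inventories,
yet databases rarely link their members. `homologues` detects them
automatically: given a CSV of SMILES strings and a repeating unit expressed
as a SMARTS pattern, it groups molecules into series without any prior
knowledge of which cores exist or how many series there are.

## Algorithm

For a repeating unit **RU** (default: alkyl CH₂, SMARTS `[#6&H2]`) and
chain-length bounds *n*ₘᵢₙ … *n*ₘₐₓ (default 3 … 30):

1. **Preprocess** — parse each SMILES and sanitise it; unusable rows are
   discarded with a logged reason, never fatal.
2. **Enumerate chains** — build substructure queries RU, RU–RU, …, up to
   *n*ₘₐₓ copies joined by single bonds. A molecule with no match of at
   least *n*ₘᵢₙ units takes no further part (`series_no = -1`).
3. **Fragment** — for a fixed number of steps (default 2), find the single
   *longest* matching chain and delete exactly that one match, capping every
   broken bond with a hydrogen. One chain per step, even in symmetric
   molecules — removing all matches at once would give homologues with
   different chain counts different cores. A molecule whose atoms are all
   consumed is "purely repeating units" (`series_no = -2`).
4. **Classify** — the remaining fragment(s), as one canonical SMILES string
   (possibly dot-disconnected), are the molecule's **core**. Molecules with
   string-identical cores form a series (`series_no = 0 … N`); a core that
   occurs once in the dataset does not form a series (`series_no = -3`).

Series membership is therefore dataset-dependent by design: whether a
molecule is "in a series" depends on which potential partners are present.

## Worked example

```bash
$ cat molecules.csv
SMILES,Name
CCCCC,pentane
CCCCCC,hexane
CCCCCCC,heptane
CCCCCOCCCCC,dipentyl ether
CCCCOCCCC,dibutyl ether
BrCCCCN1CCCC1,1-(4-bromobutyl)pyrrolidine
c1ccccc1,benzene
C1CCCCC1,cyclohexane

$ homologues --input molecules.csv --out-dir results
2 homologous series detected (5 member molecules); outputs written to
results/classified-series.csv and results/classification-results.txt

$ cat results/classified-series.csv
SMILES,Name,series_no
CCCCC,pentane,0
CCCCCC,hexane,0
CCCCCCC,heptane,0
CCCCCOCCCCC,dipentyl ether,1
CCCCOCCCC,dibutyl ether,1
BrCCCCN1CCCC1,1-(4-bromobutyl)pyrrolidine,-3
c1ccccc1,benzene,-1
C1CCCCC1,cyclohexane,-2
```

The alkanes form series 0: removing their interior CH₂ chain leaves two
hydrogen-capped terminal carbons, core `C.C`. The two symmetric ethers form
series 1 with core `C.C.O` (one arm removed per fragmentation step). The
bromobutyl-pyrrolidine contains CH₂ chains but its core `Br.N` is unique
here (−3); benzene has no CH₂ at all (−1); cyclohexane is consumed entirely
by the ring-wrapping chain match (−2). `classification-results.txt` records
the same counts plus the full run configuration.

Other repeating units from the same interface: ethoxy
`[#8]-[#6&H2]-[#6&H2]`, perfluoroalkyl `[#6](-[#9])(-[#9])`, or a
ring-excluding alkyl `[#6;!R&H2]` that keeps rings intact as part of the
core. See `docs/methods.md` for the method's assumptions and limitations.

## Library use

```python
from rdkit import Chem
from homologues import detect_core, validate_repeating_unit

ru = validate_repeating_unit("[#6&H2]")
result = detect_core(Chem.MolFromSmiles("BrCCCCN1CCCC1"), ru)
result.core_canonical   # 'Br.N'
```

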