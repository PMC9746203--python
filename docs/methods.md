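# Methods

## The classification model

A homologous series is modelled as a set of molecules that become identical
once every chain of a chosen repeating unit is deleted. The method is
purely structural and fully unsupervised at the level of cores: nothing is
assumed about which cores exist, how many series there are, or how large
they are. The one piece of prior knowledge it does require is the repeating
unit itself, supplied as a SMARTS pattern whose first and last atoms have
open valences so that an n-unit chain can be expressed as n copies of the
pattern joined by explicit single bonds.

Per molecule the procedure is:

1. test whether any chain of at least `min_len` units matches as a
   substructure (by containment this is decided by the shortest query, but
   every enumerated query is honoured);
2. for `n_steps` fragmentation steps, find the longest matching chain,
   delete exactly that one match, and cap every broken bond with a hydrogen
   on the surviving atom; re-sanitise the remainder;
3. emit the canonical SMILES of everything that remains — one or several
   disconnected fragments in a single dot-separated string — as the core.

Series are then equivalence classes under string equality of cores. This
makes "same number and identity of fragments" a plain string comparison,
because RDKit's canonicalisation fixes both fragment structure and fragment
order within the string.

### Why only one chain per step

Removing every match of the chain query simultaneously would destroy the
grouping: a symmetric two-chain molecule would lose both arms in one step
while its one-chain homologue loses one, leaving cores that differ by a
capped attachment and therefore never compare equal. Removing exactly one
longest chain per step, with the step count as an explicit budget, makes
the core independent of how many chains a molecule carries — provided the
budget covers the number of chains actually present.

### Tie-breaking and determinism

When several equal-longest matches exist (symmetric molecules), exactly one
must be chosen. The choice is made deterministic by renumbering the
molecule's atoms into canonical rank order before every match search and
taking RDKit's first match. Consequently the entire fragmentation
trajectory, and hence the core, is a function of the molecular graph alone,
not of the order in which the input SMILES happened to list atoms. This is
verified by a 200-case property test that compares runs on randomly
renumbered copies of the same molecule. For symmetric ties the two
candidate trajectories are related by an automorphism, so the canonical
core string coincides either way.

### Stereochemistry

The hydrogen cap carries no stereo information: chiral tags on atoms at a
fragmentation site, and stereo descriptors on bonds touching such atoms,
are cleared, and stereo perception is re-run on the remainder. Stereo
centres and double-bond stereo away from every cut survive and distinguish
cores — two otherwise-homologous molecules of which only one has a
stereo-bearing core are deliberately *not* grouped. Stereo-bearing and
stereo-free cores are distinct grouping keys; no formula- or mass-level
merging of distinct cores is attempted.

## Parameters

| parameter  | default   | meaning and rationale |
|------------|-----------|------------------------|
| `ru`       | `[#6&H2]` | repeating-unit SMARTS; H-counts are exact, so alkane termini (CH₃) never match an alkyl CH₂ unit |
| `min_len`  | 3         | chains shorter than this are ignored everywhere; avoids classifying on trivially short runs that occur in most organic molecules |
| `max_len`  | 30 units  | longest enumerated chain query; a longer real chain is removed only partially (truncation), which can split one expected series member into extra fragments |
| `n_steps`  | 2         | one removable chain per step; raise it for molecules expected to carry more than two chains — extra steps are no-ops and cost only time |

SMARTS specificity is part of the model, not a nuisance: `[#6&H2]` matches
CH₂ inside rings (a cyclohexane is "purely repeating units"), while
`[#6;!R&H2]` confines chains to acyclic atoms and keeps rings in the core.
Recursive SMARTS are rejected at validation, since their meaning under
concatenation is not well defined.

## Degenerate inputs and numerical choices

- Unparseable or unsanitisable SMILES (e.g. pentavalent carbons) are
  discarded with a per-row reason and a WARN log line; they appear in the
  summary counts but not in the output CSV. An all-discarded input yields a
  header-only CSV rather than an error.
- Empty SMILES cells count as unparseable; duplicate rows are kept and
  classified independently; a parseable row with an empty name is kept.
- Explicit hydrogens in input SMILES are normalised to implicit during
  sanitisation so SMARTS H-count primitives see consistent totals.
- The output CSV echoes input SMILES verbatim (identifiers round-trip);
  canonical SMILES exist only internally as grouping keys.
- Matched chain atoms are required to be distinct, so a unit is never
  reused within one match; a chain may wrap a ring.
- Everything is single-threaded and deterministic: identical configuration
  and input give byte-identical outputs.

## The synthetic generator

`homologues.synthetic` builds datasets with known ground truth: a core
template with one or two `[*]` attachment points, a repeating-unit fragment
spliced in k times, and a terminal cap (default methyl, so alkane-like
`C.C`-style cores arise naturally). Distractors come from a fixed pool of
molecules containing no aliphatic CH₂ at all. Because spliced chains are
unbranched and strictly the longest runs present, the generator's partition
is provably what the classifier should recover whenever chain lengths lie
within `[min_len, max_len]` and chains per molecule do not exceed
`n_steps`. The standard benchmark used in the tests is 20 parallel series
of 4 members (chain lengths 3–6) plus 50 distractors.

What the generator does *not* emulate: the size and redundancy of real
collections (hundreds of thousands of structures), salts/mixtures and other
curation artefacts, branched repeating-unit chains, multi-chain molecules
beyond two attachments, and realistic property distributions. Passing the
recovery tests therefore demonstrates correctness of the mechanism, not
performance characteristics on production databases.

## Known limitations

- A chain longer than `max_len` is only partially removed; the affected
  molecule may land in a different (typically branched-analogue) series.
  Raising `max_len` fixes this at quadratic cost in matching work.
- The atomic neighbourhood of removed chains is ignored: branched analogues
  of the same total core, ring-substitution isomers (ortho/meta/para), and
  cores sitting terminally vs centrally are all grouped together. This is
  by design; callers wanting finer classes can post-process series by
  formula or mass.
- One repeating unit per run. A molecule can belong to different series
  across runs with different units; no attempt is made to merge them.
- Series numbering follows first appearance in the input, so labels are
  stable for a fixed file but not comparable across datasets; only the
  partition is.
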