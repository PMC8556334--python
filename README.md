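# bbbcurate

A curation toolkit that turns heterogeneous, redundant, partially erroneous
multi-source records of molecular blood–brain-barrier (BBB) permeability
into a clean, deduplicated, provenance-annotated dataset.

The BBB keeps most small molecules out of the central nervous system, so
whether a compound crosses it is a central question in CNS drug discovery.
Permeability is reported in the literature in two forms: numerically as

    log BB = log10( C_brain / C_blood )

(the brain-to-blood concentration ratio of the compound), and categorically
as BBB+ (permeable) / BBB− (non-permeable), conventionally thresholded at
log BB = −1. Published values for the same molecule are scattered across
dozens of sources with incompatible table layouts, transcription errors in
SMILES strings, salt forms, missing identifiers, conflicting labels, and
occasional implausible outliers. `bbbcurate` is for anyone assembling such
data into a benchmark set for QSAR/ML modelling.

## What it does

1. **Ingest** — reads CSV/XLSX source tables through explicit per-source
   column maps into one record schema; invalid rows become reject records
   with reasons, never silent drops.
2. **Standardize** — repairs SMILES text (whitespace, typographic minus
   signs), strips salts to the largest organic fragment, normalizes
   functional groups, neutralizes charges where chemically possible, and
   removes molecules containing metals or atoms with Z > 20 or more than 7
   boron atoms; outputs canonical isomeric SMILES plus standard InChI.
3. **Resolve** — fills missing name/SMILES/CID fields through a pluggable
   compound-registry resolver (live PUG-REST client, persistent cache, or
   offline table stub) and refreshes identifiers after standardization.
4. **Merge & curate** — merges records by byte-identical InChI, drops
   outlier instances (log BB ≤ −9), discards molecules whose values span
   more than 1 log unit, and grades consensus reliability:

   | group | numeric track | categorical track |
   |-------|---------------|-------------------|
   | A | one unique value → that value | has curated numeric data → label from log BB at −1 |
   | B | all values within 5 % of the mean → mean | sources agree, all report threshold −1 |
   | C | two distinct values → weighted mean | sources agree, threshold unreported |
   | D | >2 distinct values → modal value (tie → discard) | sources conflict → majority (tie → discard) |

5. **Extend** — appends a full 2D molecular-descriptor block (RDKit set by
   default; the mordred 1613-descriptor set when installed) and Lipinski
   Rule-of-5 profiles (MW < 500 Da, HBD < 5, HBA < 10, log P < 5).
6. **Validate** — re-parses every curated SMILES with an independent second
   parser (OpenBabel), cross-tabulates reliability group × measurement
   multiplicity, and summarizes log BB and physicochemical distributions.

A synthetic-fixture generator (`bbbcurate.synthetic`) produces messy
multi-source corpora with known ground truth — per-molecule record
multiplicity, value noise, outliers, label conflicts, SMILES corruption,
missing-field patterns — so every pipeline stage is testable offline, and
`score_recovery` measures end-to-end truth recovery.

## Worked example

```python
from bbbcurate import assign_numeric_group, filter_outliers, label_from_logbb

values = [-0.50, -0.51, -0.50]          # three sources, one molecule
kept, dropped = filter_outliers(values)  # nothing <= -9 here
group, logbb = assign_numeric_group(kept)
print(group, round(logbb, 4), label_from_logbb(logbb))
```

prints

```
B -0.5033 BBB+
```

meaning: all three values lie within 5 % of their mean, so the molecule is
graded group B with consensus log BB −0.5033, which is above the −1
threshold, hence BBB+. The `examples/` directory has one narrative script
per capability (standardization, consensus curation, the full pipeline on
synthetic fixtures, descriptors/Rule-of-5, QC); each prints the numbers it
computes and what they mean. The same workflow is scriptable from the
shell via the `bbbcurate` CLI (`ingest`, `curate`, `extend`, `qc`,
`fixtures`, `run-all`).

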