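# Methods

## The curation problem

Literature values of blood–brain-barrier permeability come in two forms:
numeric log BB (log10 of the brain-to-blood concentration ratio) and binary
BBB+/BBB− labels assigned by each source at its own log BB cutoff. The same
molecule is frequently reported by several sources — under different assay
conditions, with different structure transcriptions (salt forms, charged
protonation states, whitespace-mangled SMILES), and sometimes with
disagreeing numbers or labels. The toolkit's job is to reduce this to at
most one numeric and one categorical record per molecular identity, with an
explicit reliability grade, while keeping full provenance and never
discarding data silently.

## Structure standardization

Pipeline order: text repair → parse → largest-organic-fragment selection →
normalization/neutralization → element filter → canonicalization. The
element filter runs after desalting so that a metal counterion (e.g. a
sodium salt) does not reject an acceptable organic parent.

* Text repair removes all whitespace/line breaks and maps typographic dash
  variants (en dash, minus sign) onto the ASCII minus used in charge
  annotations. Unparsable SMILES are rejected as `invalid_smiles`, a value,
  not an exception.
* Salt stripping keeps the largest organic covalent fragment
  (RDKit `LargestFragmentChooser`, organic-preferred). Inputs with no
  carbon-containing fragment are `unresolvable`.
* Neutralization (RDKit `Uncharger` after `Normalize`) brings the net
  formal charge to 0 where chemistry allows. Permanently charged species
  (quaternary ammonium) are *kept*, uncharged-as-far-as-possible, with an
  explanatory comment — such drugs exist in BBB datasets and rejecting them
  would silently bias the corpus.
* The element filter rejects any molecule containing an atom with atomic
  number > 20 or a metal of any Z (Li, Na, Mg, Al, K, Ca are metals despite
  Z ≤ 20), and any molecule with more than 7 boron atoms (borane clusters
  depict unreliably). The boundary is strict: 7 borons pass, 8 fail;
  chlorine (Z = 17) passes. The literal Z > 20 default excludes Br/I
  compounds, which is chemically aggressive; `ElementFilterConfig.max_z`
  exposes the cutoff (e.g. 53 keeps halogenated drugs).
* Canonicalization emits RDKit canonical SMILES, isomeric when stereo
  annotations are present (stereochemistry matters for transporter-mediated
  BBB crossing, so enantiomers are deliberately kept distinct), plus the
  standard InChI. The contract is determinism and stereo preservation, not
  byte-agreement with any particular toolkit; the backend is replaceable.
* The full pipeline is idempotent: standardizing its own output is a
  no-op (tested over the whole built-in library).

Tautomer canonicalization is deliberately not applied; InChI cannot fully
resolve tautomers and no tautomer normalizer is used.

## Identity resolution and merging

The merge key is the standard InChI of the standardized structure,
compared byte-for-byte: resonance-variant and atom-order-variant SMILES of
one molecule collapse to one key; explicit enantiomers stay distinct.
Missing name/SMILES/CID fields are filled from a registry resolver; when a
name query returns several registry instances the first is taken and the
record is flagged ambiguous. The resolver is an interface with three
implementations (live PUG-REST, persistent TSV-backed cache, offline table
stub); all automated tests use the stub, and with a warm cache a rerun
performs zero network operations. After standardization the CID is
refreshed by SMILES lookup, since desalting changes the structure the
original identifier pointed at.

## Consensus rules

Numeric track, applied to each identity's value list in order:

1. **Outlier filter** — instances with log BB ≤ −9 are dropped
   (per-instance; the boundary is inclusive). These values are physically
   implausible relative to the observed distribution.
2. **Spread filter** — if max − min of the surviving values exceeds 1 log
   unit the molecule is discarded (strictly greater; a spread of exactly
   1.0 is kept).
3. **Grading** — value *distinctness* is judged after rounding to 2
   decimal places (`round_decimals`, configurable), matching typical
   reporting precision:
   * **A**: one unique value → consensus is the mean of the raw values
     (identical to "that value" when they are literally equal).
   * **B**: several values, every value within 5 % of the mean
     (operationalized as |v − mean| ≤ 0.05·|mean|; at mean ≈ 0 the relative
     criterion is undefined and B effectively requires identical rounded
     values, which branch A already captured) → consensus = mean. The mean
     is unweighted, as stated for this group.
   * **C**: exactly two distinct values → multiplicity-weighted mean of
     the distinct values (equal weights when each value occurs once).
   * **D**: more than two distinct values → the modal value (mean of the
     raw values rounding to the mode); a tie for greatest frequency
     discards the molecule.

   The consensus always lies within [min, max] of the surviving values,
   and grading is invariant under permutation of the value list (property
   tested, and cross-checked against an independently written literal
   transliteration of the rules on randomized inputs).

Categorical track: a molecule with curated numeric data is **group A**, its
label recomputed as BBB+ iff log BB ≥ −1 (the boundary log BB = −1 exactly
is classified BBB+; the convention is recorded here because the rule text
leaves it open, and source labels conflicting with the numeric-derived
label are noted in comments rather than used). Otherwise, unanimous labels
with every source reporting the −1 threshold are **group B**; unanimous
labels with unreported thresholds are **group C**; conflicting labels take
the majority as **group D**, with exact ties discarded. Unanimous labels
accompanied by a *reported* threshold different from −1 fit neither B
(threshold must be −1) nor C (threshold must be unreported): such labels
are not comparable under the common convention and the molecule is
discarded with reason `threshold_mismatch`. Per-source threshold metadata
arrives via configuration (`default_threshold` per source), not from text
mining.

## Descriptor extension and Rule-of-5

The descriptor backend is pluggable. The default is RDKit's full 2D
descriptor list (210 columns, deterministic order); the mordred 2D set
(1613 columns at the pinned version) is used when that optional package is
installed. Per-molecule computation failures become missing-value rows and
never abort a batch.

Rule-of-5 profiling uses Lipinski's original counting convention — HBD =
number of O–H and N–H bonds, HBA = number of N and O atoms — with
molecular weight as the sum of standard atomic weights and log P from the
Crippen atom-contribution estimator. The log P estimator differs from the
proprietary ALOGPS predictor used in some published analyses, so log P
class fractions from this package are not comparable to values computed
with that tool; the estimator name is recorded in output metadata.

## Technical validation

* **Parse validity**: every curated SMILES is re-parsed with OpenBabel — a
  codebase independent of the RDKit used for cleaning — via a batch
  subprocess; the check accepts any independent parser implementation.
* **Multiplicity tables**: group × multiplicity cross-tabulations for
  source values, unique values, source labels, unique labels. Counts sum
  to the dataset sizes, verified against a brute-force recount from
  provenance lists. Group-A categorical records count as one (derived)
  label.
* **Distributions**: log BB histogram with 0.25-wide bins over [−2 … 2]
  extended to [−3, 2] plus open under/overflow bins so counts always sum
  to the dataset size (binning is a presentation choice recorded in report
  metadata), per-class MW/HBD/HBA/logP summaries, and Rule-of-5 class
  fractions.
* **Released-data recounts**: `recount_released` computes row counts,
  class counts, per-group counts and the fraction of BBB+ molecules under
  500 Da from a released curated dataset's tables, for external
  cross-validation; the tables are supplied by the user (they are not
  redistributed with the package).

## Synthetic fixtures

The generator emulates the failure modes of literature compilation, not
assay chemistry: per-molecule record counts from a truncated Poisson
(mean 2, capped at 23 — matching the largest observed per-molecule source
multiplicity), true log BB from an equal-weight normal mixture centered at
0.0 and −1.2 (sd 0.5 each) so both permeability classes are populated and
most values fall in [−2, 2], reporting noise of 0.02 log units, and
configurable rates for outlier injection (values ≤ −9), label flips,
whitespace insertion, salt appending, carboxylate deprotonation (a charged
variant restored by neutralization), name-only and CID-only rows, and
threshold reporting (default 0.5). Structures come from a hand-listed
library of ~55 simple valid organics (including one enantiomer pair)
extended by a procedural chain + functional-group family, deduplicated by
InChI, so corpora of arbitrary size need no external structure source. All
randomness flows from one seeded generator; output is byte-identical under
a fixed seed.

Ground truth stores every corruption applied and the consensus each
molecule *should* receive, computed by an independent, literal
transliteration of the rules (`oracle_group`); `score_recovery` then
reports identity-merge, group, value and label recovery. Because fixtures
use simple, highly distinct structures, perfect recovery demonstrates the
correctness of the rule implementations and the robustness of the cleaning
steps to the modeled corruptions — not performance on real assay data,
whose structural diversity, tautomerism and transcription pathologies are
broader.

## Problem sizes and numeric choices

The test suite and the acceptance script run corpora of 40–500 molecules —
sizes chosen so the full battery exercises every rule path, including the
rare discard branches, while remaining quick to run routinely. Group-B
degeneracy at mean ≈ 0 is cut at |mean| ≤ 1e−8; value-distinctness rounding
is 2 decimals; float consensus values are serialized with 6 significant
digits, sufficient for exact read-back at reporting precision. Curated
outputs write `BBB-` with the ASCII hyphen-minus; the reader also accepts
the Unicode minus found in published tables.

## Known limitations

* Name- or CID-only records are only as resolvable as the configured
  registry resolver; offline runs leave them flagged `unresolved`.
* The default Z > 20 element filter excludes brominated and iodinated
  drugs; relax `max_z` if that is not desired.
* No tautomer normalization: distinct tautomers keep distinct InChIs when
  InChI itself distinguishes them.
* Rule-of-5 log P fractions depend on the estimator; only the MW, HBD and
  HBA rules are estimator-independent.
* The mordred descriptor backend requires an optional package; without it
  the descriptor block is the RDKit 2D set.
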