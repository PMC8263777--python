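# Methods

## The safety-concern metric

Each drug *j* is summarized by its vector of adverse-event counts
N<sup>j</sup> = (N₁ʲ, …, N₂₇ʲ) over the 27 MedDRA system organ classes,
using each term's *primary* SOC only. The metric standardizes the drug
against itself:

    Z_i^j = (N_i^j − μ_j) / σ_j,    μ_j = Σ_i N_i^j / 27

This is a within-drug, across-SOC disproportionality measure: it asks which
organ systems a drug's reports concentrate in, not whether the drug is
reported more than other drugs. It therefore carries the assumptions of
that design — no adjustment for reporting-rate confounders (time on market,
stimulated reporting, indication channeling), no severity weighting, no
multiple-testing correction, and the 27-cell profile always includes
zero-count SOCs (μ divides by 27 regardless).

**Standard-deviation divisor.** σ_j uses the population divisor 27
(`ddof=0`). The mean is defined over all 27 cells and no Bessel correction
is implied by the metric's definition; the population choice also gives the
exact identities used throughout the test suite: for every defined Z
vector, Σ Z = 0, Σ Z² = 27, |Z| ≤ √26, and — since each cell above 2
contributes more than 4 to Σ Z² — at most ⌊27/4⌋ = 6 SOCs can exceed 2. The
sample divisor (`ddof=1`) is available as a configuration option for
sensitivity analysis; it shrinks no ordering, only the scale (by
√(27/26) ≈ 1.019).

**Degenerate profiles.** A drug whose 27 counts are all equal has σ = 0 and
no defined Z; such drugs are reported as `undefined` rather than forced to
0 or ±∞. An all-zero profile is an error (such a drug should not have a
profile at all). Drugs appear in a stratified table only if they have at
least one record in that stratum.

**Banding.** Significance is strict: Z > 2. The five bands use half-open
intervals (2, ∞), (1, 2], (0, 1], (−1, 0], (−∞, −1], so Z = 2.0 is
"frequent", not significant — the strict significance rule forces the
endpoint out of the top band, and the remaining boundaries follow the same
convention. Human-readable outputs round Z to one decimal; machine outputs
(CSV) keep full precision.

## Cleaning and counting rules

- **Completeness**: a report is kept only if it has a case id, at least one
  drug mention, and at least one reaction.
- **Deduplication key**: (case id, normalized drug-name *set*, normalized
  reaction *set*); within a group only the highest case version survives.
  The set reading makes "the latest version of the report" well defined at
  the report level. Version ties keep the last report in input order and
  log a warning.
- **Suspect filter**: only primary-suspect (PS) and secondary-suspect (SS)
  mentions count; concomitant/interacting mentions are ignored. A drug
  mentioned as both PS and SS in one report counts once per reaction —
  the unit is the drug-event combination.
- **Within-report repeats**: identical normalized reactions in one report
  collapse to one before counting (transcription repeats should not double
  count).
- **Unmapped terms / unmatched names** are dropped and counted, never
  errors.
- **Sex strata**: F → female, M → male; every other code (unknown,
  missing, intersex-like codes) stays in the overall stream but is excluded
  from the sex tables, so overall = female + male + excluded by
  construction — asserted, not assumed.
- **Drug-name matching** is whole-token: a synonym fires only as a
  contiguous token run in the normalized text (tokens are alphanumeric
  runs). This is what prevents "chloroquine" from firing inside
  "hydroxychloroquine" while still matching "Hydroxychloroquine Sulfate
  200 mg" and crediting both partners of "Lopinavir/Ritonavir". Synonym
  collisions across drugs are a hard load error.
- **ATC classes** use the first letter of each code; a drug with codes in
  several classes contributes its full totals to each distinct class;
  drugs without codes are excluded from the ATC summary.
- **Trial filtering**: statuses whose leading word (case-insensitive) is
  withdrawn/suspended/terminated are excluded, so "Terminated (halted)"
  counts as terminated; any other status passes. Only trials with a
  `Drug:` intervention survive, and a trial counts once per matched drug.
  Intervention matching searches intervention descriptions only, not
  titles.

## The synthetic corpus

The generator emulates the statistical structure the analysis assumes: each
drug's reactions are i.i.d. draws from a 27-way categorical distribution.
A planted enrichment (drug, SOC, λ ≥ 1) multiplies that SOC's weight by λ
and renormalizes, so with a uniform baseline the planted probability is
λ/(26 + λ) — e.g. 10/36 ≈ 0.278 at λ = 10, which the calibration test
checks within three binomial standard errors.

Realism features: reports carry sex codes (F/M/UNK at 0.45/0.45/0.10 by
default), suspect roles (PS/SS/C at 0.60/0.25/0.15), 1 + Poisson(0.5)
reactions per report, a 30% LLT / 70% PT spelling mix, verbatim drug names
drawn from the synonym set with occasional case mangling and dose suffixes.
Duplicates re-emit an existing case with version 2 and identical content,
matching the dedup key exactly, so the cleaner's removals are predictable
from the manifest; incomplete reports lack the case id, the drug, or the
reactions. Default sizes — 20 drugs × 200 reports, 5% duplicates, 5%
incomplete — are the package's standing study conditions; the oracle-
equivalence check uses a 10 × 500 (5,000-report) corpus and the planted-
signal study uses λ = 5 with exactly one reaction per report across 10
seeds. These sizes were chosen once as representative small-corpus
conditions under which every property is sharply testable.

What the generator does **not** model: reporting-rate confounders, term
misspellings (every generated term is in the dictionary; unmapped-term
handling is exercised by the hand-built micro-fixture instead), report
dates, dose, outcomes, and drug–drug interactions. Passing tests therefore
demonstrate correctness of the counting and standardization machinery under
the multinomial model, not robustness to real FAERS messiness beyond the
corruption modes listed above.

A single seeded numpy `Generator` drives all draws in a fixed order
(lexicon ATC codes → trials → per-drug reports → duplicate selection →
incomplete reports); adding a feature must not silently reorder existing
draws, which the byte-identity regression tests would catch. Within one
report, reaction terms are drawn without replacement so the within-report
collapse rule never desynchronizes the manifest from the pipeline.

## Numerical and design choices

- Term normalization: case-fold, collapse internal whitespace, strip
  surrounding punctuation; idempotent by construction and property-tested.
- The 27-SOC table ships as package data and fixes the column order of all
  matrices; loading any table without exactly 27 unique entries is an
  error.
- The dictionary dialect is a plain TSV (term, level, parent PT, primary
  SOC) with only LLT/PT levels — the analysis needs no HLT/HLGT
  intermediates — validated for dangling parents and unknown SOCs at load.
- An unmapped term is a value (None), not an error: discarding with a
  counter is part of the method.
- All outputs are deterministic CSV/JSON (sorted keys, fixed row order,
  `\n` newlines); re-running any stage on identical inputs is
  byte-identical, which doubles as a no-hidden-state check.
- The independent oracle used in tests is a separate brute-force
  implementation (nested loops, its own normalizer, matcher, dedup) kept
  free of package imports so agreement is meaningful.

## Known limitations

Counts are of drug × mapped-reaction pairs after all filters; spontaneous
data cannot support incidence estimates, and the Z profile of a drug with
very few reports is noisy (the metric has no shrinkage). Ambiguous
intervention strings matching several lexicon drugs credit all of them —
with a combination product this is the intended behaviour, but it means a
trial count is not a partition. The five-band boundaries at exactly 1, 0
and −1 follow the same half-open convention as the significance threshold;
prose descriptions of the bands do not pin the endpoints, and the choice at
those interior boundaries is a convention, not a result.
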