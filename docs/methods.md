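# Methods

## Problem and pipeline

`promread` estimates how hard questionnaire text is to read and compares
that estimate with the age group the questionnaire claims to serve. The
pipeline is:

1. **Standardization.** Questionnaire items are rarely punctuated prose,
   and sentence-based formulas misbehave on them. Each text unit therefore
   gets a terminal period if it lacks one, and enumeration prefixes
   ("1.", "Q3)", "a:") are removed — letter-counting formulas such as
   Coleman–Liau are highly sensitive to stray numbering. Existing terminal
   marks (?, !) are kept as-is; only missing punctuation is added.
   Response options join the analysed text only when they are full
   sentences rather than short Likert labels; if any response set in a
   questionnaire is full-sentence, all of that questionnaire's option sets
   are included, keeping one instrument internally consistent. Options
   that complete the item stem ("My health is" + "very good") are
   concatenated before the period is placed. Instructions, the scored item
   set, and demographic items are analysed as separate streams, because
   their reading demands differ; example items embedded in instructions
   stay in the instructions stream and are counted once, as they appear.
   Demographic items are reported separately and excluded from item-set
   summaries.

2. **Lexical statistics.** One pass computes every count the formulas
   need. Classical formulas do not specify tokenization, so one documented
   convention is fixed: words are whitespace tokens with surrounding
   punctuation stripped; hyphenated compounds are one word whose letters
   and syllables sum over the parts; digit groups count as words with 0
   letters and 1 syllable each; letters are alphabetic characters only;
   everything is case-insensitive. Sentence re-validation splits on
   `. ! ?` + whitespace with a configurable abbreviation guard ("e.g.",
   "i.e.", ...). Syllables come from a small exceptions lexicon first
   (words like "every" or "doing" where vowel-group counting fails), then
   the heuristic: count maximal a/e/i/o/u/y groups, drop a silent final
   "e" unless the word ends in consonant+"le", minimum one syllable. The
   per-token source (lexicon / heuristic / digits) is exposed through an
   audit table for reproducibility across software, which is a known
   source of score divergence between readability tools.

3. **Formulas.** Coleman–Liau, Flesch–Kincaid, FORCAST, Gunning Fog and
   the Powers-recalculated Dale–Chall point estimate
   (`3.2672 + 0.0596·ASL + 0.1155·%difficult`), constants kept in one
   cited table (`formulas.FORMULA_CONSTANTS`). Fog's "difficult word" is
   the plain ≥3-syllable count; the original Fog exclusions (proper nouns,
   inflected -es/-ed forms) are deliberately not applied — the simpler
   rule is the one the rest of the pipeline documents and tests. Dale–Chall
   is reported as the Powers point estimate only, not an age band, so it
   can enter a cross-formula mean. Reading age = grade + 5 uniformly.
   Reported values are rounded half-up to 1 decimal; means are always
   taken over unrounded values first.

4. **Easy-word list.** The difficulty test is surface-form membership in
   an expanded easy list. Expansion applies both noun and verb rules to
   every base word (part of speech is unknown); over-generated forms
   ("runned") are accepted — they can only make a judgment more lenient,
   and almost never collide with real hard words. Rules: +s (+es after
   s/x/z/ch/sh, consonant-y→ies), +ed (final-e drop, consonant-y→ied),
   +ing (final-e drop), consonant doubling for CVC monosyllables; a
   bundled irregular table adds forms like wrote/children/feet, including
   irregular plurals — an assumption, flagged here, since expansion
   conventions differ. The bundled base list
   (`data/easy_words_synthetic.txt`) is a curated synthetic stand-in for
   classic ~3000-word easy vocabularies, which are licensed; ~750 base
   forms expand to ~3000 surface forms. No analysis is tied to this
   particular list: every list-sensitive test also runs with tiny custom
   lists, and any plain-text list (one word per line) can be supplied.

5. **Battery aggregation.** Per stream: mean, SD, min/max per formula and
   for the cross-formula mean. The SD is the sample (n−1) estimator; on
   battery-sized n both estimators round identically at report precision,
   so the choice is documented rather than load-bearing. A questionnaire
   lacking a stream is simply omitted from that stream's summary and from
   the percentage denominator. Discrepancy: `delta = target_age_min −
   mean_reading_age`; a questionnaire is flagged when `delta ≤ −1` year,
   and flagged-only aggregates (count, percentage, mean |delta|, SD,
   range) are recomputed exactly from the per-record deltas. When
   consuming published 1-decimal reading ages, deltas are computed on
   those rounded values (the published ranges arise that way); full-text
   mode can keep unrounded ages via `analyze_battery(round_ages=False)`.
   Correlations are Pearson r with two-sided p from the t distribution on
   n−2 df (scipy.stats.pearsonr); zero-variance columns are reported as
   undefined rather than 0 or 1. The length-vs-readability analysis
   correlates stream word count with mean reading age and records any
   excluded outliers by name. Age-group classification
   (child / adolescent / child-and-adolescent) is input metadata, not
   inferred from the target range, because published classifications do
   not follow a single mechanical rule.

## Synthetic data: what it emulates and what it does not

Real questionnaire texts are licensed and cannot ship with the package, so
the test surface rests on two substitutes.

The **count-exact generator** assembles items from word pools stratified by
(syllable count × easy-list membership): difficult words are drawn
monosyllabic and extra syllable mass comes only from 3-syllable easy
words, so percent-difficult and syllables-per-word are independently
controllable and every target is hit by integer word placement, not by
sampling. Expected token statistics — and hence every formula's expected
grade — are therefore analytic, and the round-trip test demands exact
(integer) agreement after the full standardize→count pipeline. Targets
that do not resolve to whole words, or that overfill the word budget,
raise an error naming the offending target or stratum. Defaults (10 items
× 10 words) mirror the short item sets typical of youth QoL instruments.
What the generator does **not** emulate: meaningful semantics, realistic
word-frequency profiles, response-option structure, or punctuation noise.
Passing round-trips show the counting and aggregation machinery is exact;
they say nothing about how well any tokenization convention matches
another tool's on real instrument text, where software-to-software score
differences of a grade level or more are documented.

The **packaged reference battery** (`data/reference_battery.json`) carries
published per-formula reading ages, target age ranges, item counts and
age-group labels for 21 widely used youth QoL questionnaires (20 with
instructions). It feeds the aggregation, discrepancy and correlation
stages in age-passthrough mode, so those stages are testable against
published battery-level figures without the underlying texts. Two minor
internal inconsistencies of the published table are noted: recomputing the
item-set Fog column mean from the printed rows gives 10.9 against a
printed 10.8, and the instructions Coleman–Liau SD gives 2.7 against a
printed 2.6 — both consistent with the published column statistics having
been computed on unrounded scores. The cross-formula grand means,
flagged counts, percentages and discrepancy ranges all reproduce exactly
from the printed rows.

## Numerical choices

- Half-up decimal rounding (`formulas.round_half_up`) for all reported
  figures; banker's rounding would shift boundary cases like 11.275.
- Exact intercept: `power_dale_chall(0, 0)` returns 3.2672 with no
  floating error (the constants are exact decimals in binary-safe ranges;
  the test asserts equality).
- Pearson correlations require n ≥ 3 and report NaN (flagged `defined ==
  False`) on constant input rather than raising mid-battery.
- Degenerate inputs: empty sections, zero-word text and zero-word
  percent-difficult raise typed errors; a missing target age skips the
  record with a warning instead of failing the battery.

## Problem sizes

The synthetic analyses use 100-word questionnaires (10 × 10), the scale at
which readability estimates start to stabilise and the scale of real item
sets; the reference battery is the full 21-questionnaire set. The whole
suite and the acceptance script each run in well under a minute.

## Known limitations

- Readability is not comprehensibility: layout, ambiguity, construct
  complexity and double-barrelled phrasing are out of scope.
- English only; the formulas' constants are calibrated on US English.
- Exact per-instrument score parity with other readability software is not
  a goal — tokenizer and syllabifier conventions differ by tool — so
  per-instrument formula scores for real instruments are not an
  acceptance surface; battery-level aggregation is.
- The syllable heuristic errs on some words ("lived" → 2); the exceptions
  lexicon covers frequent offenders and is extendable.
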