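# promread

Readability analysis for self-report questionnaires used with children and
adolescents.

Young people can only complete a quality-of-life (QoL) or mental-health
questionnaire meaningfully and on their own if its reading difficulty
matches their reading ability — a core facet of a measure's content
validity. `promread` quantifies that difficulty: it standardizes
questionnaire text, computes five classical readability formulas, converts
the resulting US school grades to reading ages, and reports, per
instrument, whether the required reading age exceeds the youngest age the
instrument claims to target.

## The statistics at the core

Each formula maps surface lexical statistics to a US grade level `G`;
reading age is `G + 5` years (North American grade/age correspondence).
With `L` = letters per 100 words, `S` = sentences per 100 words, `ASL` =
words per sentence, `ASW` = syllables per word, `M` = monosyllables per 150
words, `P3` = percent of words with ≥3 syllables and `PD` = percent of
words absent from an easy-word list:

| formula | grade |
| --- | --- |
| Coleman–Liau (CLI) | `0.0588·L − 0.296·S − 15.8` |
| Flesch–Kincaid (FK) | `0.39·ASL + 11.8·ASW − 15.59` |
| FORCAST (FCST) | `20 − M/10` (ignores sentences — suited to non-prose) |
| Gunning Fog (FOG) | `0.4·(ASL + P3)` |
| Dale–Chall, Powers point estimate (DC) | `3.2672 + 0.0596·ASL + 0.1155·PD` |

The five grades are triangulated into a mean reading age per section
stream (instructions / items / demographics). `PD` is computed against an
easy-word list whose base entries are morphologically expanded (plural,
third-person, past, gerund: "writes", "writing", "wrote" join "write"),
since inflections are not meaningfully less familiar than their stems.

A questionnaire is **flagged** when its mean reading age exceeds its
minimum target age by at least one year — i.e. when the youngest intended
respondents are not expected to be able to read it.

## Worked example

Score a synthetic questionnaire end to end:

```bash
promread generate --n-items 10 --words-per-item 10 --pct-difficult 20 --seed 3 -o demo
promread analyze demo.questionnaire.json -o demo_report
promread summarize demo_report.json --section items
```

Aggregate the packaged reference battery — published per-formula reading
ages for 21 widely used youth QoL questionnaires — through the same
summary and discrepancy stages (age-passthrough mode):

```bash
python analysis/03_reference_battery_analysis.py
```

prints

```
items: n=21, mean reading age 10.7 years (SD 1.2, range 9.1-12.4)
  flagged 13/21 (61.9%), mean discrepancy 3.0 years, delta range (-4.4, -1.2)
instructions: n=20, mean reading age 11.3 years (SD 1.6, range 9.9-15.9)
  flagged 15/20 (75.0%), mean discrepancy 2.8 years, delta range (-4.8, -1.6)
```

Read: across the 21 item sets the average required reading age is 10.7
years; for 13 of them (61.9%) it exceeds the instrument's minimum target
age by at least a year, by 3.0 years on average (deltas are `target_min −
reading_age`, so negative values are deficits). Instructions read harder
still. The other drivers (`analysis/01_…`, `analysis/02_…`) build a
synthetic battery with exactly controlled lexical statistics and verify
the full text pipeline reproduces its construction-time expectations.

## Layout

- `src/promread/` — the library: `model` (questionnaire model +
  standardization), `textstats` (tokenization and lexical counts),
  `wordlist` (easy-list expansion and the difficulty test), `formulas`
  (the five formulas and reading-age conversion), `battery` (aggregation,
  discrepancies, correlations, report I/O), `synthetic` (count-exact
  generator + packaged reference battery), `cli` (click interface).
- `analysis/` — numbered narrative drivers writing tables under `results/`.
- `tests/` — unit, property (hypothesis) and end-to-end suites.
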