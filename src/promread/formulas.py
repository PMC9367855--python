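"""The five readability formulas and reading-age conversion.

Each formula maps lexical statistics to a US school-grade level; grades are
converted to reading ages by adding five years, matching the North American
grade/age correspondence. The formulas triangulate different surface
features of difficulty:

====  ======================================  ==========================
id    inputs                                  constants from
====  ======================================  ==========================
CLI   letters / 100 words (L),                Coleman & Liau (1975):
      sentences / 100 words (S)               0.0588 L - 0.296 S - 15.8
FK    words/sentence (ASL),                   Kincaid et al. (1975):
      syllables/word (ASW)                    0.39 ASL + 11.8 ASW - 15.59
FCST  monosyllables per 150 words (M)         Caylor et al. (1973):
                                              20 - M / 10
FOG   ASL, % words with 3+ syllables          Gunning (1952):
                                              0.4 (ASL + % poly)
DC    ASL, % difficult words                  Powers, Sumner & Kearl
                                              (1958) recalculated
                                              Dale-Chall:
                                              3.2672 + 0.0596 ASL
                                              + 0.1155 %difficult
====  ======================================  ==========================

FORCAST deliberately ignores sentence boundaries, which suits questionnaire
text where punctuation is sparse and sentences are artificially short; the
Powers point-estimate form of Dale-Chall is used so the vocabulary-based
score is a single grade rather than an age band.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from promread.model import StandardizedText
from promread.textstats import TokenStats, compute_text_stats
from promread.wordlist import EasyWordList

FORMULA_IDS = ("CLI", "DC", "FK", "FOG", "FCST")

GRADE_TO_AGE_OFFSET = 5.0

#: Auditable constants table; one row per formula, with source.
FORMULA_CONSTANTS = {
    "CLI": {"letters": 0.0588, "sentences": -0.296, "intercept": -15.8,
            "source": "Coleman & Liau 1975, J Appl Psychol 60:283-284"},
    "FK": {"asl": 0.39, "asw": 11.8, "intercept": -15.59,
           "source": "Kincaid et al. 1975, Naval Technical Training Command"},
    "FCST": {"base": 20.0, "divisor": 10.0, "sample": 150.0,
             "source": "Caylor et al. 1973, HumRRO FORCAST study"},
    "FOG": {"factor": 0.4,
            "source": "Gunning 1952, The Technique of Clear Writing"},
    "DC": {"intercept": 3.2672, "asl": 0.0596, "pct_difficult": 0.1155,
           "source": "Powers, Sumner & Kearl 1958 recalculated Dale-Chall"},
}


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding used for every reported figure."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def grade_to_age(grade: float) -> float:
    """US grade level -> reading age in years (grade + 5)."""
    return grade + GRADE_TO_AGE_OFFSET


@dataclass(frozen=True)
class GradeScore:
    formula_id: str
    grade: float

    def __post_init__(self) -> None:
        if self.formula_id not in FORMULA_IDS:
            raise ValueError(f"unknown formula id {self.formula_id!r}")

    @property
    def reading_age(self) -> float:
        return grade_to_age(self.grade)


def coleman_liau(stats: TokenStats) -> GradeScore:
    """Grade from letters and sentences per 100 words (no syllables)."""
    c = FORMULA_CONSTANTS["CLI"]
    grade = (
        c["letters"] * stats.letters_per_100_words
        + c["sentences"] * stats.sentences_per_100_words
        + c["intercept"]
    )
    return GradeScore("CLI", grade)


def flesch_kincaid(stats: TokenStats) -> GradeScore:
    """Grade from average sentence length and syllables per word."""
    c = FORMULA_CONSTANTS["FK"]
    grade = (
        c["asl"] * stats.words_per_sentence
        + c["asw"] * stats.syllables_per_word
        + c["intercept"]
    )
    return GradeScore("FK", grade)


def forcast(stats: TokenStats) -> GradeScore:
    """Grade from monosyllable incidence alone; sentence-segmentation-free."""
    c = FORMULA_CONSTANTS["FCST"]
    m = stats.n_monosyllabic * c["sample"] / stats.n_words
    return GradeScore("FCST", c["base"] - m / c["divisor"])


def gunning_fog(stats: TokenStats) -> GradeScore:
    """Grade from sentence length and percent of 3+-syllable words."""
    c = FORMULA_CONSTANTS["FOG"]
    pct_poly = 100.0 * stats.n_poly3 / stats.n_words
    return GradeScore("FOG", c["factor"] * (stats.words_per_sentence + pct_poly))


def power_dale_chall(asl: float, pct_difficult: float) -> GradeScore:
    """Powers-recalculated Dale-Chall point estimate.

    grade = 3.2672 + 0.0596 * ASL + 0.1155 * %difficult, with %difficult on
    the 0-100 scale.
    """
    if asl < 0:
        raise ValueError("average sentence length must be non-negative")
    if not 0.0 <= pct_difficult <= 100.0:
        raise ValueError("pct_difficult must lie in [0, 100]")
    c = FORMULA_CONSTANTS["DC"]
    grade = c["intercept"] + c["asl"] * asl + c["pct_difficult"] * pct_difficult
    return GradeScore("DC", grade)


def dale_chall(stats: TokenStats) -> GradeScore:
    return power_dale_chall(stats.words_per_sentence, stats.pct_difficult)


@dataclass(frozen=True)
class SectionResult:
    """One section's five grades plus the cross-formula mean reading age."""

    section_kind: str
    stats: TokenStats
    scores: dict[str, GradeScore]

    @property
    def reading_ages(self) -> dict[str, float]:
        return {fid: self.scores[fid].reading_age for fid in FORMULA_IDS}

    @property
    def mean_reading_age(self) -> float:
        """Arithmetic mean of the five unrounded reading ages."""
        ages = self.reading_ages
        return sum(ages.values()) / len(ages)

    def rounded_reading_ages(self, ndigits: int = 1) -> dict[str, float]:
        return {k: round_half_up(v, ndigits) for k, v in self.reading_ages.items()}


def score_section(
    standardized: StandardizedText, easy: EasyWordList
) -> SectionResult:
    """Compute all five formulas from one pass over the lexical statistics."""
    stats = compute_text_stats(standardized, easy)
    scores = {
        "CLI": coleman_liau(stats),
        "DC": dale_chall(stats),
        "FK": flesch_kincaid(stats),
        "FOG": gunning_fog(stats),
        "FCST": forcast(stats),
    }
    return SectionResult(
        section_kind=standardized.source_kind, stats=stats, scores=scores
    )
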