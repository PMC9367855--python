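"""Synthetic questionnaires with exactly controlled lexical statistics.

Real questionnaire texts are licensed and cannot be redistributed, so the
test surface of this package is built on two substitutes:

* a count-exact generator: words are drawn from pools stratified by
  (syllable count, easy-list membership) and placed to hit integer targets
  for difficult-word count and total syllables, so the expected lexical
  statistics — and therefore every formula's expected grade — are known
  analytically at assembly time, not approximated by sampling;
* a packaged reference battery: per-questionnaire reading ages, target age
  ranges and item counts for 21 widely used youth quality-of-life
  questionnaires, as published, feeding the aggregation and discrepancy
  stages in age-passthrough mode.

Generation is deterministic given the seed.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

from promread.formulas import (
    GradeScore,
    coleman_liau,
    dale_chall,
    flesch_kincaid,
    forcast,
    gunning_fog,
)
from promread.model import Questionnaire, Section, TextUnit
from promread.textstats import TokenStats, count_letters, count_syllables
from promread.wordlist import EasyWordList, is_difficult


class SyntheticSpecError(ValueError):
    """Raised when a spec's targets are unachievable with its pools."""


#: Curated monosyllabic words unlikely to appear on any easy-word list.
DEFAULT_DIFFICULT_POOL = [
    "flux", "glyph", "plinth", "wisp", "gaunt", "brusque", "quartz",
    "sphinx", "tryst", "wraith", "scythe", "knell", "dirge", "fjord",
]


def default_word_pools(easy: EasyWordList) -> dict[str, list[str]]:
    """Stratified pools built from an easy list plus curated difficult words.

    Strata: ``easy_mono`` (on-list, 1 syllable), ``easy_tri`` (on-list,
    3 syllables), ``difficult_mono`` (off-list, 1 syllable). Membership is
    verified against the package's own counters so generated expectations
    are exact by construction.
    """
    easy_mono = sorted(
        w for w in easy.base_words if w.isalpha() and count_syllables(w) == 1
    )
    easy_tri = sorted(
        w for w in easy.base_words if w.isalpha() and count_syllables(w) == 3
    )
    difficult_mono = [
        w
        for w in DEFAULT_DIFFICULT_POOL
        if is_difficult(w, easy) and count_syllables(w) == 1
    ]
    return {
        "easy_mono": easy_mono,
        "easy_tri": easy_tri,
        "difficult_mono": difficult_mono,
    }


@dataclass
class SyntheticSpec:
    """Targets for one generated questionnaire.

    ``target_pct_difficult`` (0-100) and ``target_asw`` (>= 1) must be
    achievable as integer word placements given ``n_items`` x
    ``words_per_item`` total words; difficult words are monosyllabic and
    syllable mass is added through 3-syllable easy words, so the two targets
    are independently controllable.
    """

    n_items: int
    words_per_item: Union[int, Sequence[int]] = 10
    target_pct_difficult: float = 0.0
    target_asw: float = 1.0
    seed: int = 0
    word_pools: Optional[dict[str, list[str]]] = None
    name: str = "synthetic"

    def item_lengths(self) -> list[int]:
        if isinstance(self.words_per_item, int):
            return [self.words_per_item] * self.n_items
        lengths = list(self.words_per_item)
        if len(lengths) != self.n_items:
            raise SyntheticSpecError(
                "words_per_item sequence length must equal n_items"
            )
        return lengths


@dataclass(frozen=True)
class ExpectedStats:
    """Construction-time expectations for a generated questionnaire."""

    stats: TokenStats
    grades: dict[str, float] = field(default_factory=dict)


def _expected_grades(stats: TokenStats) -> dict[str, float]:
    scores: list[GradeScore] = [
        coleman_liau(stats),
        dale_chall(stats),
        flesch_kincaid(stats),
        gunning_fog(stats),
        forcast(stats),
    ]
    return {s.formula_id: s.grade for s in scores}


def _exact_count(value: float, what: str) -> int:
    if abs(value - round(value)) > 1e-9:
        raise SyntheticSpecError(
            f"{what} does not resolve to a whole number of words ({value!r})"
        )
    return int(round(value))


def generate_questionnaire(
    spec: SyntheticSpec, easy: EasyWordList
) -> tuple[Questionnaire, ExpectedStats]:
    """Assemble a questionnaire whose exact TokenStats are known.

    Each item becomes one sentence (standardization appends the period).
    Raises :class:`SyntheticSpecError` when a target is not attainable with
    the given pools, naming the offending stratum or target.
    """
    if spec.n_items <= 0:
        raise SyntheticSpecError("n_items must be positive")
    lengths = spec.item_lengths()
    if any(w <= 0 for w in lengths):
        raise SyntheticSpecError("words_per_item must be positive")
    n_words = sum(lengths)

    n_difficult = _exact_count(
        spec.target_pct_difficult / 100.0 * n_words, "target_pct_difficult"
    )
    n_tri = _exact_count(n_words * (spec.target_asw - 1.0) / 2.0, "target_asw")
    if n_tri < 0:
        raise SyntheticSpecError("target_asw must be >= 1")
    n_easy_mono = n_words - n_difficult - n_tri
    if n_easy_mono < 0:
        raise SyntheticSpecError(
            "targets overfill the questionnaire: difficult + trisyllabic "
            "words exceed the total word budget"
        )

    pools = spec.word_pools or default_word_pools(easy)
    needs = {
        "easy_mono": n_easy_mono,
        "easy_tri": n_tri,
        "difficult_mono": n_difficult,
    }
    rng = random.Random(spec.seed)
    words: list[str] = []
    for stratum, need in needs.items():
        if need == 0:
            continue
        pool = pools.get(stratum, [])
        if not pool:
            raise SyntheticSpecError(f"stratum {stratum!r} has an empty pool")
        words.extend(rng.choice(pool) for _ in range(need))
    rng.shuffle(words)

    units: list[TextUnit] = []
    start = 0
    for i, length in enumerate(lengths):
        item_words = words[start : start + length]
        start += length
        units.append(
            TextUnit(text=" ".join(item_words), numbering_prefix=f"{i + 1}.")
        )

    n_letters = sum(count_letters(w) for w in words)
    total_syllables = sum(count_syllables(w) for w in words)
    stats = TokenStats(
        n_words=n_words,
        n_sentences=spec.n_items,
        n_letters=n_letters,
        total_syllables=total_syllables,
        n_monosyllabic=n_words - n_tri,
        n_poly3=n_tri,
        n_difficult=n_difficult,
    )
    questionnaire = Questionnaire(
        name=spec.name,
        target_age_min=8,
        target_age_max=18,
        sections=[Section(kind="items", units=units)],
    )
    return questionnaire, ExpectedStats(stats=stats, grades=_expected_grades(stats))


# --------------------------------------------------------------------------
# Packaged reference battery


def _reference_path() -> Path:
    return Path(str(resources.files("promread").joinpath("data", "reference_battery.json")))


def generate_battery_fixture() -> list[dict]:
    """The packaged reference battery of published reading ages.

    Returns one record per questionnaire (21 in total; 20 carry instruction
    figures) with name, target age range, age-group label, item count, and
    per-section reading ages for the five formulas plus their printed
    cross-formula mean. Feed to
    :func:`promread.battery.rows_from_reference` for aggregation.
    """
    with open(_reference_path(), encoding="utf-8") as fh:
        payload = json.load(fh)
    return payload["questionnaires"]
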