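"""Questionnaire data model and text standardization.

A questionnaire is analysed in up to three separate streams — instructions,
the scored item set, and any demographic items — because their reading
demands differ and summary statistics are reported per stream. Before any
counting, raw questionnaire text is standardized: enumeration prefixes
("1.", "Q3)") are stripped, a period is appended to any unit that lacks
terminal punctuation, and response options are folded in according to a
whole-questionnaire policy (see :func:`resolve_response_option_policy`).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

SECTION_KINDS = ("instructions", "items", "demographics")

TERMINAL_PUNCTUATION = (".", "!", "?")

#: Leading enumeration: digits or a single letter, followed by ".", ")" or ":"
#: and whitespace (or nothing, when the prefix is carried separately).
DEFAULT_NUMBERING_PATTERN = r"^\s*(?:\(?\d+|\(?[A-Za-z])[\.\):]\s+"


class EmptySectionError(ValueError):
    """Raised when a section holds no analyzable text."""


@dataclass(frozen=True)
class StandardizationPolicy:
    """Options controlling text standardization.

    numbering_pattern
        Regular expression matched (and removed) at the start of each unit.
    strip_numbering
        Disable to keep enumeration prefixes (used to probe their effect on
        letter-based formulas, which are highly sensitive to them).
    """

    numbering_pattern: str = DEFAULT_NUMBERING_PATTERN
    strip_numbering: bool = True

    def numbering_re(self) -> re.Pattern:
        return re.compile(self.numbering_pattern)


@dataclass
class TextUnit:
    """One raw text unit (an item, an instruction paragraph, ...)."""

    text: str
    numbering_prefix: Optional[str] = None
    response_options: Optional[Sequence[str]] = None
    response_options_are_full_sentences: bool = False
    options_complete_item_sentence: bool = False

    def __post_init__(self) -> None:
        if not self.text or not self.text.strip():
            raise ValueError("TextUnit.text must be non-empty after trimming")


@dataclass
class Section:
    kind: str
    units: list[TextUnit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in SECTION_KINDS:
            raise ValueError(
                f"section kind must be one of {SECTION_KINDS}, got {self.kind!r}"
            )


@dataclass
class Questionnaire:
    """A named instrument with a target age range and its text sections."""

    name: str
    target_age_min: int
    target_age_max: int
    sections: list[Section] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.target_age_min > self.target_age_max:
            raise ValueError("target_age_min must not exceed target_age_max")
        kinds = [s.kind for s in self.sections]
        if len(kinds) != len(set(kinds)):
            raise ValueError("section kinds must be unique within a questionnaire")
        if "items" not in kinds:
            raise ValueError("a questionnaire requires an 'items' section")

    def section(self, kind: str) -> Optional[Section]:
        for s in self.sections:
            if s.kind == kind:
                return s
        return None


@dataclass
class StandardizedText:
    """Sentence-segmented text ready for lexical counting."""

    sentences: list[str]
    source_kind: str


def _ensure_terminal_punctuation(text: str) -> str:
    text = text.strip()
    if not text.endswith(TERMINAL_PUNCTUATION):
        text += "."
    return text


def _strip_numbering(text: str, policy: StandardizationPolicy) -> str:
    if not policy.strip_numbering:
        return text
    return policy.numbering_re().sub("", text, count=1)


def resolve_response_option_policy(questionnaire: Questionnaire) -> dict[int, bool]:
    """Decide, per item-set unit, whether its response options are analysed.

    Response options are included when they are full sentences rather than
    short Likert-type labels. To keep a single questionnaire internally
    consistent, if ANY unit carries full-sentence options, the options of
    every unit are included. Options that complete the item stem into a
    sentence are always folded into the stem (handled in
    :func:`standardize_section`), independent of this flag.

    Returns a mapping from unit index (within the items section) to a
    boolean "include this unit's options as standalone sentences".
    """
    items = questionnaire.section("items")
    if items is None:
        return {}
    any_full = any(
        u.response_options and u.response_options_are_full_sentences
        for u in items.units
    )
    decisions: dict[int, bool] = {}
    for i, unit in enumerate(items.units):
        has_options = bool(unit.response_options)
        decisions[i] = has_options and any_full and not unit.options_complete_item_sentence
    return decisions


def standardize_section(
    section: Section,
    policy: StandardizationPolicy = StandardizationPolicy(),
    include_options: Optional[dict[int, bool]] = None,
) -> StandardizedText:
    """Standardize one section into a list of sentences.

    Each unit has its enumeration prefix removed and a period appended if no
    terminal punctuation is present. When ``include_options`` marks a unit,
    its response options follow the item as standalone sentences; options
    flagged as completing the item sentence are concatenated onto the stem
    before the period is placed ("My health is" + "very good" ->
    "My health is very good.").
    """
    if not section.units:
        raise EmptySectionError(f"section {section.kind!r} has no analyzable text")
    include_options = include_options or {}
    sentences: list[str] = []
    for i, unit in enumerate(section.units):
        text = _strip_numbering(unit.text, policy)
        if unit.options_complete_item_sentence and unit.response_options:
            stem = text.rstrip()
            for opt in unit.response_options:
                sentences.append(_ensure_terminal_punctuation(f"{stem} {opt.strip()}"))
            continue
        sentences.append(_ensure_terminal_punctuation(text))
        if include_options.get(i):
            for opt in unit.response_options or ():
                sentences.append(_ensure_terminal_punctuation(opt))
    return StandardizedText(sentences=sentences, source_kind=section.kind)


def standardize_questionnaire(
    questionnaire: Questionnaire,
    policy: StandardizationPolicy = StandardizationPolicy(),
) -> dict[str, StandardizedText]:
    """Standardize every section, applying the response-option policy."""
    option_decisions = resolve_response_option_policy(questionnaire)
    out: dict[str, StandardizedText] = {}
    for section in questionnaire.sections:
        include = option_decisions if section.kind == "items" else None
        out[section.kind] = standardize_section(section, policy, include)
    return out


# --------------------------------------------------------------------------
# JSON dialect


def _unit_from_dict(d: dict) -> TextUnit:
    return TextUnit(
        text=d["text"],
        numbering_prefix=d.get("numbering_prefix"),
        response_options=d.get("response_options"),
        response_options_are_full_sentences=d.get(
            "response_options_are_full_sentences", False
        ),
        options_complete_item_sentence=d.get("options_complete_item_sentence", False),
    )


def questionnaire_from_dict(d: dict) -> Questionnaire:
    return Questionnaire(
        name=d["name"],
        target_age_min=int(d["target_age_min"]),
        target_age_max=int(d["target_age_max"]),
        sections=[
            Section(kind=s["kind"], units=[_unit_from_dict(u) for u in s["units"]])
            for s in d["sections"]
        ],
    )


def questionnaire_to_dict(q: Questionnaire) -> dict:
    return {
        "name": q.name,
        "target_age_min": q.target_age_min,
        "target_age_max": q.target_age_max,
        "sections": [
            {
                "kind": s.kind,
                "units": [
                    {
                        "text": u.text,
                        "numbering_prefix": u.numbering_prefix,
                        "response_options": list(u.response_options)
                        if u.response_options
                        else None,
                        "response_options_are_full_sentences": u.response_options_are_full_sentences,
                        "options_complete_item_sentence": u.options_complete_item_sentence,
                    }
                    for u in s.units
                ],
            }
            for s in q.sections
        ],
    }


def load_questionnaire(path: str | Path) -> Questionnaire:
    """Read a questionnaire from its JSON file format (UTF-8)."""
    with open(path, encoding="utf-8") as fh:
        return questionnaire_from_dict(json.load(fh))


def save_questionnaire(q: Questionnaire, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(questionnaire_to_dict(q), fh, indent=2, ensure_ascii=False)
        fh.write("\n")


def load_questionnaires(paths: Iterable[str | Path]) -> list[Questionnaire]:
    return [load_questionnaire(p) for p in paths]
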