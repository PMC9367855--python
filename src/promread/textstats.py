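"""Lexical statistics: sentences, words, letters, syllables.

Every readability formula in this package consumes only the counts gathered
here (letters per 100 words, words per sentence, syllables per word,
monosyllable and 3+-syllable incidence, percent difficult vocabulary), so
tokenization conventions are fixed in one place:

* words are whitespace-delimited tokens with surrounding punctuation
  stripped; hyphenated compounds stay one word; digit-only tokens count as
  words with 0 letters and 1 syllable per digit group;
* letters are alphabetic characters only;
* syllables come from a small exceptions lexicon first, then a vowel-group
  heuristic (a/e/i/o/u/y groups, silent final "e" except "-le", minimum 1);
* case is ignored throughout.

Classical readability formulas leave these conventions unspecified and
different software disagrees on them; the convention here is deliberate,
documented, and auditable per token.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from promread.model import StandardizedText
from promread.wordlist import EasyWordList, is_difficult

VOWELS = set("aeiouy")

#: Abbreviations that must not terminate a sentence at their period.
DEFAULT_ABBREVIATIONS = frozenset(
    {"e.g.", "i.e.", "etc.", "vs.", "dr.", "mr.", "mrs.", "ms.", "no.", "st."}
)

#: Words whose syllable count the vowel-group heuristic gets wrong.
#: Acts as the dictionary tier consulted before the heuristic.
SYLLABLE_EXCEPTIONS: dict[str, int] = {
    "every": 2,
    "everything": 3,
    "everyone": 3,
    "everybody": 4,
    "evening": 2,
    "different": 3,
    "interesting": 4,
    "family": 3,
    "science": 2,
    "quiet": 2,
    "being": 2,
    "doing": 2,
    "going": 2,
    "seeing": 2,
    "idea": 3,
    "area": 3,
    "really": 2,
    "usually": 4,
    "business": 2,
    "chocolate": 3,
    "favorite": 3,
    "favourite": 3,
}

_WORD_STRIP_RE = re.compile(r"^[^0-9A-Za-z]+|[^0-9A-Za-z]+$")
_SENT_SPLIT_RE = re.compile(r"(?<=[.!?])\s+")
_DIGIT_GROUP_RE = re.compile(r"\d+")


class UnanalyzableTextError(ValueError):
    """Raised when text contains no countable words."""


@dataclass(frozen=True)
class TokenStats:
    """All lexical counts and ratios any readability formula consumes."""

    n_words: int
    n_sentences: int
    n_letters: int
    total_syllables: int
    n_monosyllabic: int
    n_poly3: int
    n_difficult: int

    @property
    def letters_per_100_words(self) -> float:
        """L — average letters per 100 words (Coleman-Liau input)."""
        return 100.0 * self.n_letters / self.n_words

    @property
    def sentences_per_100_words(self) -> float:
        """S — average sentences per 100 words (Coleman-Liau input)."""
        return 100.0 * self.n_sentences / self.n_words

    @property
    def words_per_sentence(self) -> float:
        """ASL — average sentence length in words."""
        return self.n_words / self.n_sentences

    @property
    def syllables_per_word(self) -> float:
        """ASW — average syllables per word (Flesch-Kincaid input)."""
        return self.total_syllables / self.n_words

    @property
    def pct_difficult(self) -> float:
        """Percent of words absent from the easy list, 0-100 scale."""
        return 100.0 * self.n_difficult / self.n_words


def split_sentences(
    standardized: StandardizedText | Sequence[str],
    abbreviations: Iterable[str] = DEFAULT_ABBREVIATIONS,
) -> list[str]:
    """Split standardized units into sentences.

    Standardization already yields one unit per intended sentence; this
    re-validates and splits any unit that still holds several sentences.
    Splitting happens after terminal punctuation (., !, ?) followed by
    whitespace, except directly after a guarded abbreviation.
    """
    units = (
        standardized.sentences
        if isinstance(standardized, StandardizedText)
        else list(standardized)
    )
    guard = {a.lower() for a in abbreviations}
    sentences: list[str] = []
    for unit in units:
        parts = _SENT_SPLIT_RE.split(unit.strip())
        merged: list[str] = []
        for part in parts:
            if not part:
                continue
            if merged:
                last_token = merged[-1].rsplit(None, 1)[-1].lower()
                if last_token in guard:
                    merged[-1] = merged[-1] + " " + part
                    continue
            merged.append(part)
        sentences.extend(s for s in merged if s.strip())
    return sentences


def tokenize_words(sentence: str) -> list[str]:
    """Whitespace-split, then strip surrounding punctuation from each token.

    Hyphenated compounds remain a single token ("self-esteem"); tokens of
    digits only are kept as words ("aged 8 years" -> 3 words).
    """
    tokens = []
    for raw in sentence.split():
        token = _WORD_STRIP_RE.sub("", raw)
        if token:
            tokens.append(token)
    return tokens


def count_letters(word: str) -> int:
    """Alphabetic characters only; hyphens, apostrophes and digits excluded."""
    return sum(1 for ch in word if ch.isalpha())


def _vowel_group_count(word: str) -> int:
    groups = 0
    prev_vowel = False
    for ch in word:
        vowel = ch in VOWELS
        if vowel and not prev_vowel:
            groups += 1
        prev_vowel = vowel
    return groups


def _heuristic_syllables(word: str) -> int:
    """Vowel-group count with a silent final "e" correction, minimum 1.

    A final "e" is dropped unless the word ends in consonant+"le"
    ("little", "table"), where the "e" carries the syllable.
    """
    n = _vowel_group_count(word)
    if word.endswith("e") and not word.endswith(("ae", "ee", "ie", "oe", "ue", "ye")):
        keeps_le = (
            len(word) >= 3
            and word.endswith("le")
            and word[-3] not in VOWELS
        )
        if not keeps_le and n > 1:
            n -= 1
    return max(n, 1)


def count_syllables(
    word: str, exceptions: Optional[dict[str, int]] = None
) -> int:
    """Syllables in a token: exceptions lexicon first, heuristic fallback.

    Hyphenated compounds sum their parts. A group of digits counts as one
    syllable ("8" -> 1, "2022" -> 1); tokens mixing digits and letters sum
    digit groups and alphabetic runs.
    """
    if not word:
        raise ValueError("cannot count syllables of an empty token")
    lexicon = SYLLABLE_EXCEPTIONS if exceptions is None else exceptions
    word = word.lower()
    if "-" in word:
        return sum(count_syllables(part, lexicon) for part in word.split("-") if part)
    if word in lexicon:
        return lexicon[word]
    digit_groups = len(_DIGIT_GROUP_RE.findall(word))
    alpha = "".join(ch for ch in word if ch.isalpha())
    if not alpha:
        return max(digit_groups, 1)
    return digit_groups + _heuristic_syllables(alpha)


def syllable_source(word: str) -> str:
    """Name the syllable-count source for a token (for audit logs)."""
    w = word.lower()
    if any(part in SYLLABLE_EXCEPTIONS for part in w.split("-")):
        return "lexicon"
    if not any(ch.isalpha() for ch in w):
        return "digits"
    return "heuristic"


def compute_text_stats(
    standardized: StandardizedText | Sequence[str],
    easy: EasyWordList,
    abbreviations: Iterable[str] = DEFAULT_ABBREVIATIONS,
) -> TokenStats:
    """Gather every lexical count from standardized text in one pass."""
    sentences = split_sentences(standardized, abbreviations)
    n_words = n_letters = total_syll = n_mono = n_poly3 = n_diff = 0
    for sentence in sentences:
        for token in tokenize_words(sentence):
            n_words += 1
            n_letters += count_letters(token)
            syll = count_syllables(token)
            total_syll += syll
            if syll == 1:
                n_mono += 1
            if syll >= 3:
                n_poly3 += 1
            if is_difficult(token, easy):
                n_diff += 1
    if n_words == 0:
        raise UnanalyzableTextError("no countable words in text")
    return TokenStats(
        n_words=n_words,
        n_sentences=len(sentences),
        n_letters=n_letters,
        total_syllables=total_syll,
        n_monosyllabic=n_mono,
        n_poly3=n_poly3,
        n_difficult=n_diff,
    )


def token_audit(
    standardized: StandardizedText | Sequence[str], easy: EasyWordList
) -> list[dict]:
    """Per-token audit rows: letters, syllables, source, difficulty."""
    rows = []
    for sentence_idx, sentence in enumerate(split_sentences(standardized)):
        for token in tokenize_words(sentence):
            rows.append(
                {
                    "sentence": sentence_idx,
                    "token": token,
                    "letters": count_letters(token),
                    "syllables": count_syllables(token),
                    "syllable_source": syllable_source(token),
                    "difficult": is_difficult(token, easy),
                }
            )
    return rows
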