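"""Easy-word lists and the morphologically expanded difficulty test.

Dale-Chall-style readability defines a "difficult" word by absence from a
fixed list of words familiar to young readers. Such base lists carry only
stem forms, so a literal membership test misclassifies everyday inflections
("things", "writes", "wrote"). The expansion implemented here adds, for
every base word, the regular plural / third-person form, the past tense,
and the gerund, plus irregular forms from a bundled table — the rationale
being that these derivations are not considerably less familiar than their
stem.

Matching is surface-form: an input token is lowercased, stripped of
punctuation and tested against the expanded list. Digit-only tokens are
never difficult (numerals are not vocabulary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

VOWELS = set("aeiou")
_SIBILANT_ENDINGS = ("s", "x", "z", "ch", "sh")


@dataclass(frozen=True)
class EasyWordList:
    """A base easy-word list plus its deterministic morphological expansion."""

    base_words: frozenset[str]
    expanded_words: frozenset[str]
    irregular_forms: Mapping[str, frozenset[str]] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.base_words <= self.expanded_words:
            raise ValueError("base_words must be a subset of expanded_words")

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.expanded_words

    def __len__(self) -> int:
        return len(self.expanded_words)


def _is_cvc_monosyllable(word: str) -> bool:
    """Consonant-vowel-consonant ending on a short word: doubling applies."""
    if len(word) < 3:
        return False
    c1, v, c2 = word[-3], word[-2], word[-1]
    if c1 in VOWELS or v not in VOWELS or c2 in VOWELS:
        return False
    if c2 in "wxy":
        return False
    # one vowel group == monosyllable for the short stems this rule targets
    groups = 0
    prev = False
    for ch in word:
        is_v = ch in VOWELS or ch == "y"
        if is_v and not prev:
            groups += 1
        prev = is_v
    return groups == 1


def inflect(word: str) -> set[str]:
    """Regular inflected forms of one base word.

    Plural / third-person: +s; +es after s, x, z, ch, sh; consonant+y -> ies.
    Past: +ed with final-e drop; consonant+y -> ied.
    Gerund: +ing with final-e drop.
    CVC monosyllables double the final consonant before -ed/-ing.
    """
    w = word.lower()
    forms: set[str] = set()
    # plural / 3rd person singular
    if w.endswith(_SIBILANT_ENDINGS):
        forms.add(w + "es")
    elif w.endswith("y") and len(w) > 1 and w[-2] not in VOWELS:
        forms.add(w[:-1] + "ies")
    else:
        forms.add(w + "s")
    # past tense and gerund
    if w.endswith("e"):
        forms.add(w + "d")
        forms.add(w[:-1] + "ing")
    elif w.endswith("y") and len(w) > 1 and w[-2] not in VOWELS:
        forms.add(w[:-1] + "ied")
        forms.add(w + "ing")
    elif _is_cvc_monosyllable(w):
        forms.add(w + w[-1] + "ed")
        forms.add(w + w[-1] + "ing")
    else:
        forms.add(w + "ed")
        forms.add(w + "ing")
    return forms


def expand_easy_list(
    base: Iterable[str],
    irregulars: Optional[Mapping[str, Iterable[str]]] = None,
    provenance: str = "",
) -> EasyWordList:
    """Build an :class:`EasyWordList` from base words and an irregular table.

    Expansion is applied to base words only (never re-applied to generated
    forms), is deterministic, and never removes a base word. Irregular
    entries whose base is absent from the list are ignored, so one shipped
    irregular table serves lists of any size.
    """
    base_set = frozenset(w.strip().lower() for w in base if w.strip())
    if not base_set:
        raise ValueError("base word list is empty")
    irregulars = irregulars or {}
    expanded: set[str] = set(base_set)
    for word in base_set:
        expanded |= inflect(word)
        for form in irregulars.get(word, ()):
            expanded.add(form.strip().lower())
    return EasyWordList(
        base_words=base_set,
        expanded_words=frozenset(expanded),
        irregular_forms={
            b: frozenset(f.lower() for f in forms)
            for b, forms in irregulars.items()
        },
        provenance=provenance,
    )


def _normalize_token(token: str) -> str:
    return "".join(ch for ch in token.lower() if ch.isalnum() or ch in "-'")


def is_difficult(token: str, easy: EasyWordList) -> bool:
    """True when a token is absent from the expanded easy list.

    Digit-only tokens are familiar by definition. A hyphenated compound is
    easy when the whole form, or every hyphen-separated part, is listed.
    Possessive "'s" is stripped before lookup.
    """
    word = _normalize_token(token)
    if not word:
        return False
    if word.replace("-", "").isdigit():
        return False
    if word.endswith("'s"):
        word = word[:-2]
    if word in easy.expanded_words:
        return False
    if "-" in word:
        parts = [p for p in word.split("-") if p]
        if parts and all(not is_difficult(p, easy) for p in parts):
            return False
    return True


def percent_difficult(tokens: Iterable[str], easy: EasyWordList) -> float:
    """100 x (difficult words / total words) over already-tokenized words."""
    tokens = list(tokens)
    if not tokens:
        raise ValueError("cannot compute percent difficult of zero words")
    n_diff = sum(1 for t in tokens if is_difficult(t, easy))
    return 100.0 * n_diff / len(tokens)


# --------------------------------------------------------------------------
# File formats and bundled data


def read_word_file(path: str | Path) -> list[str]:
    """One word per line; '#' starts a comment; blank lines ignored."""
    words = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            word = line.split("#", 1)[0].strip()
            if word:
                words.append(word.lower())
    return words


def read_irregulars_file(path: str | Path) -> dict[str, set[str]]:
    """Two whitespace-separated columns: base form, extra form."""
    table: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"expected 'base form' pairs, got: {line!r}")
            table.setdefault(parts[0].lower(), set()).add(parts[1].lower())
    return table


def _data_path(name: str) -> Path:
    return Path(str(resources.files("promread").joinpath("data", name)))


def load_default_easy_list() -> EasyWordList:
    """The bundled synthetic Dale-Chall-style list, expanded with the
    bundled irregular-forms table.

    The list is a curated stand-in of common English words in the spirit of
    classic easy-word vocabularies (the historical lists are licensed); no
    analysis in this package depends on one particular list version.
    """
    base = read_word_file(_data_path("easy_words_synthetic.txt"))
    irregulars = read_irregulars_file(_data_path("irregular_forms.txt"))
    return expand_easy_list(
        base, irregulars, provenance="promread bundled synthetic easy list v1"
    )
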