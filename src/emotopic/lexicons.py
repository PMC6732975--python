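"""Word-emotion and word-happiness lexicons.

Two flat-file formats are supported:

* **EmoLex format** — one association per line, ``word<TAB>category<TAB>flag``
  with ``flag`` in {0, 1} and ``category`` one of the ten fixed categories
  (eight Plutchik emotions plus *negative*/*positive*). Only flag-1 lines
  create associations; a word whose flags are all zero is simply absent.
* **labMT format** — delimited rows carrying a word and its mean happiness
  score on the 1–9 scale. Accepted layouts: ``word score``,
  ``word rank score`` or ``word rank score sd`` (only word and score are
  consumed); an optional non-numeric header row is skipped.

Lookups are case-insensitive and expect lemmatized forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from emotopic.constants import CATEGORIES
from emotopic.errors import FormatError, RangeError


@dataclass(frozen=True)
class EmotionLexicon:
    """Mapping word -> subset of the 10 fixed categories (binary membership)."""

    associations: Mapping[str, frozenset[str]]

    def categories(self, word: str) -> frozenset[str]:
        return self.associations.get(word.lower(), frozenset())

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.associations

    def __len__(self) -> int:
        return len(self.associations)

    def words(self, category: str | None = None) -> list[str]:
        if category is None:
            return sorted(self.associations)
        return sorted(w for w, cats in self.associations.items() if category in cats)


@dataclass(frozen=True)
class HappinessLexicon:
    """Mapping word -> mean happiness score in [1, 9]."""

    scores: Mapping[str, float]

    def score(self, word: str) -> float | None:
        return self.scores.get(word.lower())

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.scores

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def min_score(self) -> float:
        return min(self.scores.values())

    @property
    def max_score(self) -> float:
        return max(self.scores.values())


def load_emotion_lexicon(path: str | Path) -> EmotionLexicon:
    """Parse an EmoLex flat file.

    Raises
    ------
    FormatError
        On an unknown category name, a non-binary flag, a malformed line, or
        duplicate (word, category) lines with conflicting flags.
    """
    seen: dict[tuple[str, str], int] = {}
    assoc: dict[str, set[str]] = {}
    for lineno, line in enumerate(_lines(path), start=1):
        parts = line.split()
        if len(parts) != 3:
            raise FormatError(f"{path}:{lineno}: expected 'word category flag', got {line!r}")
        word, category, flag_s = parts
        word = word.lower()
        if category not in CATEGORIES:
            raise FormatError(f"{path}:{lineno}: unknown category {category!r}")
        if flag_s not in ("0", "1"):
            raise FormatError(f"{path}:{lineno}: non-binary flag {flag_s!r}")
        flag = int(flag_s)
        key = (word, category)
        if key in seen and seen[key] != flag:
            raise FormatError(
                f"{path}:{lineno}: conflicting duplicate for {word!r}/{category}"
            )
        seen[key] = flag
        if flag == 1:
            assoc.setdefault(word, set()).add(category)
    return EmotionLexicon({w: frozenset(c) for w, c in assoc.items()})


def write_emotion_lexicon(lexicon: EmotionLexicon, path: str | Path) -> None:
    """Write EmoLex flat format (flag-1 lines only, sorted for determinism)."""
    with open(path, "w", encoding="utf-8") as fh:
        for word in sorted(lexicon.associations):
            for category in sorted(lexicon.associations[word]):
                fh.write(f"{word}\t{category}\t1\n")


def load_happiness_lexicon(path: str | Path) -> HappinessLexicon:
    """Parse a labMT-style delimited file.

    Raises
    ------
    RangeError
        If a score lies outside [1, 9]; the message names the word.
    FormatError
        On rows that are not 2–4 columns or carry a non-numeric score.
    """
    scores: dict[str, float] = {}
    for lineno, line in enumerate(_lines(path), start=1):
        parts = line.split()
        if not 2 <= len(parts) <= 4:
            raise FormatError(f"{path}:{lineno}: expected 2-4 columns, got {line!r}")
        word = parts[0].lower()
        raw = parts[1] if len(parts) == 2 else parts[2]
        try:
            value = float(raw)
        except ValueError:
            if lineno == 1:  # header row
                continue
            raise FormatError(f"{path}:{lineno}: non-numeric score {raw!r}") from None
        if not 1.0 <= value <= 9.0:
            raise RangeError(f"{path}:{lineno}: score {value} for word {word!r} outside [1, 9]")
        scores[word] = value
    return HappinessLexicon(scores)


def write_happiness_lexicon(lexicon: HappinessLexicon, path: str | Path) -> None:
    """Write labMT-style rows ``word<TAB>rank<TAB>score`` (rank by descending score)."""
    ordered = sorted(lexicon.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("word\trank\thappiness_average\n")
        for rank, (word, value) in enumerate(ordered, start=1):
            fh.write(f"{word}\t{rank}\t{value!r}\n")


def _lines(path: str | Path) -> Iterable[str]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield line
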