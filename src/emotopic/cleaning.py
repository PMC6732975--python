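"""Deterministic text normalization for microblog posts.

The pipeline applies, in this fixed order:

1. lowercase;
2. replace every ``@``-prefixed user mention with the literal token
   ``"@user"`` (anonymization that still records that *someone* was
   addressed);
3. remove URLs;
4. remove ASCII punctuation;
5. remove remaining non-alphanumeric characters (emoji, typographic
   punctuation, control characters);
6. whitespace tokenization;
7. stopword removal;
8. lemmatization by table lookup.

Mentions are normalized *before* punctuation stripping so the ``@`` of
``"@user"`` survives; it is the single sanctioned exception to the rule that
tokens contain no punctuation. Lemmatization is a plain word→lemma table
(shipped default covers common English inflections) so output is
reproducible bit for bit; no statistical lemmatizer is involved.
"""

from __future__ import annotations

import re
import string
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

MENTION_TOKEN = "@user"
# Private-use sentinel char: survives the punctuation and non-alphanumeric
# sweeps, restored to "@user" at tokenization time.
_SENTINEL_CHAR = "\ue000"
_SENTINEL = _SENTINEL_CHAR + "user"

_MENTION_RE = re.compile(r"(?<!\w)@\w+")
_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)")
_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


def _keep_char(ch: str) -> bool:
    return ch.isalnum() or ch.isspace() or ch == _SENTINEL_CHAR


def clean_text(
    raw_text: str,
    stopwords: Iterable[str] | None = None,
    lemma_table: Mapping[str, str] | None = None,
) -> list[str]:
    """Normalize ``raw_text`` into a token list.

    Degenerate inputs (empty strings, pure punctuation/emoji) yield an empty
    list rather than an error. The operation is idempotent: cleaning the
    space-joined output again returns the same tokens.

    Parameters
    ----------
    raw_text
        Any unicode string.
    stopwords
        Words removed after tokenization; defaults to the packaged list.
    lemma_table
        word→lemma lookup applied last; defaults to the packaged table.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    stop = stopwords if isinstance(stopwords, (set, frozenset)) else frozenset(stopwords)
    if lemma_table is None:
        lemma_table = default_lemmas()

    text = raw_text.lower()
    text = _MENTION_RE.sub(_SENTINEL, text)
    text = _URL_RE.sub(" ", text)
    text = text.translate(_PUNCT_TABLE)
    text = "".join(ch for ch in text if _keep_char(ch))
    tokens = []
    for tok in text.split():
        if tok == _SENTINEL:
            tok = MENTION_TOKEN
        if tok in stop:
            continue
        tokens.append(lemma_table.get(tok, tok))
    return tokens


def _read_packaged(name: str) -> str:
    return resources.files("emotopic.data").joinpath(name).read_text(encoding="utf-8")


@lru_cache(maxsize=1)
def default_stopwords() -> frozenset[str]:
    """The packaged English stopword list (one word per line, '#' comments)."""
    words = []
    for line in _read_packaged("stopwords.txt").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.append(line)
    return frozenset(words)


@lru_cache(maxsize=1)
def default_lemmas() -> dict[str, str]:
    """The packaged word→lemma table (TSV: inflected form, lemma)."""
    table: dict[str, str] = {}
    for line in _read_packaged("lemmas.tsv").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        form, lemma = line.split("\t")
        table[form] = lemma
    return table


def join_tokens(tokens: Sequence[str]) -> str:
    """Inverse-ish of tokenization, used to express the idempotence property."""
    return " ".join(tokens)
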