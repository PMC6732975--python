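"""Hedonometer-style word-happiness averaging.

Each word carries a crowd-rated mean happiness score on a 1-9 scale; the
happiness of a text is the frequency-weighted mean of its matched words'
scores. An optional "lens" excludes near-neutral words (those with
5 - delta < h < 5 + delta); the default delta of 0 keeps every matched word,
because downstream topic/cluster happiness summaries include mid-scale
vocabulary.

Daily aggregation pools at the *word* level: a day's score is the mean over
all matched word occurrences across that day's tweets, not a mean of
per-tweet means, so wordier tweets weigh more. A per-user variant (average
per user within a day, then across users) is available via ``per_user``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from emotopic.corpus import Corpus
from emotopic.errors import ParameterError
from emotopic.lexicons import HappinessLexicon

_STRATIFIED = ("woman", "man")


def _matched_scores(
    tokens: Iterable[str], lexicon: HappinessLexicon, lens_delta: float
) -> list[float]:
    if lens_delta < 0 or lens_delta >= 4:
        raise ParameterError(
            f"lens_delta must be in [0, 4), got {lens_delta}"
        )
    lo, hi = 5.0 - lens_delta, 5.0 + lens_delta
    out = []
    for token in tokens:
        h = lexicon.score(token)
        if h is None:
            continue
        if lens_delta > 0 and lo < h < hi:
            continue
        out.append(h)
    return out


def tweet_happiness(
    tokens: Sequence[str], lexicon: HappinessLexicon, lens_delta: float = 0.0
) -> float:
    """Frequency-weighted mean happiness of a token list; NaN if no match."""
    scores = _matched_scores(tokens, lexicon, lens_delta)
    if not scores:
        return math.nan
    return float(np.mean(scores))


def daily_series(
    corpus: Corpus,
    lexicon: HappinessLexicon,
    lens_delta: float = 0.0,
    per_user: bool = False,
) -> pd.DataFrame:
    """Mean happiness by calendar day (UTC) and gender.

    Long format: date (YYYY-MM-DD), gender, mean, n_words. Days with zero
    matched words are absent. With ``per_user=True`` the day mean averages
    per-user means instead of pooling word occurrences.
    """
    records = []
    for tweet in corpus:
        gender = corpus.gender_of(tweet)
        if gender not in _STRATIFIED:
            continue
        scores = _matched_scores(tweet.tokens, lexicon, lens_delta)
        if not scores:
            continue
        day = tweet.timestamp.strftime("%Y-%m-%d")
        records.append(
            {
                "date": day,
                "gender": gender,
                "user_id": tweet.user_id,
                "sum": float(np.sum(scores)),
                "n": len(scores),
            }
        )
    if not records:
        return pd.DataFrame(columns=["date", "gender", "mean", "n_words"])
    frame = pd.DataFrame.from_records(records)
    if per_user:
        per = (
            frame.groupby(["date", "gender", "user_id"], sort=True)
            .agg(total=("sum", "sum"), n=("n", "sum"))
            .reset_index()
        )
        per["user_mean"] = per["total"] / per["n"]
        out = (
            per.groupby(["date", "gender"], sort=True)
            .agg(mean=("user_mean", "mean"), n_words=("n", "sum"))
            .reset_index()
        )
    else:
        out = (
            frame.groupby(["date", "gender"], sort=True)
            .agg(total=("sum", "sum"), n_words=("n", "sum"))
            .reset_index()
        )
        out["mean"] = out["total"] / out["n_words"]
        out = out[["date", "gender", "mean", "n_words"]]
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class SetHappiness:
    """Unweighted happiness summary of a word set."""

    mean: float
    sd: float
    n: int
    n_unmatched: int

    @property
    def defined(self) -> bool:
        return self.n > 0


def set_happiness(
    words: Sequence[str], lexicon: HappinessLexicon, lens_delta: float = 0.0
) -> SetHappiness:
    """Mean and sample SD of the matched words' scores (each word once).

    ``sd`` is the n-1 sample standard deviation, 0 when a single word
    matches; with no matches the summary is missing (NaN mean, n = 0).
    """
    scores = _matched_scores(words, lexicon, lens_delta)
    n_unmatched = len(words) - len(scores) if lens_delta == 0 else len(
        [w for w in words if w.lower() not in lexicon.scores]
    )
    if not scores:
        return SetHappiness(math.nan, math.nan, 0, n_unmatched)
    mean = float(np.mean(scores))
    sd = 0.0 if len(scores) == 1 else float(np.std(scores, ddof=1))
    return SetHappiness(mean, sd, len(scores), n_unmatched)
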