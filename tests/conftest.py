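"""Shared fixtures: toy lexicons and corpora built in memory."""

from __future__ import annotations

from datetime import datetime, timezone

import pytest

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass

from emotopic.corpus import Corpus, Tweet, UserRecord
from emotopic.lexicons import EmotionLexicon, HappinessLexicon


@pytest.fixture
def toy_emotion_lexicon() -> EmotionLexicon:
    return EmotionLexicon(
        {
            "good": frozenset({"joy", "positive"}),
            "bad": frozenset({"sadness", "negative"}),
            "dread": frozenset({"fear", "negative"}),
            "cake": frozenset({"joy", "anticipation", "positive"}),
            "trusty": frozenset({"trust", "positive"}),
        }
    )


@pytest.fixture
def toy_happiness_lexicon() -> HappinessLexicon:
    return HappinessLexicon(
        {"love": 8.42, "happy": 8.3, "stroke": 2.58, "park": 5.5, "sad": 2.38}
    )


def make_tweet(i, uid, text, tokens=None, when="2018-06-01T12:00:00"):
    ts = datetime.fromisoformat(when).replace(tzinfo=timezone.utc)
    return Tweet(
        tweet_id=f"t{i}",
        user_id=uid,
        timestamp=ts,
        raw_text=text,
        tokens=tuple(tokens) if tokens is not None else (),
    )


def make_corpus(rows, genders=None):
    """rows: (uid, token list[, iso timestamp]) tuples; genders: uid -> gender."""
    genders = genders or {}
    tweets = []
    for i, row in enumerate(rows):
        uid, tokens = row[0], row[1]
        when = row[2] if len(row) > 2 else "2018-06-01T12:00:00"
        tweets.append(make_tweet(i, uid, " ".join(tokens), tokens, when))
    users = {
        uid: UserRecord(user_id=uid, gender=genders.get(uid, "unknown"))
        for uid in {t.user_id for t in tweets}
    }
    return Corpus(tuple(tweets), users)


@pytest.fixture
def two_gender_corpus(toy_emotion_lexicon):
    rows = [
        ("w1", ["good", "good", "cake"]),
        ("w1", ["good", "bad"]),
        ("w2", ["cake", "trusty", "plain"]),
        ("m1", ["bad", "dread"]),
        ("m1", ["bad", "good"]),
        ("m2", ["dread", "dread", "plain"]),
    ]
    return make_corpus(rows, {"w1": "woman", "w2": "woman", "m1": "man", "m2": "man"})
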