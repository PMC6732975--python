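"""Corpus data model and readers/writers.

A :class:`Corpus` couples a tweet collection with a user-metadata table
(gender label, country, lifetime activity, curated-list memberships).
Supported on-disk layouts:

* tweets as JSON-lines (one object per line: ``tweet_id``, ``user_id``,
  ``timestamp`` in ISO-8601 UTC, ``text``) or as CSV/TSV with the same
  columns;
* users as CSV/TSV with columns ``user_id``, ``gender``, and optionally
  ``country``, ``lifetime_tweet_count``, ``follower_count``,
  ``list_memberships`` (semicolon-separated list identifiers).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from emotopic.cleaning import clean_text
from emotopic.constants import GENDERS
from emotopic.errors import FormatError, ReferentialIntegrityError

_TWEET_FIELDS = ("tweet_id", "user_id", "timestamp", "text")


@dataclass(frozen=True)
class Tweet:
    """One microblog post; ``tokens`` is empty until the text is cleaned."""

    tweet_id: str
    user_id: str
    timestamp: datetime
    raw_text: str
    tokens: tuple[str, ...] = ()

    def cleaned(self, stopwords=None, lemma_table=None) -> "Tweet":
        return replace(
            self, tokens=tuple(clean_text(self.raw_text, stopwords, lemma_table))
        )


@dataclass(frozen=True)
class UserRecord:
    """Author metadata; ``gender`` is one of woman / man / unknown."""

    user_id: str
    gender: str = "unknown"
    country: str | None = None
    lifetime_tweet_count: int = 0
    follower_count: int = 0
    list_memberships: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.gender not in GENDERS:
            raise FormatError(
                f"gender must be one of {GENDERS}, got {self.gender!r}"
            )


@dataclass(frozen=True)
class Corpus:
    """A tweet collection plus its user table, referentially intact."""

    tweets: tuple[Tweet, ...]
    users: Mapping[str, UserRecord]

    def __post_init__(self):
        for tweet in self.tweets:
            if tweet.user_id not in self.users:
                raise ReferentialIntegrityError(
                    f"tweet {tweet.tweet_id!r} references unknown user "
                    f"{tweet.user_id!r}"
                )

    def __len__(self) -> int:
        return len(self.tweets)

    def __iter__(self) -> Iterator[Tweet]:
        return iter(self.tweets)

    def gender_of(self, tweet: Tweet) -> str:
        return self.users[tweet.user_id].gender

    def cleaned(self, stopwords=None, lemma_table=None) -> "Corpus":
        """Return a copy with every tweet's tokens populated."""
        return Corpus(
            tuple(t.cleaned(stopwords, lemma_table) for t in self.tweets),
            self.users,
        )

    def subset(self, predicate) -> "Corpus":
        return Corpus(tuple(t for t in self.tweets if predicate(t)), self.users)


def parse_timestamp(value: str) -> datetime:
    """ISO-8601, with 'Z' accepted; naive stamps are taken as UTC."""
    ts = datetime.fromisoformat(value.replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def load_users(path: str | Path) -> dict[str, UserRecord]:
    """Read a user table from CSV/TSV (delimiter sniffed from the header)."""
    with open(path, encoding="utf-8", newline="") as fh:
        first = fh.readline()
        if not first:
            return {}
        delim = "\t" if "\t" in first else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or "user_id" not in reader.fieldnames:
            raise FormatError(f"{path}: user table missing required field 'user_id'")
        users: dict[str, UserRecord] = {}
        for row in reader:
            lists = row.get("list_memberships") or ""
            users[row["user_id"]] = UserRecord(
                user_id=row["user_id"],
                gender=(row.get("gender") or "unknown").strip().lower(),
                country=(row.get("country") or None),
                lifetime_tweet_count=int(row.get("lifetime_tweet_count") or 0),
                follower_count=int(row.get("follower_count") or 0),
                list_memberships=frozenset(x for x in lists.split(";") if x),
            )
    return users


def load_corpus(
    path: str | Path,
    format: str = "jsonl",
    users_path: str | Path | None = None,
) -> Corpus:
    """Load tweets (JSONL or delimited) plus an optional user table.

    Without ``users_path`` a stub gender-unknown record is synthesized per
    author; with one, every tweet's ``user_id`` must resolve
    (:class:`ReferentialIntegrityError` otherwise). Row order is preserved.
    """
    if format == "jsonl":
        rows = _read_jsonl(path)
    elif format == "delimited":
        rows = _read_delimited(path)
    else:
        raise FormatError(f"unknown corpus format {format!r}")

    tweets = []
    for lineno, row in rows:
        missing = [f for f in _TWEET_FIELDS if f not in row or row[f] in (None, "")]
        if missing:
            raise FormatError(f"{path}:{lineno}: missing required field(s) {missing}")
        tweets.append(
            Tweet(
                tweet_id=str(row["tweet_id"]),
                user_id=str(row["user_id"]),
                timestamp=parse_timestamp(str(row["timestamp"])),
                raw_text=str(row["text"]),
            )
        )

    if users_path is not None:
        users = load_users(users_path)
    else:
        users = {
            uid: UserRecord(user_id=uid)
            for uid in dict.fromkeys(t.user_id for t in tweets)
        }
    return Corpus(tuple(tweets), users)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write tweets as JSON-lines (ISO-8601 UTC timestamps)."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in corpus.tweets:
            fh.write(
                json.dumps(
                    {
                        "tweet_id": t.tweet_id,
                        "user_id": t.user_id,
                        "timestamp": t.timestamp.strftime("%Y-%m-%dT%H:%M:%SZ"),
                        "text": t.raw_text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def write_users(users: Mapping[str, UserRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "user_id",
                "gender",
                "country",
                "lifetime_tweet_count",
                "follower_count",
                "list_memberships",
            ]
        )
        for uid in sorted(users):
            u = users[uid]
            writer.writerow(
                [
                    u.user_id,
                    u.gender,
                    u.country or "",
                    u.lifetime_tweet_count,
                    u.follower_count,
                    ";".join(sorted(u.list_memberships)),
                ]
            )


def _read_jsonl(path: str | Path) -> Iterable[tuple[int, dict]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                out.append((lineno, json.loads(line)))
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}:{lineno}: invalid JSON ({exc})") from None
    return out


def _read_delimited(path: str | Path) -> Iterable[tuple[int, dict]]:
    with open(path, encoding="utf-8", newline="") as fh:
        first = fh.readline()
        if not first.strip():
            return []
        delim = "\t" if "\t" in first else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        return [(i, dict(row)) for i, row in enumerate(reader, start=2)]
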