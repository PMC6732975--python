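"""Synthetic microblog corpora with recorded ground truth.

The generator emulates the statistical structure the analysis assumes so
that every pipeline stage can be exercised and validated offline:

* two author groups (women / men) with per-group emission probabilities
  pi(g, c) for each of the ten emotion/sentiment categories — the defaults
  plant the field's reported direction (women elevated on joy, trust,
  anticipation and positive; men on fear, sadness, disgust and negative);
* K planted topics over disjoint topic-word blocks, with gender-shifted
  Dirichlet prevalence;
* neutral filler words absorbing the remaining emission mass;
* per-word happiness scores following a category profile (positive
  categories near 7, negative near 3, neutral near 5 on the 1-9 scale);
* timestamps uniform over a multi-year window.

Each token is drawn either from an emotion category (probability
pi(g, c), uniform within the category's word list) or from the remaining
mass, which is split between the author's active planted topic
(``topic_token_rate``) and neutral fillers. Every planted parameter and
every token's provenance are recorded in :class:`SyntheticGroundTruth` for
recovery tests. Word forms are synthetic (``joy012``, ``t3w005``,
``fill017``): lowercase, punctuation-free and disjoint from the packaged
stopword list, so the cleaning pipeline is the identity on them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from emotopic.constants import CATEGORIES
from emotopic.corpus import Corpus, Tweet, UserRecord
from emotopic.errors import ParameterError
from emotopic.lexicons import EmotionLexicon, HappinessLexicon

#: categories whose words also carry the matching sentiment label
_POSITIVE_COUPLED = ("anticipation", "joy", "trust")
_NEGATIVE_COUPLED = ("anger", "disgust", "fear", "sadness")

_DEFAULT_PI = {
    "woman": {
        "anger": 0.02, "anticipation": 0.03, "disgust": 0.015, "fear": 0.015,
        "joy": 0.03, "sadness": 0.015, "surprise": 0.02, "trust": 0.03,
        "negative": 0.015, "positive": 0.03,
    },
    "man": {
        "anger": 0.02, "anticipation": 0.02, "disgust": 0.03, "fear": 0.03,
        "joy": 0.02, "sadness": 0.03, "surprise": 0.02, "trust": 0.02,
        "negative": 0.03, "positive": 0.02,
    },
}

_DEFAULT_HAPPINESS_PROFILE = {
    "anticipation": 7.0, "joy": 7.0, "trust": 7.0, "positive": 7.0,
    "anger": 3.0, "disgust": 3.0, "fear": 3.0, "sadness": 3.0, "negative": 3.0,
    "surprise": 5.0, "filler": 5.0, "topic": 5.0,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Planted study conditions for a synthetic corpus."""

    n_users_per_gender: int = 200
    tweets_per_user: int = 50
    start: str = "2007-08-01"
    end: str = "2018-12-01"
    words_per_category: int = 30
    n_fillers: int = 100
    topic_words_per_topic: int = 40
    K_true: int = 5
    topic_concentration: float = 5.0  # total Dirichlet mass over topics
    #: women's mean topic-prevalence shift per topic (sums to ~0); men get -shift
    women_topic_shift: tuple[float, ...] | None = None
    pi: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(c) for g, c in _DEFAULT_PI.items()}
    )
    topic_token_rate: float = 0.5  # share of non-emotion mass that is topical
    mean_tokens_per_tweet: float = 12.0
    happiness_profile: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_HAPPINESS_PROFILE)
    )
    happiness_sd: float = 0.4
    sentiment_coupling: bool = True
    emotion_topic_overlap: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_users_per_gender < 1 or self.tweets_per_user < 1:
            raise ParameterError("need at least one user and one tweet per user")
        if self.K_true < 1 or self.topic_words_per_topic < 1:
            raise ParameterError("need K_true >= 1 with a non-empty word block")
        if self.words_per_category < 1 or self.n_fillers < 1:
            raise ParameterError("vocabulary sizes must be positive")
        if not 0 <= self.topic_token_rate <= 1:
            raise ParameterError("topic_token_rate must lie in [0, 1]")
        for g in ("woman", "man"):
            rates = self.pi.get(g)
            if rates is None or set(rates) != set(CATEGORIES):
                raise ParameterError(f"pi[{g!r}] must cover all 10 categories")
            total = sum(rates.values())
            if any(v < 0 for v in rates.values()) or total > 1:
                raise ParameterError(
                    f"pi[{g!r}] must be nonnegative and sum to <= 1 (got {total})"
                )
        for v in self.happiness_profile.values():
            if not 1 <= v <= 9:
                raise ParameterError("happiness profile means must lie in [1, 9]")
        if self.women_topic_shift is not None and len(self.women_topic_shift) != self.K_true:
            raise ParameterError("women_topic_shift must have K_true entries")


@dataclass
class SyntheticGroundTruth:
    """Planted parameters and per-token provenance of a generated corpus."""

    config: SyntheticConfig
    vocab: tuple[str, ...]
    topic_word: np.ndarray  # K_true x V planted distributions
    doc_gender: tuple[str, ...]
    doc_theta: np.ndarray  # D x K_true planted proportions
    provenance: tuple[tuple[str, ...], ...]  # per doc, per token: "cat:joy"/"topic:3"/"filler"
    emotion_lexicon: EmotionLexicon
    happiness_lexicon: HappinessLexicon
    expected_gender_happiness: dict[str, float]

    def to_json(self) -> str:
        payload = {
            "config": dataclasses.asdict(self.config),
            "vocab": list(self.vocab),
            "topic_word": self.topic_word.tolist(),
            "doc_gender": list(self.doc_gender),
            "doc_theta": self.doc_theta.tolist(),
            "provenance": [list(p) for p in self.provenance],
            "expected_gender_happiness": self.expected_gender_happiness,
        }
        return json.dumps(payload)


def _category_words(config: SyntheticConfig) -> dict[str, list[str]]:
    words: dict[str, list[str]] = {}
    for cat in CATEGORIES:
        words[cat] = [f"{cat}{i:03d}" for i in range(config.words_per_category)]
    words["filler"] = [f"fill{i:03d}" for i in range(config.n_fillers)]
    for k in range(config.K_true):
        words[f"topic:{k}"] = [
            f"t{k}w{i:03d}" for i in range(config.topic_words_per_topic)
        ]
    return words


def _build_lexicons(
    config: SyntheticConfig, words: Mapping[str, list[str]], rng: np.random.Generator
) -> tuple[EmotionLexicon, HappinessLexicon]:
    assoc: dict[str, frozenset[str]] = {}
    for cat in CATEGORIES:
        labels = {cat}
        if config.sentiment_coupling:
            if cat in _POSITIVE_COUPLED:
                labels.add("positive")
            elif cat in _NEGATIVE_COUPLED:
                labels.add("negative")
        for w in words[cat]:
            assoc[w] = frozenset(labels)
    scores: dict[str, float] = {}
    profile = config.happiness_profile
    for group, wordlist in words.items():
        key = "topic" if group.startswith("topic:") else group
        mean = profile.get(key, 5.0)
        vals = np.clip(
            rng.normal(mean, config.happiness_sd, size=len(wordlist)), 1.0, 9.0
        )
        for w, v in zip(wordlist, vals):
            scores[w] = round(float(v), 2)
    return EmotionLexicon(assoc), HappinessLexicon(scores)


def generate_corpus(
    config: SyntheticConfig,
) -> tuple[Corpus, EmotionLexicon, HappinessLexicon, SyntheticGroundTruth]:
    """Generate a corpus under the planted conditions; fully seeded."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    words = _category_words(config)
    emo_lex, hap_lex = _build_lexicons(config, words, rng)

    K = config.K_true
    vocab = tuple(
        sorted(w for group in words.values() for w in group)
    )
    vocab_index = {w: i for i, w in enumerate(vocab)}

    # planted topic-word distributions (uniform over each topic's block)
    topic_word = np.zeros((K, len(vocab)))
    for k in range(K):
        block = words[f"topic:{k}"]
        for w in block:
            topic_word[k, vocab_index[w]] = 1.0 / len(block)

    shift = (
        np.asarray(config.women_topic_shift)
        if config.women_topic_shift is not None
        else np.zeros(K)
    )
    base = np.full(K, 1.0 / K)
    mean_prev = {
        "woman": _renormalize(base + shift / 2),
        "man": _renormalize(base - shift / 2),
    }

    start = datetime.fromisoformat(config.start).replace(tzinfo=timezone.utc)
    end = datetime.fromisoformat(config.end).replace(tzinfo=timezone.utc)
    span = (end - start).total_seconds()

    users: dict[str, UserRecord] = {}
    tweets: list[Tweet] = []
    doc_gender: list[str] = []
    doc_theta: list[np.ndarray] = []
    provenance: list[tuple[str, ...]] = []

    cats = list(CATEGORIES)
    countries = ["US", "GB", "AU", "CA"]
    country_p = [0.55, 0.30, 0.075, 0.075]

    tweet_no = 0
    for gender, prefix in (("woman", "w"), ("man", "m")):
        pi = config.pi[gender]
        pi_vec = np.array([pi[c] for c in cats])
        p_emotion = pi_vec.sum()
        p_topic = (1 - p_emotion) * config.topic_token_rate
        # token source distribution: 10 categories, then topic, then filler
        source_p = np.concatenate(
            [pi_vec, [p_topic, 1 - p_emotion - p_topic]]
        )
        alpha_g = config.topic_concentration * mean_prev[gender]
        for u in range(config.n_users_per_gender):
            uid = f"{prefix}{u:04d}"
            collected = config.tweets_per_user
            lifetime = int(collected * rng.uniform(1.0, 10.0))
            geolocated = rng.random() < 0.79
            users[uid] = UserRecord(
                user_id=uid,
                gender=gender,
                country=countries[
                    rng.choice(len(countries), p=country_p)
                ] if geolocated else None,
                lifetime_tweet_count=max(lifetime, collected),
                follower_count=int(rng.lognormal(5.0, 1.5)),
                list_memberships=frozenset(
                    f"list{j}" for j in rng.choice(20, size=int(rng.integers(3, 7)),
                                                   replace=False)
                ),
            )
            for _ in range(config.tweets_per_user):
                theta = rng.dirichlet(alpha_g)
                n_tokens = max(1, int(rng.poisson(config.mean_tokens_per_tweet)))
                sources = rng.choice(len(source_p), size=n_tokens, p=source_p)
                toks: list[str] = []
                prov: list[str] = []
                for s in sources:
                    if s < len(cats):
                        cat = cats[s]
                        toks.append(
                            words[cat][int(rng.integers(len(words[cat])))]
                        )
                        prov.append(f"cat:{cat}")
                    elif s == len(cats):  # topical token
                        z = int(rng.choice(K, p=theta))
                        if (
                            config.emotion_topic_overlap > 0
                            and rng.random() < config.emotion_topic_overlap
                        ):
                            cat = cats[int(rng.integers(len(cats)))]
                            toks.append(
                                words[cat][int(rng.integers(len(words[cat])))]
                            )
                        else:
                            block = words[f"topic:{z}"]
                            toks.append(block[int(rng.integers(len(block)))])
                        prov.append(f"topic:{z}")
                    else:
                        toks.append(
                            words["filler"][int(rng.integers(config.n_fillers))]
                        )
                        prov.append("filler")
                stamp = start + timedelta(seconds=float(rng.uniform(0, span)))
                tweets.append(
                    Tweet(
                        tweet_id=f"t{tweet_no:07d}",
                        user_id=uid,
                        timestamp=stamp.replace(microsecond=0),
                        raw_text=" ".join(toks),
                        tokens=tuple(toks),
                    )
                )
                doc_gender.append(gender)
                doc_theta.append(theta)
                provenance.append(tuple(prov))
                tweet_no += 1

    expected_h = {
        g: _expected_happiness(config, words, hap_lex, g) for g in ("woman", "man")
    }
    truth = SyntheticGroundTruth(
        config=config,
        vocab=vocab,
        topic_word=topic_word,
        doc_gender=tuple(doc_gender),
        doc_theta=np.asarray(doc_theta),
        provenance=tuple(provenance),
        emotion_lexicon=emo_lex,
        happiness_lexicon=hap_lex,
        expected_gender_happiness=expected_h,
    )
    corpus = Corpus(tuple(tweets), users)
    return corpus, emo_lex, hap_lex, truth


def _renormalize(v: np.ndarray) -> np.ndarray:
    v = np.clip(v, 1e-6, None)
    return v / v.sum()


def _expected_happiness(
    config: SyntheticConfig,
    words: Mapping[str, list[str]],
    lexicon: HappinessLexicon,
    gender: str,
) -> float:
    """Expected happiness of one emitted word under the planted mixture."""
    pi = config.pi[gender]
    p_emotion = sum(pi.values())
    p_topic = (1 - p_emotion) * config.topic_token_rate
    p_filler = 1 - p_emotion - p_topic
    total = 0.0
    for cat in CATEGORIES:
        mean_cat = float(np.mean([lexicon.score(w) for w in words[cat]]))
        total += pi[cat] * mean_cat
    topic_means = [
        float(np.mean([lexicon.score(w) for w in words[f"topic:{k}"]]))
        for k in range(config.K_true)
    ]
    total += p_topic * float(np.mean(topic_means))
    total += p_filler * float(np.mean([lexicon.score(w) for w in words["filler"]]))
    return total


def write_synthetic_bundle(
    out_dir: str | Path,
    corpus: Corpus,
    emo_lex: EmotionLexicon,
    hap_lex: HappinessLexicon,
    truth: SyntheticGroundTruth,
) -> dict[str, Path]:
    """Write the corpus/lexicons in the exact formats the loaders read."""
    from emotopic.corpus import write_corpus, write_users
    from emotopic.lexicons import write_emotion_lexicon, write_happiness_lexicon

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": out / "corpus.jsonl",
        "users": out / "users.csv",
        "emotion_lexicon": out / "emolex.txt",
        "happiness_lexicon": out / "labmt.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_corpus(corpus, paths["corpus"])
    write_users(corpus.users, paths["users"])
    write_emotion_lexicon(emo_lex, paths["emotion_lexicon"])
    write_happiness_lexicon(hap_lex, paths["happiness_lexicon"])
    paths["ground_truth"].write_text(truth.to_json(), encoding="utf-8")
    return paths
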