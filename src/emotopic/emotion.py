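"""Lexicon-based emotion counting and gender comparison.

The unit of analysis is the tweet. Each cleaned token adds one count to every
category its lemma is associated with in the word-emotion lexicon (bag of
words, no negation handling). From the per-tweet counts, the emotion
proportion statistic for category X is

    proportion_X = n_X / (n_negative + n_positive),

undefined (missing) when the tweet matches no sentiment-bearing word. For
X in {positive, negative} the proportions are complementary:
proportion_positive + proportion_negative = 1 wherever defined.

Group comparison pools the defined per-tweet proportions by author gender
and applies a variance-ratio (F) test followed by a Wilcoxon rank-sum
(Mann-Whitney) test, mirroring the convention of testing variance
homogeneity first and falling back to a rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from emotopic.constants import CATEGORIES
from emotopic.corpus import Corpus
from emotopic.errors import DegenerateSampleError, ParameterError
from emotopic.lexicons import EmotionLexicon

_STRATIFIED = ("woman", "man")


def score_emotions(
    tokens: Sequence[str], lexicon: EmotionLexicon
) -> dict[str, int]:
    """Per-category word counts for one tweet; order-invariant."""
    counts = dict.fromkeys(CATEGORIES, 0)
    for token in tokens:
        for category in lexicon.categories(token):
            counts[category] += 1
    return counts


def emotion_proportion(counts: Mapping[str, int], emotion: str) -> float:
    """The per-tweet proportion statistic; NaN when the denominator is zero."""
    if emotion not in CATEGORIES:
        raise ParameterError(f"unknown category {emotion!r}")
    denom = counts["negative"] + counts["positive"]
    if denom == 0:
        return math.nan
    return counts[emotion] / denom


def proportions_frame(corpus: Corpus, lexicon: EmotionLexicon) -> pd.DataFrame:
    """Per-tweet proportions for all 10 categories, with gender and timestamp.

    Tweets from gender-unknown users are excluded; rows where no sentiment
    word matched carry NaN in every proportion column.
    """
    records = []
    for tweet in corpus:
        gender = corpus.gender_of(tweet)
        if gender not in _STRATIFIED:
            continue
        counts = score_emotions(tweet.tokens, lexicon)
        denom = counts["negative"] + counts["positive"]
        row = {
            "tweet_id": tweet.tweet_id,
            "gender": gender,
            "timestamp": tweet.timestamp,
        }
        for cat in CATEGORIES:
            row[cat] = counts[cat] / denom if denom else math.nan
        records.append(row)
    frame = pd.DataFrame.from_records(
        records, columns=["tweet_id", "gender", "timestamp", *CATEGORIES]
    )
    return frame


def emotion_percentages(
    counts: Mapping[str, int], decimals: int = 1
) -> dict[str, float]:
    """Each category's share (%) of the 10-category total, rounded.

    This is the percentage rule of the per-gender emotion frequency table.
    """
    total = sum(counts[c] for c in CATEGORIES)
    if total == 0:
        return dict.fromkeys(CATEGORIES, math.nan)
    return {c: round(100.0 * counts[c] / total, decimals) for c in CATEGORIES}


def build_emotion_table(corpus: Corpus, lexicon: EmotionLexicon) -> pd.DataFrame:
    """Raw per-gender category counts and their within-gender percentages.

    Rows are the 10 categories; columns are a (gender, {count, pct})
    MultiIndex. Percentages are each gender's category count over that
    gender's 10-category total, at 1 decimal; a gender with no matched
    words gets zero counts and missing percentages.
    """
    sums = {g: dict.fromkeys(CATEGORIES, 0) for g in _STRATIFIED}
    for tweet in corpus:
        gender = corpus.gender_of(tweet)
        if gender not in _STRATIFIED:
            continue
        counts = score_emotions(tweet.tokens, lexicon)
        bucket = sums[gender]
        for cat in CATEGORIES:
            bucket[cat] += counts[cat]
    data = {}
    for gender in _STRATIFIED:
        pcts = emotion_percentages(sums[gender])
        data[(gender, "count")] = [sums[gender][c] for c in CATEGORIES]
        data[(gender, "pct")] = [pcts[c] for c in CATEGORIES]
    return pd.DataFrame(data, index=list(CATEGORIES))


@dataclass(frozen=True)
class VarianceRatioResult:
    statistic: float  # F = var(x)/var(y)
    df: tuple[int, int]
    pvalue: float


def variance_ratio_test(
    x: Sequence[float], y: Sequence[float]
) -> VarianceRatioResult:
    """Two-sided F test of variance equality, F = var(x)/var(y) (ddof=1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateSampleError("variance ratio needs >= 2 values per sample")
    vy = y.var(ddof=1)
    if vy == 0:
        raise DegenerateSampleError("var(y) = 0: variance ratio undefined")
    f = x.var(ddof=1) / vy
    dfn, dfd = len(x) - 1, len(y) - 1
    dist = stats.f(dfn, dfd)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return VarianceRatioResult(float(f), (dfn, dfd), float(min(p, 1.0)))


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U for x: #{x_i > y_j} + ties/2
    pvalue: float


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Wilcoxon rank-sum via the Mann-Whitney U statistic.

    W counts pairs with x_i > y_j plus half the tied pairs. The p-value is
    exact (enumeration) for small tie-free samples and otherwise uses the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DegenerateSampleError("rank-sum test needs nonempty samples")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return RankSumResult(float(res.statistic), float(res.pvalue))


def compare_groups(
    corpus: Corpus,
    lexicon: EmotionLexicon,
    emotions: Iterable[str] = CATEGORIES,
    *,
    frame: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-emotion gender comparison of the proportion statistic.

    For each emotion, tweets with a defined proportion are pooled by gender
    (women as sample x, men as sample y); medians/means, the variance-ratio
    test and the rank-sum test are reported. Emotions where either gender
    has fewer than two defined values are flagged untestable (statistics
    NaN, ``testable`` False).
    """
    emotions = list(emotions)
    for e in emotions:
        if e not in CATEGORIES:
            raise ParameterError(f"unknown category {e!r}")
    if frame is None:
        frame = proportions_frame(corpus, lexicon)
    rows = []
    for emotion in emotions:
        women = frame.loc[frame["gender"] == "woman", emotion].dropna().to_numpy()
        men = frame.loc[frame["gender"] == "man", emotion].dropna().to_numpy()
        row = {
            "emotion": emotion,
            "n_women": len(women),
            "n_men": len(men),
            "median_women": float(np.median(women)) if len(women) else math.nan,
            "median_men": float(np.median(men)) if len(men) else math.nan,
            "mean_women": float(np.mean(women)) if len(women) else math.nan,
            "mean_men": float(np.mean(men)) if len(men) else math.nan,
        }
        testable = len(women) >= 2 and len(men) >= 2
        if testable:
            try:
                fres = variance_ratio_test(women, men)
                row.update(
                    F=fres.statistic,
                    df1=fres.df[0],
                    df2=fres.df[1],
                    p_f=fres.pvalue,
                )
            except DegenerateSampleError:
                row.update(F=math.nan, df1=len(women) - 1, df2=len(men) - 1, p_f=math.nan)
            wres = rank_sum_test(women, men)
            row.update(W=wres.statistic, p_w=wres.pvalue)
        else:
            row.update(F=math.nan, df1=math.nan, df2=math.nan, p_f=math.nan,
                       W=math.nan, p_w=math.nan)
        row["testable"] = testable
        rows.append(row)
    return pd.DataFrame(rows).set_index("emotion")


def monthly_series(
    corpus: Corpus,
    lexicon: EmotionLexicon,
    emotions: Iterable[str] = CATEGORIES,
    *,
    frame: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean defined proportions by calendar month (UTC) and gender.

    Long format: month (YYYY-MM), gender, emotion, mean, n. Months with no
    defined values for an emotion/gender are absent.
    """
    emotions = list(emotions)
    if frame is None:
        frame = proportions_frame(corpus, lexicon)
    if frame.empty:
        return pd.DataFrame(columns=["month", "gender", "emotion", "mean", "n"])
    stamps = pd.to_datetime(frame["timestamp"], utc=True)
    frame = frame.assign(month=stamps.dt.strftime("%Y-%m"))
    out = []
    for emotion in emotions:
        grouped = (
            frame.dropna(subset=[emotion])
            .groupby(["month", "gender"], sort=True)[emotion]
            .agg(["mean", "size"])
            .reset_index()
        )
        for _, r in grouped.iterrows():
            out.append(
                {
                    "month": r["month"],
                    "gender": r["gender"],
                    "emotion": emotion,
                    "mean": float(r["mean"]),
                    "n": int(r["size"]),
                }
            )
    return pd.DataFrame(out, columns=["month", "gender", "emotion", "mean", "n"])
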