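"""Participant selection and sample-description arithmetic.

Cohort inclusion follows the curated-list heuristic: a user qualifies when
they appear on at least ``min_lists`` topical lists (default 3), i.e. several
independent curators consider them part of the community.

:class:`CohortSummary` reproduces the arithmetic of a sample-description
section: per-gender user counts, collected and lifetime tweet totals, mean
tweets per user (nearest integer), shares of users above activity thresholds,
follower totals, and the collected/lifetime fraction; overall, the
geolocated share and per-country breakdown. Rounding conventions are
explicit: means to the nearest integer, fractions to 1 decimal,
geolocation/country percentages to 2 decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Set

from emotopic.corpus import Corpus
from emotopic.errors import ParameterError


def select_members(
    memberships: Mapping[str, Set[str]], min_lists: int = 3
) -> set[str]:
    """Users appearing on at least ``min_lists`` distinct lists."""
    if min_lists < 1:
        raise ParameterError(f"min_lists must be >= 1, got {min_lists}")
    return {user for user, lists in memberships.items() if len(set(lists)) >= min_lists}


@dataclass(frozen=True)
class GenderSummary:
    n_users: int
    collected_tweets: int
    lifetime_tweets: int
    follower_total: int
    mean_tweets_per_user: int | None
    pct_over_500: float | None
    pct_over_1000: float | None
    collected_fraction_pct: float | None


@dataclass(frozen=True)
class CohortSummary:
    by_gender: dict[str, GenderSummary]
    total_users: int
    total_collected: int
    total_lifetime: int
    overall_collected_fraction_pct: float | None
    geolocated_n: int
    geolocated_pct: float | None
    countries: dict[str, tuple[int, float]]  # country -> (n users, % of geolocated)

    @classmethod
    def from_aggregates(
        cls,
        per_gender: Mapping[str, Mapping[str, float]],
        geolocated_n: int = 0,
        total_users: int | None = None,
        country_counts: Mapping[str, int] | None = None,
        *,
        mean_decimals: int = 0,
        fraction_decimals: int = 1,
        geo_decimals: int = 2,
    ) -> "CohortSummary":
        """Build a summary from already-tallied per-gender aggregates.

        ``per_gender`` maps a gender label to a dict with keys ``n_users``,
        ``collected``, ``lifetime`` and optionally ``followers``,
        ``n_over_500``, ``n_over_1000``. A gender with zero users gets its
        ratio fields reported as missing (``None``), never a division error.
        """
        by_gender: dict[str, GenderSummary] = {}
        tot_col = tot_life = tot_users_acc = 0
        for gender, agg in per_gender.items():
            n = int(agg["n_users"])
            collected = int(agg["collected"])
            lifetime = int(agg["lifetime"])
            tot_users_acc += n
            tot_col += collected
            tot_life += lifetime
            if n > 0:
                mean = round(collected / n, mean_decimals)
                mean = int(mean) if mean_decimals == 0 else mean
                p500 = _pct(agg.get("n_over_500"), n, fraction_decimals)
                p1000 = _pct(agg.get("n_over_1000"), n, fraction_decimals)
            else:
                mean = p500 = p1000 = None
            frac = _pct(collected, lifetime, fraction_decimals) if lifetime else None
            by_gender[gender] = GenderSummary(
                n_users=n,
                collected_tweets=collected,
                lifetime_tweets=lifetime,
                follower_total=int(agg.get("followers", 0)),
                mean_tweets_per_user=mean,
                pct_over_500=p500,
                pct_over_1000=p1000,
                collected_fraction_pct=frac,
            )
        if total_users is None:
            total_users = tot_users_acc
        overall_frac = _pct(tot_col, tot_life, fraction_decimals) if tot_life else None
        countries = {}
        if country_counts:
            for country in sorted(country_counts, key=lambda c: (-country_counts[c], c)):
                n = country_counts[country]
                countries[country] = (n, _pct(n, geolocated_n, geo_decimals))
        return cls(
            by_gender=by_gender,
            total_users=total_users,
            total_collected=tot_col,
            total_lifetime=tot_life,
            overall_collected_fraction_pct=overall_frac,
            geolocated_n=geolocated_n,
            geolocated_pct=_pct(geolocated_n, total_users, geo_decimals)
            if total_users
            else None,
            countries=countries,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def to_tsv(self) -> str:
        lines = [
            "gender\tn_users\tcollected\tlifetime\tfollowers\tmean_tweets_per_user"
            "\tpct_over_500\tpct_over_1000\tcollected_fraction_pct"
        ]
        for gender in sorted(self.by_gender):
            g = self.by_gender[gender]
            lines.append(
                "\t".join(
                    str(x if x is not None else "NA")
                    for x in (
                        gender,
                        g.n_users,
                        g.collected_tweets,
                        g.lifetime_tweets,
                        g.follower_total,
                        g.mean_tweets_per_user,
                        g.pct_over_500,
                        g.pct_over_1000,
                        g.collected_fraction_pct,
                    )
                )
            )
        return "\n".join(lines) + "\n"


def summarize_cohort(corpus: Corpus) -> CohortSummary:
    """Tally a corpus into a :class:`CohortSummary`.

    Gender-unknown users are excluded from the gender-stratified rows but
    counted in overall totals (user count, geolocation).
    """
    collected: dict[str, int] = {}
    for t in corpus.tweets:
        collected[t.user_id] = collected.get(t.user_id, 0) + 1

    per_gender: dict[str, dict[str, float]] = {}
    tot_geo = 0
    country_counts: dict[str, int] = {}
    for user in corpus.users.values():
        if user.country:
            tot_geo += 1
            country_counts[user.country] = country_counts.get(user.country, 0) + 1
        if user.gender == "unknown":
            continue
        agg = per_gender.setdefault(
            user.gender,
            {
                "n_users": 0,
                "collected": 0,
                "lifetime": 0,
                "followers": 0,
                "n_over_500": 0,
                "n_over_1000": 0,
            },
        )
        n_col = collected.get(user.user_id, 0)
        agg["n_users"] += 1
        agg["collected"] += n_col
        agg["lifetime"] += user.lifetime_tweet_count
        agg["followers"] += user.follower_count
        agg["n_over_500"] += n_col > 500
        agg["n_over_1000"] += n_col > 1000
    return CohortSummary.from_aggregates(
        per_gender,
        geolocated_n=tot_geo,
        total_users=len(corpus.users),
        country_counts=country_counts,
    )


def _pct(num, den, decimals: int) -> float | None:
    if num is None or not den:
        return None
    return round(100.0 * num / den, decimals)
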