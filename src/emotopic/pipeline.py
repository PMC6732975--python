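"""End-to-end pipeline: configuration, orchestration, report assembly.

A :class:`PipelineConfig` (typically loaded from YAML) names either input
files (corpus JSONL/CSV, user table, lexicon files) or a synthetic-corpus
configuration — exactly one of the two. :func:`run_pipeline` then produces a
report bundle of TSV/JSON artifacts: cohort summary, emotion frequency
table, gender comparison table, monthly emotion series, daily happiness
series, optional topic-number diagnostics, topic profiles / diagnostics /
prevalence labels / correlations, the topic-happiness analysis, and a run
manifest (config hash, seed, package version) from which every table
regenerates identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from emotopic import __version__
from emotopic.cohort import summarize_cohort
from emotopic.constants import CATEGORIES
from emotopic.corpus import Corpus, load_corpus
from emotopic.emotion import (
    build_emotion_table,
    compare_groups,
    monthly_series,
    proportions_frame,
)
from emotopic.errors import ParameterError, PipelineError
from emotopic.happiness import daily_series
from emotopic.lexicons import load_emotion_lexicon, load_happiness_lexicon
from emotopic.synthetic import SyntheticConfig, generate_corpus
from emotopic import topics as tp

log = logging.getLogger("emotopic")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    # inputs: either file paths ...
    corpus_path: str | None = None
    corpus_format: str = "jsonl"
    users_path: str | None = None
    emotion_lexicon_path: str | None = None
    happiness_lexicon_path: str | None = None
    # ... or a synthetic config
    synthetic: SyntheticConfig | None = None

    clean: bool = True
    dedup: bool = False
    emotions: tuple[str, ...] = CATEGORIES
    lens_delta: float = 0.0
    K: int = 5
    k_candidates: tuple[int, ...] | None = None
    alpha: float | None = None
    beta: float = 0.1
    n_iter: int = 300
    burn_in: int = 150
    thin: int = 5
    tfidf_threshold: float = 0.1
    min_count: int = 1
    top_n: int = 20
    frex_weight: float = 0.5
    n_boot: int = 1000
    run_topics: bool = True
    seed: int = 0
    output_dir: str = "emotopic_report"

    def validate(self) -> None:
        file_mode = self.corpus_path is not None
        if file_mode == (self.synthetic is not None):
            raise ParameterError(
                "exactly one of corpus_path / synthetic must be configured"
            )
        if file_mode:
            needed = {
                "corpus_path": self.corpus_path,
                "emotion_lexicon_path": self.emotion_lexicon_path,
                "happiness_lexicon_path": self.happiness_lexicon_path,
            }
            for name, p in needed.items():
                if p is None:
                    raise ParameterError(f"{name} is required in file mode")
                if not Path(p).exists():
                    raise PipelineError("preflight", "missing-input", f"{name}: {p}")
            if self.users_path is not None and not Path(self.users_path).exists():
                raise PipelineError(
                    "preflight", "missing-input", f"users_path: {self.users_path}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        synth = raw.pop("synthetic", None)
        cfg = cls(**{k: _tuplify(v) for k, v in raw.items()})
        if synth is not None:
            if "pi" in synth:
                synth["pi"] = {g: dict(c) for g, c in synth["pi"].items()}
            if synth.get("women_topic_shift") is not None:
                synth["women_topic_shift"] = tuple(synth["women_topic_shift"])
            cfg.synthetic = SyntheticConfig(**synth)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()


def _tuplify(v):
    return tuple(v) if isinstance(v, list) else v


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every configured stage and write the report bundle.

    Returns a mapping of artifact name to path. Any stage failure raises
    :class:`PipelineError` carrying the stage name and an error code.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name):
        log.info("stage: %s", name)

    # --- load or synthesize -------------------------------------------------
    stage("load")
    try:
        if config.synthetic is not None:
            synth_cfg = dataclasses.replace(config.synthetic, seed=config.seed)
            corpus, emo_lex, hap_lex, _truth = generate_corpus(synth_cfg)
        else:
            corpus = load_corpus(
                config.corpus_path, config.corpus_format, config.users_path
            )
            emo_lex = load_emotion_lexicon(config.emotion_lexicon_path)
            hap_lex = load_happiness_lexicon(config.happiness_lexicon_path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("load", "input-error", str(exc)) from exc

    if config.dedup:
        seen: set[tuple[str, str]] = set()
        keep = []
        for t in corpus.tweets:
            key = (t.user_id, t.raw_text)
            if key not in seen:
                seen.add(key)
                keep.append(t)
        corpus = Corpus(tuple(keep), corpus.users)
    if config.clean:
        corpus = corpus.cleaned()

    # --- cohort -------------------------------------------------------------
    stage("cohort")
    summary = summarize_cohort(corpus)
    artifacts["cohort_tsv"] = _write(out / "cohort.tsv", summary.to_tsv())
    artifacts["cohort_json"] = _write(out / "cohort.json", summary.to_json())

    # --- emotions -----------------------------------------------------------
    stage("emotions")
    try:
        frame = proportions_frame(corpus, emo_lex)
        table = build_emotion_table(corpus, emo_lex)
        comparison = compare_groups(corpus, emo_lex, config.emotions, frame=frame)
        monthly = monthly_series(corpus, emo_lex, config.emotions, frame=frame)
    except Exception as exc:
        raise PipelineError("emotions", "stage-failure", str(exc)) from exc
    flat = table.copy()
    flat.columns = ["_".join(c) for c in flat.columns]
    artifacts["emotion_table"] = _write_df(out / "emotion_table.tsv", flat)
    artifacts["group_comparison"] = _write_df(
        out / "group_comparison.tsv", comparison.reset_index()
    )
    artifacts["monthly_series"] = _write_df(out / "monthly_series.tsv", monthly)

    # --- happiness ----------------------------------------------------------
    stage("happiness")
    daily = daily_series(corpus, hap_lex, config.lens_delta)
    artifacts["daily_happiness"] = _write_df(out / "daily_happiness.tsv", daily)

    # --- topics -------------------------------------------------------------
    if config.run_topics:
        stage("topics")
        try:
            dtm = tp.build_dtm(corpus, min_count=config.min_count)
            dtm = tp.tfidf_filter(dtm, config.tfidf_threshold)
            if config.k_candidates:
                ksel = tp.select_k(
                    dtm,
                    config.k_candidates,
                    n_iter=config.n_iter,
                    burn_in=config.burn_in,
                    thin=config.thin,
                    seed=config.seed,
                    alpha=config.alpha,
                    beta=config.beta,
                )
                artifacts["k_selection"] = _write_df(
                    out / "k_selection.tsv", ksel.reset_index()
                )
            results = tp.fit_lda_gibbs(
                dtm,
                config.K,
                alpha=config.alpha,
                beta=config.beta,
                n_iter=config.n_iter,
                burn_in=config.burn_in,
                thin=config.thin,
                seed=config.seed,
            )
            kept = set(results.doc_ids)
            id_gender = {
                t.tweet_id: corpus.gender_of(t) for t in corpus.tweets
            }
            genders = [id_gender[d] for d in results.doc_ids]
            known = [g in ("woman", "man") for g in genders]
            if not all(known):
                raise PipelineError(
                    "topics", "unknown-gender",
                    "prevalence requires gendered documents",
                )
            prevalence = tp.estimate_prevalence(
                results, genders, n_boot=config.n_boot, seed=config.seed
            )
            profiles = tp.label_topics(
                results, n=min(config.top_n, len(dtm.vocab)),
                frex_weight=config.frex_weight,
            )
            coherence = tp.semantic_coherence(results, dtm)
            excl = tp.exclusivity(results)
            corr = tp.topic_correlations(results) if config.K >= 2 else None
            th = tp.topic_happiness_analysis(profiles, prevalence, hap_lex)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("topics", "stage-failure", str(exc)) from exc

        prof_rows = [
            {
                "topic": k,
                "ordering": ordering,
                "words": " ".join(getattr(profiles, ordering)[k]),
            }
            for k in range(results.K)
            for ordering in ("prob", "frex", "score")
        ]
        artifacts["topic_profiles"] = _write_df(
            out / "topic_profiles.tsv", pd.DataFrame(prof_rows)
        )
        artifacts["topic_diagnostics"] = _write_df(
            out / "topic_diagnostics.tsv",
            pd.DataFrame(
                {
                    "topic": range(results.K),
                    "semantic_coherence": coherence,
                    "exclusivity": excl,
                }
            ),
        )
        artifacts["prevalence"] = _write_df(
            out / "prevalence.tsv", prevalence.reset_index()
        )
        if corr is not None:
            artifacts["correlations"] = _write_df(
                out / "topic_correlations.tsv",
                pd.DataFrame(
                    corr,
                    index=[f"topic{k}" for k in range(results.K)],
                    columns=[f"topic{k}" for k in range(results.K)],
                ).reset_index(names="topic"),
            )
        artifacts["topic_happiness"] = _write_df(
            out / "topic_happiness.tsv", th.per_topic.reset_index()
        )
        artifacts["topic_happiness_pairs"] = _write_df(
            out / "topic_happiness_pairs.tsv", th.pairwise
        )
        artifacts["topic_trend"] = _write(
            out / "topic_trend.json",
            json.dumps(
                {
                    "slope": th.slope,
                    "slope_p": th.slope_p,
                    "intercept": th.intercept,
                    "degenerate": th.degenerate,
                },
                indent=2,
            ),
        )

    # --- manifest -----------------------------------------------------------
    stage("manifest")
    manifest = {
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "seed": config.seed,
        "version": __version__,
    }
    artifacts["manifest"] = _write(
        out / "manifest.json", json.dumps(manifest, indent=2, default=str)
    )
    return artifacts


def _write(path: Path, text: str) -> Path:
    path.write_text(text, encoding="utf-8")
    return path


def _write_df(path: Path, frame: pd.DataFrame) -> Path:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
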