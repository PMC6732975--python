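"""Topic modeling with a gender covariate.

The corpus is converted to a document-term matrix, pruned by a TF-IDF score,
and fitted with latent Dirichlet allocation via collapsed Gibbs sampling
(:class:`GibbsLDA`; ``fit()`` returns a :class:`TopicModelResults`). On top
of the fitted model:

* ``select_k`` computes four standard topic-number diagnostics
  (Griffiths2004, CaoJuan2009, Arun2010, Deveaud2014);
* ``estimate_prevalence`` measures each topic's gender-prevalence effect
  (difference of mean document-topic proportions, women minus men) with a
  stratified nonparametric bootstrap CI — a transparent surrogate for a
  covariate-aware topical-prevalence model;
* ``label_topics`` ranks words by highest probability, FREX
  (frequency-exclusivity harmonic mean) and the term score;
* ``semantic_coherence`` and ``exclusivity`` provide topic validation;
* ``topic_correlations`` computes Pearson correlations of centered-log-ratio
  transformed document-topic proportions, a surrogate for the
  logistic-normal topic covariance of correlated topic models;
* ``topic_happiness_analysis`` scores each topic's defining words with a
  happiness lexicon, regresses word happiness on the topics'
  gender-prevalence ordering, and compares mirrored topic pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.special import gammaln, logsumexp

from emotopic.corpus import Corpus
from emotopic.errors import DegenerateSampleError, ParameterError
from emotopic.happiness import SetHappiness, set_happiness
from emotopic.lexicons import HappinessLexicon


# ---------------------------------------------------------------------------
# document-term matrix


@dataclass(frozen=True)
class DocumentTermMatrix:
    """Sparse document x vocabulary count matrix with aligned identifiers."""

    counts: sparse.csr_matrix
    vocab: tuple[str, ...]
    doc_ids: tuple[str, ...]
    dropped_doc_ids: tuple[str, ...] = ()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def doc_lengths(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def document_frequencies(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()


def build_dtm(
    docs: Corpus | Sequence[Sequence[str]],
    min_count: int = 1,
    doc_ids: Sequence[str] | None = None,
) -> DocumentTermMatrix:
    """Tally cleaned documents into a term-count matrix.

    The vocabulary is sorted lexicographically for determinism; terms with
    total corpus count below ``min_count`` are dropped. Documents are kept
    in order (including ones emptied by ``min_count``).
    """
    if isinstance(docs, Corpus):
        token_lists = [t.tokens for t in docs.tweets]
        doc_ids = [t.tweet_id for t in docs.tweets]
    else:
        token_lists = [list(d) for d in docs]
        if doc_ids is None:
            doc_ids = [f"d{i}" for i in range(len(token_lists))]
    if len(token_lists) == 0:
        raise ParameterError("cannot build a document-term matrix from an empty corpus")

    totals: dict[str, int] = {}
    for toks in token_lists:
        for tok in toks:
            totals[tok] = totals.get(tok, 0) + 1
    vocab = tuple(sorted(w for w, c in totals.items() if c >= min_count))
    index = {w: i for i, w in enumerate(vocab)}

    rows, cols, vals = [], [], []
    for d, toks in enumerate(token_lists):
        tally: dict[int, int] = {}
        for tok in toks:
            j = index.get(tok)
            if j is not None:
                tally[j] = tally.get(j, 0) + 1
        for j, c in tally.items():
            rows.append(d)
            cols.append(j)
            vals.append(c)
    counts = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(token_lists), len(vocab)), dtype=np.int64
    )
    return DocumentTermMatrix(counts, vocab, tuple(doc_ids))


def tfidf_scores(dtm: DocumentTermMatrix) -> np.ndarray:
    """Per-term TF-IDF pruning score.

    score(t) = mean over documents containing t of
    [count(d,t) / len(d)] * log2(D / df(t)).
    """
    counts = dtm.counts.tocsc()
    lengths = dtm.doc_lengths().astype(float)
    df = dtm.document_frequencies().astype(float)
    n_docs = counts.shape[0]
    idf = np.log2(n_docs / np.where(df > 0, df, 1.0))
    scores = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        col = counts.getcol(j)
        docs = col.indices
        if len(docs) == 0:
            continue
        tf = col.data / lengths[docs]
        scores[j] = tf.mean() * idf[j]
    return scores


def tfidf_filter(
    dtm: DocumentTermMatrix, threshold: float = 0.1
) -> DocumentTermMatrix:
    """Drop terms whose TF-IDF score is <= ``threshold``.

    Documents emptied by the filtering are dropped, with their ids recorded
    on the returned matrix (``dropped_doc_ids``) and a warning logged.
    """
    if threshold < 0:
        raise ParameterError(f"threshold must be >= 0, got {threshold}")
    scores = tfidf_scores(dtm)
    keep = scores > threshold
    if not keep.any():
        raise ParameterError(
            f"TF-IDF threshold {threshold} removes the entire vocabulary"
        )
    counts = dtm.counts[:, keep]
    vocab = tuple(v for v, k in zip(dtm.vocab, keep) if k)
    doc_mass = np.asarray(counts.sum(axis=1)).ravel()
    alive = doc_mass > 0
    dropped = tuple(d for d, a in zip(dtm.doc_ids, alive) if not a)
    if dropped:
        warnings.warn(
            f"tfidf_filter dropped {len(dropped)} emptied document(s)",
            stacklevel=2,
        )
    return DocumentTermMatrix(
        counts[alive].tocsr(),
        vocab,
        tuple(d for d, a in zip(dtm.doc_ids, alive) if a),
        dropped_doc_ids=dropped,
    )


def write_dtm(dtm: DocumentTermMatrix, prefix: str | Path) -> None:
    """MatrixMarket matrix plus ``.vocab.txt`` / ``.docs.txt`` sidecars."""
    from scipy.io import mmwrite

    prefix = Path(prefix)
    mmwrite(str(prefix) + ".mtx", dtm.counts)
    prefix.with_suffix(prefix.suffix + ".vocab.txt").write_text(
        "\n".join(dtm.vocab) + "\n", encoding="utf-8"
    )
    prefix.with_suffix(prefix.suffix + ".docs.txt").write_text(
        "\n".join(dtm.doc_ids) + "\n", encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# collapsed Gibbs LDA


@dataclass
class TopicModelResults:
    """Posterior summaries of a fitted LDA model.

    ``topic_word`` (K x V) and ``doc_topic`` (D x K) are posterior means over
    the retained Gibbs samples; ``assignments`` is the final token-topic
    state; ``loglik_samples`` are the complete-data log likelihoods
    log P(w | z) at each retained sample.
    """

    K: int
    alpha: float
    beta: float
    seed: int
    vocab: tuple[str, ...]
    doc_ids: tuple[str, ...]
    topic_word: np.ndarray
    doc_topic: np.ndarray
    assignments: np.ndarray
    loglik_samples: np.ndarray
    loglik_trace: np.ndarray

    def top_words(self, k: int, n: int = 10) -> list[str]:
        order = _ranked_words(self.topic_word[k], self.vocab)
        return order[:n]

    def summary(self, n: int = 10) -> str:
        lines = [
            f"GibbsLDA results: K={self.K}, V={len(self.vocab)}, "
            f"D={len(self.doc_ids)}, alpha={self.alpha:.4g}, "
            f"beta={self.beta:.4g}, seed={self.seed}",
            f"mean sample log-likelihood: {float(np.mean(self.loglik_samples)):.2f}",
        ]
        for k in range(self.K):
            share = float(self.doc_topic[:, k].mean())
            words = ", ".join(self.top_words(k, n))
            lines.append(f"topic {k} (mean share {share:.3f}): {words}")
        return "\n".join(lines)


class GibbsLDA:
    """Latent Dirichlet allocation fitted by collapsed Gibbs sampling.

    Symmetric Dirichlet priors: ``alpha`` (document-topic, default 50/K) and
    ``beta`` (topic-word, default 0.1). The sampler sweeps token-topic
    assignments; posterior means are averaged over post-burn-in samples
    taken every ``thin`` sweeps. Runs are exactly reproducible given a seed.
    """

    def __init__(
        self,
        dtm: DocumentTermMatrix,
        K: int,
        alpha: float | None = None,
        beta: float = 0.1,
    ):
        if K < 1:
            raise ParameterError(f"K must be >= 1, got {K}")
        if K > len(dtm.vocab):
            raise ParameterError(
                f"K={K} exceeds vocabulary size {len(dtm.vocab)}"
            )
        self.dtm = dtm
        self.K = K
        self.alpha = 50.0 / K if alpha is None else alpha
        self.beta = beta
        coo = dtm.counts.tocoo()
        doc_of, word_of = [], []
        for d, w, c in zip(coo.row, coo.col, coo.data):
            doc_of.extend([int(d)] * int(c))
            word_of.extend([int(w)] * int(c))
        order = np.lexsort((word_of, doc_of))
        self._doc_of = [doc_of[i] for i in order]
        self._word_of = [word_of[i] for i in order]

    def fit(
        self,
        n_iter: int = 500,
        burn_in: int = 250,
        thin: int = 10,
        seed: int = 0,
    ) -> TopicModelResults:
        if n_iter <= burn_in:
            raise ParameterError("n_iter must exceed burn_in")
        K, V = self.K, len(self.dtm.vocab)
        D = self.dtm.shape[0]
        alpha, beta = self.alpha, self.beta
        v_beta = V * beta
        doc_of, word_of = self._doc_of, self._word_of
        N = len(doc_of)
        rng = np.random.default_rng(seed)

        z = rng.integers(0, K, size=N).tolist()
        ndk = [[0] * K for _ in range(D)]
        nwk = [[0] * K for _ in range(V)]
        nk = [0] * K
        for i in range(N):
            k = z[i]
            ndk[doc_of[i]][k] += 1
            nwk[word_of[i]][k] += 1
            nk[k] += 1

        theta_acc = np.zeros((D, K))
        phi_acc = np.zeros((K, V))
        logliks: list[float] = []
        trace: list[float] = []
        n_samples = 0
        cum = [0.0] * K
        k_range = range(K)

        for it in range(1, n_iter + 1):
            u = rng.random(N).tolist()
            for i in range(N):
                d = doc_of[i]
                w = word_of[i]
                k = z[i]
                row = ndk[d]
                col = nwk[w]
                row[k] -= 1
                col[k] -= 1
                nk[k] -= 1
                total = 0.0
                for j in k_range:
                    total += (row[j] + alpha) * (col[j] + beta) / (nk[j] + v_beta)
                    cum[j] = total
                r = u[i] * total
                k = 0
                while cum[k] < r:
                    k += 1
                z[i] = k
                row[k] += 1
                col[k] += 1
                nk[k] += 1
            nwk_arr = np.asarray(nwk, dtype=float).T  # K x V
            nk_arr = np.asarray(nk, dtype=float)
            ll = float(
                K * (gammaln(v_beta) - V * gammaln(beta))
                + (gammaln(nwk_arr + beta).sum() - gammaln(nk_arr + v_beta).sum())
            )
            trace.append(ll)
            if it > burn_in and (it - burn_in - 1) % thin == 0:
                ndk_arr = np.asarray(ndk, dtype=float)
                nd = ndk_arr.sum(axis=1, keepdims=True)
                theta_acc += (ndk_arr + alpha) / (nd + K * alpha)
                phi_acc += (nwk_arr + beta) / (nk_arr[:, None] + v_beta)
                logliks.append(ll)
                n_samples += 1

        return TopicModelResults(
            K=K,
            alpha=alpha,
            beta=beta,
            seed=seed,
            vocab=self.dtm.vocab,
            doc_ids=self.dtm.doc_ids,
            topic_word=phi_acc / n_samples,
            doc_topic=theta_acc / n_samples,
            assignments=np.asarray(z, dtype=np.int64),
            loglik_samples=np.asarray(logliks),
            loglik_trace=np.asarray(trace),
        )


def fit_lda_gibbs(
    dtm: DocumentTermMatrix,
    K: int,
    alpha: float | None = None,
    beta: float = 0.1,
    n_iter: int = 500,
    burn_in: int = 250,
    thin: int = 10,
    seed: int = 0,
) -> TopicModelResults:
    """Functional wrapper over :class:`GibbsLDA`."""
    return GibbsLDA(dtm, K, alpha=alpha, beta=beta).fit(
        n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed
    )


# ---------------------------------------------------------------------------
# topic-number diagnostics


def jensen_shannon(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence (natural log) between two distributions."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = 0.5 * (p + q)
    return float(0.5 * _kl(p, m) + 0.5 * _kl(q, m))


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def select_k(
    dtm: DocumentTermMatrix,
    k_candidates: Sequence[int],
    n_iter: int = 300,
    burn_in: int = 150,
    thin: int = 5,
    seed: int = 0,
    alpha: float | None = None,
    beta: float = 0.1,
) -> pd.DataFrame:
    """Topic-number diagnostics over candidate K values.

    Columns: ``griffiths2004`` (harmonic-mean marginal log likelihood;
    maximize), ``caojuan2009`` (mean pairwise topic cosine; minimize),
    ``arun2010`` (symmetric KL between singular-value and topic-marginal
    spectra; minimize), ``deveaud2014`` (mean pairwise Jensen-Shannon
    divergence; maximize).
    """
    ks = list(k_candidates)
    if not ks:
        raise ParameterError("k_candidates must be non-empty")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(ks))
    rows = []
    for k, child in zip(ks, child_seeds):
        res = fit_lda_gibbs(
            dtm, k, alpha=alpha, beta=beta, n_iter=n_iter,
            burn_in=burn_in, thin=thin, seed=int(child) % (2**31),
        )
        rows.append(
            {
                "K": k,
                "griffiths2004": _griffiths(res.loglik_samples),
                "caojuan2009": _caojuan(res.topic_word),
                "arun2010": _arun(res.topic_word, res.doc_topic, dtm.doc_lengths()),
                "deveaud2014": _deveaud(res.topic_word),
            }
        )
    return pd.DataFrame(rows).set_index("K")


def _griffiths(logliks: np.ndarray) -> float:
    # harmonic-mean estimator of the marginal likelihood over Gibbs samples
    s = len(logliks)
    return float(np.log(s) - logsumexp(-logliks))


def _caojuan(phi: np.ndarray) -> float:
    k = phi.shape[0]
    if k < 2:
        return 0.0
    norms = np.linalg.norm(phi, axis=1)
    sims = (phi @ phi.T) / np.outer(norms, norms)
    iu = np.triu_indices(k, 1)
    return float(sims[iu].mean())


def _deveaud(phi: np.ndarray) -> float:
    k = phi.shape[0]
    if k < 2:
        return 0.0
    vals = [
        jensen_shannon(phi[i], phi[j])
        for i in range(k)
        for j in range(i + 1, k)
    ]
    return float(np.mean(vals))


def _arun(phi: np.ndarray, theta: np.ndarray, lengths: np.ndarray) -> float:
    sv = np.linalg.svd(phi, compute_uv=False)
    cm1 = np.sort(sv / sv.sum())[::-1]
    marg = lengths.astype(float) @ theta
    cm2 = np.sort(marg / marg.sum())[::-1]
    eps = 1e-12
    cm1 = np.clip(cm1, eps, None)
    cm2 = np.clip(cm2, eps, None)
    return float(np.sum(cm1 * np.log(cm1 / cm2)) + np.sum(cm2 * np.log(cm2 / cm1)))


# ---------------------------------------------------------------------------
# gender prevalence


def estimate_prevalence(
    results: TopicModelResults,
    gender: Sequence[str],
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Per-topic gender-prevalence effects with bootstrap CIs.

    effect_k = mean(doc_topic_k | woman) - mean(doc_topic_k | man). The CI is
    a percentile interval from a nonparametric bootstrap resampling
    documents within each gender stratum. Topics are labeled
    ``more likely women`` / ``more likely men`` when the CI excludes zero,
    ``indeterminate`` otherwise. Effects sum to zero across topics.
    """
    gender = np.asarray(list(gender))
    if len(gender) != results.doc_topic.shape[0]:
        raise ParameterError("gender covariate length must match document count")
    bad = set(np.unique(gender)) - {"woman", "man"}
    if bad:
        raise ParameterError(f"every document needs gender woman/man; found {bad}")
    theta_w = results.doc_topic[gender == "woman"]
    theta_m = results.doc_topic[gender == "man"]
    if len(theta_w) == 0 or len(theta_m) == 0:
        raise ParameterError("both genders need at least one document")
    effect = theta_w.mean(axis=0) - theta_m.mean(axis=0)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, results.K))
    chunk = max(1, int(5e6 // max(len(theta_w), len(theta_m), 1)))
    for start in range(0, n_boot, chunk):
        stop = min(start + chunk, n_boot)
        b = stop - start
        iw = rng.integers(0, len(theta_w), size=(b, len(theta_w)))
        im = rng.integers(0, len(theta_m), size=(b, len(theta_m)))
        boots[start:stop] = theta_w[iw].mean(axis=1) - theta_m[im].mean(axis=1)
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    lower = np.quantile(boots, lo_q, axis=0)
    upper = np.quantile(boots, hi_q, axis=0)
    labels = np.where(
        lower > 0,
        "more likely women",
        np.where(upper < 0, "more likely men", "indeterminate"),
    )
    return pd.DataFrame(
        {
            "topic": np.arange(results.K),
            "effect": effect,
            "ci_lower": lower,
            "ci_upper": upper,
            "label": labels,
        }
    ).set_index("topic")


# ---------------------------------------------------------------------------
# labeling and diagnostics


def _ranked_words(
    values: np.ndarray, vocab: Sequence[str], tiebreak: np.ndarray | None = None
) -> list[str]:
    """Vocabulary sorted by descending value, then descending tiebreak, then word."""
    if tiebreak is None:
        keys = sorted(range(len(vocab)), key=lambda i: (-values[i], vocab[i]))
    else:
        keys = sorted(
            range(len(vocab)), key=lambda i: (-values[i], -tiebreak[i], vocab[i])
        )
    return [vocab[i] for i in keys]


@dataclass(frozen=True)
class TopicLabelProfile:
    """Top-n word lists per topic under three orderings."""

    n: int
    frex_weight: float
    prob: dict[int, list[str]]
    frex: dict[int, list[str]]
    score: dict[int, list[str]]


def label_topics(
    results: TopicModelResults, n: int = 20, frex_weight: float = 0.5
) -> TopicLabelProfile:
    """Rank each topic's words by probability, FREX and term score.

    * highest probability: topic_word_k descending;
    * FREX: harmonic mean (exclusivity weight ``frex_weight``) of the
      within-topic empirical-CDF ranks of exclusivity
      ex(k, v) = phi_kv / sum_j phi_jv and of phi itself;
    * score: phi_kv * (log phi_kv - mean_j log phi_jv).

    Ties are broken by raw probability, then lexicographically.
    """
    phi = results.topic_word
    vocab = results.vocab
    K, V = phi.shape
    if n > V:
        raise ParameterError(f"n={n} exceeds vocabulary size {V}")
    if not 0 <= frex_weight <= 1:
        raise ParameterError("frex_weight must lie in [0, 1]")
    ex = phi / phi.sum(axis=0, keepdims=True)
    log_phi = np.log(phi)
    score = phi * (log_phi - log_phi.mean(axis=0, keepdims=True))

    prob_lists, frex_lists, score_lists = {}, {}, {}
    for k in range(K):
        ecdf_phi = stats.rankdata(phi[k], method="max") / V
        ecdf_ex = stats.rankdata(ex[k], method="max") / V
        w = frex_weight
        with np.errstate(divide="ignore"):
            frex = 1.0 / (w / ecdf_ex + (1 - w) / ecdf_phi)
        prob_lists[k] = _ranked_words(phi[k], vocab)[:n]
        frex_lists[k] = _ranked_words(frex, vocab, tiebreak=phi[k])[:n]
        score_lists[k] = _ranked_words(score[k], vocab, tiebreak=phi[k])[:n]
    return TopicLabelProfile(n, frex_weight, prob_lists, frex_lists, score_lists)


def semantic_coherence(
    results: TopicModelResults, dtm: DocumentTermMatrix, top_m: int = 10
) -> np.ndarray:
    """Document co-occurrence coherence of each topic's top words.

    C_k = sum_{i=2..M} sum_{j<i} log[(D(v_i, v_j) + 1) / D(v_j)] over the
    topic's ``top_m`` highest-probability words, where D counts documents
    containing the word(s). Less negative is better; a topic whose top
    words always co-occur attains the maximum for the given document
    frequencies.
    """
    if top_m < 2:
        raise ParameterError(f"top_m must be >= 2, got {top_m}")
    word_index = {w: i for i, w in enumerate(dtm.vocab)}
    binary = (dtm.counts > 0).astype(np.int64).tocsc()
    df = np.asarray(binary.sum(axis=0)).ravel()
    out = np.zeros(results.K)
    for k in range(results.K):
        words = results.top_words(k, top_m)
        cols = [word_index.get(w) for w in words]
        c = 0.0
        for i in range(1, len(words)):
            for j in range(i):
                ci, cj = cols[i], cols[j]
                if cj is None or ci is None or df[cj] == 0:
                    warnings.warn(
                        f"topic {k}: word {words[j]!r} absent from all "
                        "documents; pair skipped",
                        stacklevel=2,
                    )
                    continue
                co = int(binary[:, ci].T.dot(binary[:, cj]).toarray()[0, 0])
                c += math.log((co + 1) / df[cj])
        out[k] = c
    return out


def exclusivity(results: TopicModelResults, top_m: int = 10) -> np.ndarray:
    """Mean exclusivity ex(k, v) of each topic's top-``top_m`` words (in [0, 1])."""
    phi = results.topic_word
    ex = phi / phi.sum(axis=0, keepdims=True)
    word_index = {w: i for i, w in enumerate(results.vocab)}
    out = np.zeros(results.K)
    for k in range(results.K):
        cols = [word_index[w] for w in results.top_words(k, top_m)]
        out[k] = float(ex[k, cols].mean())
    return out


# ---------------------------------------------------------------------------
# topic correlations


def topic_correlations(results: TopicModelResults) -> np.ndarray:
    """Pearson correlations of CLR-transformed document-topic proportions.

    The centered-log-ratio transform frees the proportions from the
    simplex closure before correlating; the matrix is symmetric with unit
    diagonal. A zero-variance topic column yields zero correlations (with a
    warning). Note K=2 forces an off-diagonal of -1.
    """
    theta = results.doc_topic
    if results.K < 2:
        raise ParameterError("topic correlations need K >= 2")
    if theta.shape[0] < 3:
        raise ParameterError("topic correlations need at least 3 documents")
    clr = np.log(theta) - np.log(theta).mean(axis=1, keepdims=True)
    sd = clr.std(axis=0)
    corr = np.zeros((results.K, results.K))
    ok = sd > 0
    if not ok.all():
        warnings.warn("zero-variance topic column; its correlations set to 0")
    sub = np.corrcoef(clr[:, ok], rowvar=False)
    corr[np.ix_(ok, ok)] = np.atleast_2d(sub)
    np.fill_diagonal(corr, 1.0)
    return (corr + corr.T) / 2


def correlation_edges(
    corr: np.ndarray, cutoff: float = 0.1
) -> tuple[list[tuple[int, int, float]], list[tuple[int, int, float]]]:
    """(positive, negative) topic-pair edge lists at an |r| cutoff."""
    pos, neg = [], []
    k = corr.shape[0]
    for i in range(k):
        for j in range(i + 1, k):
            r = float(corr[i, j])
            if r >= cutoff:
                pos.append((i, j, r))
            elif r <= -cutoff:
                neg.append((i, j, r))
    return pos, neg


# ---------------------------------------------------------------------------
# topic happiness


@dataclass(frozen=True)
class TopicHappiness:
    """Happiness profile of topics ordered by gender prevalence."""

    per_topic: pd.DataFrame  # topic, rank, mean, sd, n_matched, label
    slope: float
    slope_p: float
    intercept: float
    degenerate: bool
    pairwise: pd.DataFrame  # topic_men_side, topic_women_side, W, p


def topic_happiness_analysis(
    profiles: TopicLabelProfile,
    prevalence: pd.DataFrame,
    lexicon: HappinessLexicon,
) -> TopicHappiness:
    """Score topics by the happiness of their defining words.

    Each topic's top highest-probability words are summarized with
    :func:`emotopic.happiness.set_happiness`. Topics are ranked by their
    gender-prevalence effect (rank 1 = most strongly men, rank K = most
    strongly women); an OLS of word-level happiness scores on topic rank
    tests for a gender-ordered trend, and mirrored topic pairs (ends toward
    the center of the ordering) are compared with rank-sum tests.
    """
    import statsmodels.api as sm

    from emotopic.emotion import rank_sum_test

    topics = list(prevalence.index)
    order = prevalence["effect"].sort_values(kind="mergesort").index.tolist()
    ranks = {t: i + 1 for i, t in enumerate(order)}

    word_scores: dict[int, list[float]] = {}
    rows = []
    for t in topics:
        words = profiles.prob[t]
        sh = set_happiness(words, lexicon)
        word_scores[t] = [
            lexicon.score(w) for w in words if w.lower() in lexicon.scores
        ]
        if sh.n == 0:
            warnings.warn(f"topic {t}: no word matched the happiness lexicon")
        rows.append(
            {
                "topic": t,
                "rank": ranks[t],
                "mean": sh.mean,
                "sd": sh.sd,
                "n_matched": sh.n,
                "label": prevalence.loc[t, "label"],
            }
        )
    per_topic = pd.DataFrame(rows).set_index("topic").sort_values("rank")

    xs, ys = [], []
    for t in topics:
        for s in word_scores[t]:
            xs.append(ranks[t])
            ys.append(s)
    xs_a, ys_a = np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)
    degenerate = bool(len(ys_a) < 3 or np.ptp(ys_a) == 0 or np.ptp(xs_a) == 0)
    if degenerate:
        slope, slope_p = 0.0, 1.0
        intercept = float(ys_a.mean()) if len(ys_a) else math.nan
    else:
        model = sm.OLS(ys_a, sm.add_constant(xs_a)).fit()
        intercept, slope = (float(v) for v in model.params)
        slope_p = float(model.pvalues[1])

    pair_rows = []
    k = len(order)
    for i in range(k // 2):
        t_men, t_wom = order[i], order[k - 1 - i]
        a, b = word_scores[t_wom], word_scores[t_men]
        if a and b:
            res = rank_sum_test(a, b)
            w, p = res.statistic, res.pvalue
        else:
            w = p = math.nan
        pair_rows.append(
            {"topic_men_side": t_men, "topic_women_side": t_wom, "W": w, "p": p}
        )
    pairwise = pd.DataFrame(
        pair_rows, columns=["topic_men_side", "topic_women_side", "W", "p"]
    )
    return TopicHappiness(per_topic, slope, slope_p, intercept, degenerate, pairwise)
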