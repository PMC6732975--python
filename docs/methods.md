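# Methods

This note documents the models and procedures implemented in `emotopic`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data validation does and does not
show about real corpora.

## Text normalization

Cleaning applies a fixed, deterministic step order: lowercase → mention
normalization (`@name` → the literal token `@user`) → URL removal → ASCII
punctuation removal → removal of remaining non-alphanumeric characters
(emoji, typographic punctuation, control characters) → whitespace
tokenization → stopword removal → table-driven lemmatization.

Design choices:

* Mentions are normalized **before** punctuation stripping, so the `@` of
  `@user` survives; `@user` is the single sanctioned exception to the rule
  that tokens contain no punctuation.
* Lemmatization is a plain word→lemma lookup table rather than a
  statistical lemmatizer, so output is reproducible bit for bit. The
  packaged default table covers common regular plurals and frequent
  irregulars; the packaged stopword list contains function words and all
  auxiliary-verb inflections. The two artifacts are mutually consistent —
  no lemma value is a stopword or another table key — which makes the whole
  pipeline idempotent (cleaning the joined output of cleaning is a fixed
  point). Both are inputs and can be replaced per run.
* Hashtags keep their text with `#` stripped; emoji are removed, so emoji
  sentiment is out of scope. Duplicate tweets are kept by default; the
  pipeline exposes a `dedup` flag (per user id + raw text) because source
  studies do not always state whether retweets were removed.

## Emotion scoring and group comparison

Scoring is bag-of-words: each token increments every category its lemma is
associated with in the 10-category word-emotion lexicon (eight Plutchik
emotions plus negative/positive). No negation or valence-shifter handling
is attempted; that is a property of the lexicon method itself.

The per-tweet proportion statistic for category X is
`n_X / (n_negative + n_positive)`. Tweets with a zero denominator are
**excluded** from comparisons rather than imputed: the statistic is
undefined there, and retaining them would require an arbitrary value.
Per-tweet (not per-user) proportions enter the tests, so degrees of freedom
are on the tweet scale.

The variance-ratio test reports F = var(x)/var(y) with (n_x−1, n_y−1)
degrees of freedom and a two-sided p (twice the smaller tail). The rank-sum
test uses the Mann–Whitney U convention (W counts pairs x_i > y_j plus half
the ties); p-values are exact by enumeration for small tie-free samples and
otherwise use the normal approximation with tie and continuity corrections.
Women are sample x throughout, so W above n·m/2 means women stochastically
higher. Both tests are always computed; reports may annotate rather than
suppress near-null cases (e.g. F ≈ 1).

Monthly series average defined per-tweet proportions by UTC calendar month
and gender; months with no defined values are absent, not zero.

## Happiness

A text's happiness is the frequency-weighted mean of the 1–9 scores of its
matched words. The lens parameter δ (default 0) excludes words with
5 − δ < h < 5 + δ; δ ≥ 4 is rejected because it would empty the scale
interior. The default of no lens was chosen because topic- and
cluster-level summaries in this workflow include mid-scale vocabulary
(words like "stroke", h ≈ 2.6, sit well below the lens band anyway, but
neutral words like "park" would otherwise vanish); the flag remains
available for sensitivity analyses.

Daily aggregation pools matched word occurrences across a day's tweets per
gender (wordier tweets weigh more). A per-user variant — average per user
within the day, then across users — is exposed as an option because either
reading of "summarized on a daily basis for each user" is defensible; the
pooled form is the default.

Word-set summaries (used for topics) are unweighted: mean and n−1 sample SD
over distinct matched words, SD = 0 for a single word, missing for none.

## Topic model

The document-term matrix uses a lexicographically sorted vocabulary and
optional minimum-count pruning. TF-IDF pruning scores each term as the mean
over documents containing it of `(count/len) · log2(D/df)` and drops terms
with score ≤ 0.1 (the mean-over-containing-documents aggregation and log
base 2 are this package's convention); documents emptied by pruning are
dropped with their ids recorded.

Topics are fitted by collapsed Gibbs sampling of LDA with symmetric priors
α (default 50/K) and β (default 0.1). `topic_word` and `doc_topic` are
posterior means over post-burn-in samples (default thinning 10); the
complete-data log likelihood log P(w|z) is tracked every sweep. Runs are
exactly reproducible given a seed. Note that α = 50/K is the classical
long-document heuristic; for short documents (tweets, ~10–30 tokens) a
smaller α (≈ 1) lets document-topic proportions concentrate and is what the
recovery experiments use where noted.

A full covariate-aware structural topic model (variational EM with a
logistic-normal prior) is deliberately **not** implemented. Its reported
outputs are reproduced by transparent surrogates on the Gibbs fit:

* **Prevalence**: effect_k = mean(θ_k | women) − mean(θ_k | men), with a
  percentile CI from a nonparametric bootstrap over documents (stratified
  within gender so both groups stay represented in every replicate), and a
  label by sign when the 95% CI excludes zero. Effects sum to zero by
  construction (composition means).
* **Topic correlations**: Pearson correlation across documents of
  centered-log-ratio transformed θ columns, standing in for the
  logistic-normal covariance. The CLR transform removes the simplex
  closure; K = 2 necessarily yields r = −1.

Topic-number diagnostics: Griffiths2004 is the harmonic-mean estimator of
the marginal log likelihood over retained samples (maximize); CaoJuan2009
the mean pairwise cosine among topic-word rows (minimize); Arun2010 the
symmetric KL divergence between the normalized singular values of the
topic-word matrix and the length-weighted document-topic marginal
(minimize); Deveaud2014 the mean pairwise Jensen–Shannon divergence among
topic-word rows, natural log (maximize). `select_k` informs; it never
auto-picks K.

Word profiles: *highest probability* ranks by φ_kv; *exclusivity* is
ex(k,v) = φ_kv / Σ_j φ_jv; *FREX* is the harmonic mean (exclusivity weight
w, default 0.5) of the within-topic empirical-CDF ranks of ex and of φ;
*score* is φ_kv(log φ_kv − mean_j log φ_jv). The score is the standard
entropy-tilted term score; a literal ratio of log frequencies would be
numerically ill-behaved near φ → 1/V and was not used. Ties are broken by
raw probability, then lexicographically — the probability tiebreak keeps
all three orderings equal to frequency order in the degenerate K = 1 case,
where the score is identically zero.

Semantic coherence is the Mimno-style document co-occurrence score
`Σ_{i<j} log[(D(v_i,v_j)+1)/D(v_j)]` over each topic's top-m words
(default 10); exclusivity diagnostics report the mean ex of the top words,
which lies in [0, 1].

The topic-happiness analysis scores each topic's top highest-probability
words with the happiness lexicon, orders topics by their gender-prevalence
effect (rank 1 = most-men … rank K = most-women), and fits a word-level OLS
of happiness on rank; the observation unit is the word because topics
contribute different numbers of matched words. Degenerate designs (constant
scores, a single rank, fewer than 3 points) report slope 0, p 1 with a
flag. Pairwise comparisons take mirrored pairs of the ordering (ends toward
the center) and apply the rank-sum test to the two topics' word-score
lists.

## Synthetic data

The generator plants: per-gender category emission probabilities π(g, c)
(defaults encode the canonical direction — women elevated on
joy/trust/anticipation/positive at 0.03 vs 0.02/0.015, men on
fear/sadness/disgust/negative); K disjoint uniform topic-word blocks with
Dirichlet document proportions whose per-gender means can be shifted;
neutral fillers absorbing the remaining mass (the `topic_token_rate` knob
splits non-emotion mass between topics and fillers); happiness scores drawn
per word around a category profile (positive categories ≈ 7, negative ≈ 3,
neutral ≈ 5, SD 0.4, clipped to [1, 9]); timestamps uniform over a
configurable window (default August 2007 – December 2018); and user
metadata (lifetime counts, followers, ~79% geolocated across four
countries, 3–6 list memberships). Emotion-category words also carry the
matching sentiment label (joy/trust/anticipation → positive;
anger/disgust/fear/sadness → negative; surprise neutral), mirroring the
structure of real word-emotion lexicons and keeping the proportion
statistic's denominator dense. Emotion and topic vocabularies are disjoint
by default so emotion- and topic-recovery tests are independent; an overlap
knob exists.

Every token's provenance (category, topic or filler), the planted
distributions and the lexicons are recorded for recovery tests, and
generation is fully seeded (same seed → byte-identical files).

What passing the synthetic suites shows: the implementation detects planted
effects of realistic size at the stated rates and recovers planted topics.
What it does not show: robustness to real linguistic phenomena — negation,
sarcasm, topic drift, bursty posting, vocabulary mismatch between lexicon
and corpus, retweet duplication — none of which the generator emulates.

## Validation problem sizes

The standard recovery conditions, chosen once as realistic for this class
of study and used by both the test suite and the acceptance script:
joy-excess detection with women/men joy emission 0.06/0.04 on 200 users per
gender × 50 tweets, 20 seeds (expected detection at p < .01 in ≥ 95% of
seeds); topic recovery on V = 200, K = 5, D = 1000, ~30 tokens/document
(Hungarian-matched cosine ≥ 0.9); a +0.10 women-prevalence shift on one of
3 topics over 300 documents, 20 seeds; null calibration over 100 replicate
corpora with identical emission rates (rank-sum rejection ≈ the nominal
5%). Null replicates pool per-emotion decisions, which are correlated
within a replicate (the two sentiment polarities are complementary), so the
pooled rate is checked against a widened band rather than a binomial
interval.

## Known limitations

* Bag-of-words lexicon scoring; no per-user random effects (users
  contributing many tweets weigh proportionally).
* The prevalence/correlation surrogates approximate, but are not, a joint
  covariate-aware topic model; CIs do not propagate topic-assignment
  uncertainty (θ is fixed at its posterior mean before the bootstrap).
* The Gibbs sampler is a straightforward single-chain implementation;
  label switching across runs is handled in experiments by Hungarian
  matching, not inside the sampler.
* Cohort percentages follow fixed rounding conventions (means to integers,
  fractions to 1 decimal, geolocation/country to 2); printed sources that
  round differently will differ in the last digit.
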