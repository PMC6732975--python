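# emotopic

Gender-stratified emotion, happiness and topic analysis of microblog
corpora.

`emotopic` is a reusable, tested implementation of a common infodemiology
workflow: given a corpus of short social-media posts (tweets) whose authors
carry a gender label, it measures how emotional language, expressed
happiness and topical content differ between women and men. The pipeline
was designed for health-community corpora (e.g. posts by chronic-condition
survivors recruited through curated Twitter lists), where the question is
whether the two groups express systematically different affect and talk
about systematically different things.

Because such corpora usually cannot be redistributed, the package ships a
synthetic-corpus generator that plants known gender effects (emission
rates, topic prevalence shifts, happiness gaps) and records the ground
truth, so every stage of the analysis is validated end to end without any
download.

## What it computes

**Emotion analysis (Plutchik categories).** Each cleaned token adds one
count to every category its lemma carries in an EmoLex-style word-emotion
lexicon (eight basic emotions — anger, anticipation, disgust, fear, joy,
sadness, surprise, trust — plus *negative*/*positive* sentiment). The
per-tweet *emotion proportion* for a category X is

```
proportion_X = n_X / (n_negative + n_positive)
```

undefined when the tweet matches no sentiment-bearing word. For the two
sentiment polarities the proportions are complementary:
`proportion_positive + proportion_negative = 1` wherever defined. Group
comparison pools defined per-tweet proportions by author gender and applies
a two-sided variance-ratio F test followed by a Wilcoxon rank-sum
(Mann–Whitney U) test, with medians/means, monthly time series and a raw
per-gender frequency table.

**Happiness (hedonometer-style).** Each word carries a crowd-rated mean
happiness score h ∈ [1, 9] (labMT format). A text's happiness is the
frequency-weighted mean of its matched words; daily series pool at the word
level per gender; word sets (e.g. a topic's defining words) get an
unweighted mean ± SD. An optional lens excludes near-neutral words
(5 − δ < h < 5 + δ).

**Topic model with a gender covariate.** Documents → document-term matrix →
TF-IDF pruning (score ≤ 0.1 dropped) → latent Dirichlet allocation fitted by
collapsed Gibbs sampling (`GibbsLDA(dtm, K).fit(...)` returns a
`TopicModelResults` with posterior-mean `topic_word`/`doc_topic`,
log-likelihood trace and `summary()`). On top of the fit: topic-number
diagnostics (Griffiths2004, CaoJuan2009, Arun2010, Deveaud2014); per-topic
gender-prevalence effects `E[θ_k | woman] − E[θ_k | man]` with stratified
bootstrap CIs and *more likely women / more likely men* labels; word
profiles by highest probability, FREX and term score; semantic coherence
and exclusivity; CLR-based topic correlations; and a topic-happiness
analysis that regresses word happiness on the topics' gender-prevalence
ordering and compares mirrored topic pairs.

## Worked example

```python
from emotopic.synthetic import SyntheticConfig, generate_corpus
from emotopic.emotion import compare_groups

cfg = SyntheticConfig(n_users_per_gender=50, tweets_per_user=20, seed=1)
corpus, emo_lex, hap_lex, truth = generate_corpus(cfg)
comp = compare_groups(corpus, emo_lex, ["joy", "sadness", "positive"])
print(comp[["mean_women", "mean_men", "F", "p_f", "W", "p_w"]].round(4))
```

```
          mean_women  mean_men       F     p_f         W  p_w
emotion
joy           0.1503    0.1054  1.4059  0.0000  464240.5  0.0
sadness       0.0707    0.1306  0.5263  0.0000  370507.0  0.0
positive      0.6280    0.3604  1.0733  0.2832  604802.0  0.0
```

The default generator plants the canonical direction of effects — women
elevated on joy/trust/anticipation/positive emissions, men on
fear/sadness/disgust/negative — and the comparison recovers exactly that:
women's mean joy proportion (0.150) exceeds men's (0.105), sadness is
reversed, and the rank-sum test rejects decisively (W is the Mann–Whitney U
of the women sample; `p_w < 1e-4` prints as 0). The F test compares the
two variances (joy variances differ, F = 1.41).

Topic recovery on the planted-topic fixture (5 disjoint 40-word topics,
1000 documents of ~30 tokens):

```python
from emotopic.experiments import topic_fixture_config
from emotopic import topics as tp

cfg = topic_fixture_config(seed=1)
corpus, _, hap_lex, truth = generate_corpus(cfg)
dtm = tp.build_dtm(corpus)
res = tp.fit_lda_gibbs(dtm, 5, n_iter=200, burn_in=100, seed=1)
print(res.summary(n=5))
```

```
GibbsLDA results: K=5, V=200, D=1000, alpha=10, beta=0.1, seed=1
mean sample log-likelihood: -114203.40
topic 0 (mean share 0.200): t3w005, t3w017, t3w034, t3w009, t3w015
topic 1 (mean share 0.199): t4w029, t4w035, t4w009, t4w010, t4w005
topic 2 (mean share 0.203): t2w034, t2w012, t2w035, t2w018, t2w032
topic 3 (mean share 0.202): t0w020, t0w019, t0w010, t0w034, t0w033
topic 4 (mean share 0.195): t1w038, t1w018, t1w014, t1w011, t1w007
```

Each fitted topic's top words come from a single planted block (words
`t3w***` belong to planted topic 3, and so on): the sampler separates the
five topics cleanly (Hungarian-matched cosine ≥ 0.99 against the planted
distributions).

## Command line

```bash
emotopic synth --out bundle/ --seed 1          # synthetic corpus + lexicons
emotopic cohort bundle/corpus.jsonl --users bundle/users.csv
emotopic emotions bundle/corpus.jsonl --users bundle/users.csv \
    --lexicon bundle/emolex.txt --out-dir report/
emotopic report config.yaml                    # full pipeline from YAML
```

`report` writes TSV tables (emotion table, group comparison, monthly and
daily series, topic profiles/diagnostics/prevalence/correlations,
topic-happiness) plus a `manifest.json` with the config hash and seed; the
same config and seed reproduce every file byte for byte.

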