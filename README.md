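# voices

Analysis pipeline for multilingual rare-disease patient surveys: rating
statistics across disease groups, topic modelling of open-text answers, and
distinctive-phrase extraction per disease group.

It is written for researchers analysing patient-reported priority surveys —
cohorts of respondents who rate prespecified research topics on a 3-point
priority scale (1 = very important, 3 = less important; lower mean = higher
priority) and answer open questions in free text, grouped into disease
areas (MTGs, main thematic groups).

## What it computes

**Quantitative arm** (`voices.stats`, `voices.survey`):

- demographic tables (count, percent per category) with UN Statistics
  Division region mapping and keyword-guarded cohort exclusion rules;
- per-topic rating summaries (n, mean, SD) and priority ranking;
- paired-samples t-tests between topics, one-way ANOVA between groups, and
  all-pairs post-hoc t-tests with Bonferroni correction
  (p_adj = min(1, m·p_raw)).

**Text arm** (`voices.corpus`, `voices.topics`, `voices.phrases`):

- normalisation: lowercasing, punctuation stripping, rule-based
  lemmatisation, stop-word masking;
- TF-IDF weighting (tf · ln(N/df), so ubiquitous words weigh zero) and
  non-negative matrix factorisation (NMF) topic models, W·H ≈ X with
  W, H ≥ 0, topics read off as top-weight terms;
- TC-W2V model-order selection: corpus-trained skip-gram embeddings, topic
  coherence = mean pairwise cosine similarity of a topic's top-10 terms,
  k* = argmax of mean coherence;
- KLIP phrase ranking per disease group against a background corpus:
  informativeness I = P_fg·ln(P_fg/P_bg), phraseness
  P = P_fg·ln(P_fg/∏P_fg(wᵢ)), score = γ·I + (1−γ)·P with γ = 0.8, over
  1–4-word candidates that never start/end with a stop word, occur at
  least twice, and are de-duplicated per respondent for 3–4-grams.

**Synthetic cohorts** (`voices.synthetic`): because raw data of such
surveys are typically not shareable, a seeded generator produces cohorts
with planted structure — demographic proportions, per-(group, topic) rating
shifts, planted topic-word distributions, group-specific phrases, and a
background corpus — so the whole pipeline is testable against known truth.

See `docs/methods.md` for models, assumptions, parameter defaults and
limitations.

## Worked example

```python
from voices import corpus, phrases, stats, survey, synthetic, topics

# a 300-respondent synthetic cohort with the default planted structure
cohort = synthetic.generate_cohort(synthetic.CohortSpec(n_respondents=300, seed=1))
spec = synthetic.default_text_spec(k_true=3, seed=1)
docs = corpus.prepare(synthetic.generate_open_text(spec, cohort))

records = survey.records_from_table(cohort, docs)
summaries = [stats.summarise_ratings(records, t) for t in synthetic.TOPICS]
order, _ = stats.rank_topics(summaries)
print(order[:3])

matrix = topics.build_tfidf(docs)
emb = topics.embeddings_for(docs, seed=1)
sel = topics.select_k(matrix, range(2, 7), emb, seed=1)
print(sel.k_star, round(sel.results[sel.k_star].mean_coherence, 3))

bg = synthetic.generate_background_corpus(spec, 50_000)
ranked = phrases.rank_by_group(docs, bg)
print([s.text for s in ranked["Adrenal"][:3]])
```

prints (seed 1):

```
['physical_discomfort', 'work', 'social_life']
3 0.295
['adrenal crisis', 'adrenal', 'crisis']
```

i.e. the three functional-outcome topics rank most important (lowest mean
priority score), the coherence criterion recovers the three planted text
themes (mean TC-W2V coherence 0.295 at k = 3), and the Adrenal group's
phrase ranking is led by its planted signature phrase "adrenal crisis".

The same analyses run from the shell:

```sh
voices simulate --out data/ --seed 1
voices run --config config.yaml
```

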