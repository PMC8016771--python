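# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Setting

The pipeline targets multilingual patient surveys on rare endocrine
conditions: respondents report demographics (gender, age band, country,
disease group — one of eight main thematic groups, MTGs — advocacy-group
membership, patient/caregiver role), rate nine prespecified research topics
on a 3-point priority scale (1 = very important, 3 = less important; a
*lower* mean marks a *higher* priority), and answer open questions in free
text. The raw survey data of the motivating study were never deposited, so
the package ships a synthetic-cohort generator that reproduces the
*statistical structure* of such a survey and lets every downstream stage be
validated against planted ground truth.

## Quantitative arm

- **Summaries.** Per topic: n over non-missing ratings, mean, sample SD
  (n−1). Topics are ranked by ascending mean; exact ties break
  lexicographically and are flagged.
- **Between-topic tests.** Paired-samples t on complete pairs:
  t = mean(d)/(sd(d)/√n), df = n−1, two-sided p. Zero-variance differences
  are flagged degenerate with p = 1 (zero mean difference) or p = 0
  (constant nonzero shift) by convention rather than raising.
- **Between-group tests.** One-way ANOVA (F = MS_between/MS_within,
  df = (g−1, N−g)) followed by all g(g−1)/2 post-hoc pairwise t-tests with
  Bonferroni adjustment p_adj = min(1, m·p_raw), m = number of pairs.
  Post-hoc tests default to Welch's unequal-variance t because group sizes
  in such cohorts are highly unbalanced (39% vs 1.6% of the cohort); a
  pooled-variance option exists. All tests are two-sided, complete-case
  (pairwise deletion), significance 0.05. The gender contrast is run as
  female vs male; "prefer not to say" respondents stay in the demographics
  but not in the contrast.
- **Demographics.** Percentages are 100·count/total rounded half-up to one
  decimal, the presentation convention of published cohort tables.
- **Regions.** Countries map to the UN Statistics Division scheme (Eastern
  / Northern / Southern / Western Europe, everything else Non-Europe) via a
  shipped table keyed by ISO-3166 alpha-2 code, name, and common aliases.
  Unknown countries raise — they are never silently Non-Europe.

## Text arm

### Normalisation

Open answers are lowercased, punctuation-stripped, and lemmatised by a
deterministic rule-based lemmatiser (irregular-form table, plural
stripping, -ing/-ed reduction with doubled-consonant and silent-e repair).
It is idempotent on its own output, which keeps fixtures and reruns
reproducible; it is deliberately not a full morphological analyser, and
occasionally over- or under-stems (e.g. *doing* is left unchanged). Stop
words from a shipped ~130-word function-word list are **marked, never
removed**: phrase extraction needs original token adjacency to enforce its
boundary rules, while topic modelling simply skips masked tokens.
Translation is a pluggable hook (default: identity); a failing translator
leaves a document untranslated and logged, never dropped.

### TF-IDF and NMF

weight(d, t) = tf(d, t) · ln(N/df(t)), with raw term counts and an
unsmoothed idf so that a term in every document weighs exactly zero.
Stop words, terms below min_df (default 2) and ubiquitous terms are pruned.
Topics come from scikit-learn's NMF (Frobenius objective, deterministic
NNDSVD initialisation, max 500 iterations, tol 1e-5); each topic is read
off as its t = 10 highest-weight terms.

### TC-W2V model-order selection

Skip-gram-with-negative-sampling embeddings are trained on the analysis
corpus itself (dimension 100, symmetric window 5 with per-position dynamic
window sampling, min_count 1 so every modelled term has a vector, 5
negatives, 50 epochs, frequent-word subsampling threshold 5e-3, single
stream, seeded). Topic coherence is the mean pairwise cosine similarity of
a topic's top-10 terms; a model's score is the mean over topics; k* is the
coherence argmax over the candidate range (default 2–6 in the pipeline),
ties toward the smaller k and flagged.

Two training choices matter on small corpora and were fixed after
inspecting embedding quality (within-theme vs cross-theme similarity), not
the selection outcome alone: mini-batches of 1024 (larger batches
accumulate hot-word gradients within a batch and diverge) and the 5e-3
subsampling threshold (the word2vec default 1e-3 downsamples the most
frequent words so hard that precisely the head terms appearing in top-10
lists stay under-trained, making selection noisy).

### KLIP phrase extraction

Per MTG, candidates are all 1–4-token n-grams occurring wholly inside one
response, not starting or ending with a stop word, occurring at least
twice; 3–4-gram occurrences repeated by one respondent count once.
With per-length relative frequencies P_fg (candidate counts over all
n-gram occurrences of that length in the group) and an add-one-smoothed
background model P_bg (over the union vocabulary of foreground and
background n-grams of that length):

- informativeness I(w) = P_fg(w) · ln(P_fg(w)/P_bg(w))
- phraseness P(w) = P_fg(w) · ln(P_fg(w)/∏ᵢ P_fg(wᵢ)), defined 0 for
  single words
- klip(w) = γ·I(w) + (1−γ)·P(w), γ = 0.8

Natural logarithms throughout. γ multiplying informativeness follows the
original KLIP formulation; the orientation is switchable
(`gamma_weights="phraseness"`). Ranking ties break by foreground count,
then lexicographically. The ranking is checked against a brute-force
oracle (direct enumeration of every n-gram and both KL terms) to 1e-12 on
small corpora.

## Synthetic data generator

- **Cohort.** Category proportions default to the published cohort of the
  motivating survey (n = 1378): 78.7% female, 39.1% Adrenal, 47.1%
  Northern Europe, etc. Each rating is a Gaussian draw — per-topic baseline
  (defaults: the published whole-cohort means, 1.26–1.75) plus an optional
  per-(MTG, topic) shift, sd 0.7 — rounded to the nearest integer and
  clamped to {1, 2, 3}. Missingness is completely at random (default 2%);
  the nine topics are drawn independently per respondent (the real
  between-topic correlation structure is unknown and not emulated — a
  documented limitation).
- **Text.** Three planted themes (treatment burden; fatigue/daily
  function; heredity/fertility), each a Zipf-weighted ~36-word vocabulary
  (85% of mass) plus shared fillers including function words (15%). Each
  respondent has a primary theme; each word comes from it or, with
  probability 0.3, from another theme. Pure single-theme documents turn
  out not to penalise under-modelling at all — NMF with too small a k
  simply drops a theme rather than merging two, and coherence stays high —
  whereas mixed documents force blended components at small k, which is
  also what real answers look like. Documents are 8–30 words (short open
  answers); two open questions per respondent. Group-specific 2–4-word
  phrases (e.g. "adrenal crisis" for the Adrenal group) are spliced in
  verbatim with probability 0.35 per document.
- **Background.** A token stream (default ~50k tokens, 20-token lines)
  drawn from a vocabulary mixing generic encyclopedic words (60% of mass)
  with the ordinary themed vocabulary (40%): a realistic generic corpus
  contains everyday health/life vocabulary at moderate rates, while the
  group-specific planted phrases are absent from it — which is exactly why
  they, and not common survey words, stand out under informativeness.
- Each sub-generator (cohort, text, background) draws from its own stream
  derived from the master seed, so activating one never perturbs another.

What passing the planted-structure experiments shows: the estimator
correctly recovers the structure its model assumes, at realistic desk
scale. What it does not show: robustness to machine-translation noise,
heavy-tailed answer lengths, multi-theme respondents with correlated
ratings, or vocabulary far larger than documents — real-survey properties
the generator does not emulate.

## Validation experiment sizes

- Planted-k recovery: 10 corpora of 600 documents (300 respondents × 2
  questions, ≈11k content tokens), k range 2–6; recovery of k = 3
  expected in ≥ 8/10. At half this corpus size the corpus-trained
  embeddings are too noisy for coherence to distinguish k reliably — the
  experiment size is chosen as the smallest at which selection is stable.
- Planted-phrase recovery: one 300-respondent corpus per seed; every
  planted phrase must rank in its own group's top 10 and no other group's.
- Power/type-I: 100 cohorts of 1600 (8 equal groups of 200), planted 0.4
  shift on one (MTG, topic); the affected pair's Bonferroni-adjusted
  post-hoc test must reject in ≥ 90 runs; with no effect, the family-wise
  error over 28 pairs stays within the binomial 99% band around 5%.
- Determinism: two identical 80-respondent pipeline runs must produce
  byte-identical output manifests (SHA-256).

## Known limitations

- The lemmatiser is heuristic; tokens it mangles remain internally
  consistent but can look odd in reports (e.g. *counselling* → *counsell*).
- Corpus-trained embeddings need a few thousand content tokens; on very
  small corpora coherence-based selection of k degrades gracefully but
  noticeably (see above).
- The KLIP foreground model uses deduplicated candidate counts over raw
  occurrence totals; alternatives (deduplicating totals too) would change
  scores by a near-constant factor and not the ranking in practice.
- Phraseness uses foreground unigram probabilities; a
  background-product variant is not implemented.
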