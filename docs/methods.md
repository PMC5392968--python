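# Methods

This note documents the models implemented in `meshrank`, the
parameters that matter, the synthetic data the tests run on, and the
design decisions taken where the design was genuinely open.

## Problem setting

Given a document (title + abstract) and a controlled vocabulary of
hierarchical descriptors, predict the set of descriptors a human
indexer would assign. The task is treated as *ranking*: generate a
candidate list from several recall-oriented sources, score each
candidate's relevance with a learned model, and cut the ranked list to
a final prediction set.

## Text processing

All text is case-folded, tokenized into maximal alphanumeric runs,
stripped of a standard English stop-word list (scikit-learn's built-in
list, 318 words, configurable) and stemmed with the Porter algorithm
(implemented in `meshrank.text`, verified against the algorithm's
published example reductions). The same pipeline is applied to
document text and to descriptor names, so overlap-style features
compare like with like.

## Candidate source 1: k-nearest neighbours

Documents are embedded as L2-normalized tf-idf vectors over stemmed
unigrams, idf(t) = ln((N+1)/(df(t)+1)) + 1; similarity is the cosine
(dot product of normalized vectors). Gold annotations are *never*
indexed as text — similarity depends only on the words two documents
share — and the index can be restricted to documents annotated after a
configurable date floor (default 2009-01-01), because annotations made
against older vocabulary editions mislead a recency-sensitive task.

Neighbour count is dynamic. The top `probe` (= k_max) candidates set
the mean similarity s̄, mapped linearly onto

    k = round(k_min + (k_max − k_min) · clamp((s̄ − s_lo)/(s_hi − s_lo), 0, 1))

with k_min = 10, k_max = 40. The cited direction ("weaker
neighbourhoods, fewer neighbours") fixes the sign of this map but not
its form; the clamped linear interpolation is this package's choice.
The thresholds s_lo/s_hi default to the 10th/90th percentile of
per-document neighbour-mean similarity, estimated at index build on a
deterministic stride subsample of at most 500 documents (keeping the
calibration O(n·500) instead of O(n²)); both are configurable.
Retrieval excludes the query's own doc_id and breaks similarity ties
by doc_id, so output is a total order. When fewer than k_min
candidates exist, all are returned and the result carries an
`underfilled` flag.

## Candidate source 2: per-label classifiers

One binary classifier per frequent label (the paper-scale default asks
for the 20,000 most frequently annotated labels; toy vocabularies
train all of them). Features are L2-normalized stemmed-unigram term
frequencies. The objective is the cost-sensitive SVM with modified
Huber loss shown in the README; C₊ = r·C₋ with r = 1.5 weights the
scarce positive class more heavily. h is quadratic inside the margin
and linear beyond it, keeping gradients bounded on noisy labels.

The optimizer is stochastic gradient descent with inverse-t decay
(η_t = η₀/(1 + t/n), η₀ = 0.5, 10 epochs by default), seeded and
deterministic; a full-batch mode with backtracking line search is
provided when a provably monotone cost trajectory is wanted (the
objective is convex, so backtracking guarantees descent). Each label's
training set keeps all positives and a seeded random sample of at most
10× as many negatives: training every label on the full skewed corpus
is known to depress classifier quality, and the cap bounds per-label
cost. The cap, like every SGD seed, derives deterministically from the
label name and the global seed, so results are independent of worker
count and scheduling order. Labels without both classes are skipped
and reported in the persisted manifest.

The decision value θ + w·x is retained as a ranking feature for every
candidate whose label has a model — also for candidates the classifier
did not itself propose — with a companion presence indicator so the
ranker can distinguish "scored 0" from "unscored".

## Candidate source 3: external recommender

An arbitrary `doc_id → term list` TSV can be merged in; its only
footprint downstream is the binary `external_flag` feature and the
provenance flag. For self-contained testing the synthetic module
provides a rule-based pseudo-recommender (top-m name-overlap matcher),
which is a deliberately simple synthetic stand-in exercising the
interface, not a model of any production recommender.

## Feature models

- **IBM Model 1** translation probabilities t(term_token | doc_token),
  trained by EM from the canonical uniform start on (term-name tokens,
  document tokens) pairs. The conditioning side is the document
  (source language), matching the direction used in query-translation
  scoring. Normalization Σ_q t(q|w) = 1 is asserted after every
  iteration; training stops after 20 iterations or when the data
  log-likelihood improves by less than 1e−4. For tractability the
  trainer samples a configurable number of pairs (default 2,000) and
  truncates the document side to its 60 highest-frequency tokens.
- **BM25** with k1 = 1.2, b = 0.75 and idf = ln((n − df + 0.5)/(df +
  0.5) + 1) — the conventional parameterization; the method only names
  the model.
- **Translation query likelihood**: Σ_q log(mix · Σ_w t(q|w)·p_ml(w|d)
  + (1 − mix)·p_bg(q)) with Jelinek-Mercer mix = 0.5 and a smoothed
  background unigram model p_bg(q) = (df(q)+0.5)/(Σdf + 0.5(|V|+1))
  built from the background sample. A −inf sentinel is returned only
  in the degenerate mix = 1, zero-evidence case; the feature extractor
  floors it at −10⁶.
- **Background statistics** (document frequencies, average length)
  come from a sample of the training corpus (default cap 60,000
  documents, i.e. the entire corpus at fixture scale).
- **Overlap and synonym features** use the preferred name only for
  unigram/bigram overlap (fractions of the name's stemmed
  unigrams/bigrams present in the text) and the synonym list only for
  the binary synonym feature (case-folded substring match on the raw
  title + abstract). The translation feature is the product over name
  tokens of the best per-document-token translation probability, each
  factor floored at 1e−9.

## Ranking

LambdaMART with binary gains (2^y − 1 ∈ {0,1}), discount
1/log₂(pos+1), and NDCG truncated at list length (candidate lists are
short, so no cut is applied inside the gradient). Per boosting round,
for every (positive, negative) pair in a list:

    ρ = 1/(1 + exp(σ(s⁺ − s⁻))),  λ± ± = σ·ρ·|ΔNDCG|,  h = σ²·ρ(1−ρ)·|ΔNDCG|

where |ΔNDCG| is the exact NDCG change from swapping the pair in the
current ordering. A regression tree is fitted to the lambdas by greedy
best-first variance-reduction splitting (deterministic tie-breaks:
lowest feature index, then first qualifying cut), leaf values take a
Newton step Σλ/Σh, and the tree joins the ensemble with shrinkage 0.1.
Defaults — 300 trees, 10 leaves, min 1 observation per leaf — follow
common boosted-ranker practice and are all configurable; the pipeline
configs in this repository use 100–150 trees, which is past the point
where training NDCG plateaus on the synthetic corpora. The trained
model stores a hash of the feature schema and refuses to score vectors
from a different schema. Scoring ties are broken by descriptor id.

Training lists come from a seeded sample of annotated documents
(paper-scale default 5,000; fixture-scale configs use 150–300), each
list labelled by gold membership; lists without both classes carry no
gradient and are dropped.

## Post-processing

Order: age-tag injection → specificity pruning → score cutoff. The
composition is idempotent.

- **Age check tags**: a ±60-character window around each
  "age"/"aged"/"ages" keyword is scanned for integers; ranges ("8-10")
  contribute both endpoints, and a following unit word selects months
  (years otherwise). Ages map through an ordered first-match-wins
  bracket list using the conventional NLM age-group boundaries
  (newborn 0–1 m, infant 1–23 m, preschool 2–5 y, child 6–12 y,
  adolescent 13–18 y, young adult 19–24 y, adult 19–44 y, middle aged
  45–64 y, aged 65+ y, 80-and-over 80+ y). Several nominal ranges
  overlap; listing the more specific bracket first makes the effective
  ranges disjoint, which the rule validator relies on. Detected tags
  missing from the prediction are injected at the head with score
  max + ε so the cutoff cannot immediately drop them; detection only
  ever *adds* tags. Brackets whose names are absent from the loaded
  vocabulary are dropped, so partial vocabularies work.
- **Specificity pruning** removes a term when any hierarchy descendant
  (strict tree-number prefix, any depth — not just direct children)
  is ranked strictly higher. Parents ranked above their children are
  kept: both can legitimately co-occur.
- **Score cutoff**: after capping at N = 25, keep positions 1..i for
  the smallest i ≥ 2 with S_{i+1} < S_i · ln(i) · λ, λ = 0.3. At i = 1
  the rule would read S₂ < 0 (ln 1 = 0) and discard everything but one
  term whenever scores are positive, so the rule is evaluated from
  i = 2 — a deliberate reading of an ambiguous formula. The log base is
  natural; at least `min_keep` (= 1) term always survives.

## Evaluation

Per-document precision/recall/F1 with the usual empty-set conventions
(empty prediction against empty gold counts as 1.0), averaged two
ways: example-based (mean of per-document values, the headline number)
and micro-averaged (pooled TP/FP/FN), plus a per-label F1 table for
error analysis. Which averaging a given published table used is often
unstated; reporting both sidesteps the ambiguity.

## Synthetic data

`FixtureSpec` defaults define the study conditions: a depth-3,
branching-3 balanced hierarchy (39 descriptors), 2,000 documents,
labels per document ~ negative binomial (dispersion 5) truncated to
[1, 39] with mean 12.7, Zipf-like label popularity (weight ∝
1/rank^0.7), 8 signature pseudowords per label, noise rate 0.3, and a
check-tag fraction of 0.25 whose first ten members take the
conventional age-group names. Document text mixes signature words of
the document's gold labels with background words; descriptor names are
built from their own signature words so name-overlap and translation
features carry learnable signal; gold age tags are accompanied by
explicit "aged N years/months" phrases. Pseudowords are CVC-syllable
triples checked to be stable under stemming.

What the generator does **not** emulate: real English morphology and
syntax, label correlations beyond popularity skew, annotation noise or
indexer disagreement, and vocabulary drift over time. Passing tests
therefore demonstrate that the machinery is correct and that the
method recovers structure *when its assumptions hold*, not that any
particular F1 transfers to PubMed-scale corpora.

## Problem sizes and numerics

The shipped test suite and the acceptance script train on 1,800 of
2,000 synthetic documents with 39 labels, 300 ranker lists, 2,000
translation pairs and 150 trees — sizes chosen so a full run completes
in a few minutes on one CPU while every component still has signal to
learn. Degenerate inputs are handled explicitly: empty candidate lists
(warned, allowed), single-class labels (skipped with a reason),
all-equal-label ranking lists (zero gradient), lists with no relevant
item (NDCG 1.0 by convention), unknown query tokens (df = 0 branch in
BM25, smoothed background elsewhere). Determinism is a contract: one
top-level seed drives every random choice, per-label/per-document work
derives its seed from stable keys rather than scheduling order, and
repeated runs — at any worker count — produce byte-identical model
files and prediction TSVs.

## Known limitations

- The cost-sensitive SGD uses a fixed epoch budget, not a convergence
  test; pathological learning-rate settings can underfit.
- IBM Model 1 ignores word order and fertility by construction; the
  pair-sampling and doc-side truncation defaults trade likelihood for
  speed and can be raised in config.
- Age detection is a window heuristic: ages expressed in words
  ("seventy-year-old") or far from an "age" keyword are missed.
- The dynamic-k calibration assumes the indexed corpus is
  representative of queries; for very heterogeneous corpora the
  percentile thresholds should be set explicitly.
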