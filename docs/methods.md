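# Methods

This note documents the models, parameters and numerical choices behind
`triagecap`, and what the synthetic study conditions do and do not show.

## Document representation

Documents are composed from up to three parts in fixed order
(title → abstract → captions) and masked against a dictionary lexicon
mapping surface terms to the four concept categories `PRGE`, `ENZI`,
`MUTN`, `ANAT`. Masking is case-insensitive, word-boundary anchored and
resolves overlaps by longest match with leftmost-start tie-breaking; it is
idempotent as long as the category tokens themselves are not lexicon keys.
The dictionary design makes the masker deterministic and testable; it does
not model the disagreements or errors of remote annotation services.

Tokenization lowercases alphanumeric runs (hyphens split tokens) while
preserving the four category tokens in canonical uppercase. Features are
presence-valued unigrams and bigrams; bigrams do not cross a sentence
boundary, detected as a period followed by whitespace. All probabilities
are **document frequencies** (a term counts once per document), matching the
binary document vectors used downstream.

Vocabulary filtering drops stopwords (a standard English list shipped as a
package data file, replaceable via `FeatureConfig.stopwords`), single
letters, bigrams containing a stopword token, terms in fewer than
`rare_min_docfreq` documents (default 5) and terms in more than
`frequent_max_docfrac` of all documents (default 0.5). Both cutoffs are
applied corpus-wide, not per class.

## Selection and binning

The selection statistic is the pooled two-proportion Z test,

    z = (p_rel − p_irr) / sqrt( p̂ (1 − p̂) (1/n_rel + 1/n_irr) ),

with p̂ the pooled proportion; z is defined as 0 when p̂ ∈ {0, 1}. The
default cutoff |z| > 1.96 is the two-sided standard-normal critical value at
significance 0.05. Terms with identical presence in both classes are never
selected.

Feature binning partitions the selected terms: two terms share a bin iff
their Pr(t|rel) values fall in the same half-open interval
[i·w, (i+1)·w) **and** their Pr(t|irr) values do too (w = `bin_width`,
default 0.0001). This grid grouping is the fixed point of iteratively
merging any two bins whose members share both sub-intervals, which the test
suite verifies against a literal merge procedure in exact rational
arithmetic. Interval indices are computed from the integer document counts
((df · round(1/w)) // n) whenever 1/w is integral, so probabilities landing
exactly on a boundary go to the upper interval instead of wherever float
rounding drops them. A bin fires in a document when any member term occurs.

## Cluster-based under-sampling

The number of clusters defaults to the rounded imbalance ratio, clamped to
[2, 20], and can be overridden (e.g. with a value tuned by downstream
cross-validation). Clustering runs on the base-training irrelevant
documents, represented by term vectors from the *full* training-set
selection, with spherical K-means: rows and centroids are length-normalized
and the dot product is maximized, equivalent to minimizing cosine distance.
Initialization is a seeded farthest-first sweep; assignment ties go to the
lowest centroid index; convergence is an assignment fixpoint or an
objective change below `tol` (default 1e−6) within `max_iter` (default 100)
iterations. The objective sum(1 − cos) is non-increasing across iterations.
All-zero vectors (documents containing no selected term) are excluded from
fitting and assigned to the largest cluster; clusters that end up empty are
repaired by moving in the largest cluster's farthest-from-centroid member.

## Base and meta classifiers

Each base task pairs the full relevant training set with one irrelevant
cluster — roughly balanced by construction, so no class weighting is used —
and runs its own selection and binning on exactly those two document sets.
The base classifier is a Random Forest of 100 trees grown to purity with
**one randomly drawn candidate feature per split** (`max_features=1`).
The single-feature choice is deliberate: bin features aggregate many terms,
and a small training pair always admits some bins whose perfect training
contrast is a selection artifact (e.g. rare terms concentrated in one class
by chance, pooled into one bin that fires for almost every document at test
time). Greedy split selection concentrates the forest on exactly those
bins; fully randomized splits spread the trees across the whole selected
feature set and transfer far better to out-of-cluster documents. Because
the trees are grown to pure leaves, the forest's probability output equals
the fraction of trees voting relevant.

The meta classifier is a linear-kernel SVM (C = 1.0, no class weighting,
decision threshold 0) over the k base relevance probabilities — raw forest
vote fractions, not recalibrated scores. The meta stage is trained on the
25% of the training data that the base classifiers never saw (stratified
75/25 split), and test documents are scored by the same frozen base models.
The linear kernel keeps the k-dimensional model interpretable: the meta
weights say which clusters' base opinions matter.

A single master seed drives the stratified split, K-means initialization,
every forest and the meta fit (child seeds drawn in fixed order), so a
trained pipeline is bit-reproducible and serializes to identical bytes.

## Evaluation

Precision, recall, f-measure and MCC are computed from confusion counts
with relevant as the positive class; any 0/0 is defined as 0 with a warning.
Cross-validation is stratified k-fold (default 5) and re-runs the entire
pipeline — clustering included — inside every fold; per-document term
extraction is split-independent and therefore computed once. Run
comparison uses the Welch (unequal-variance) two-sample t-test, two-sided;
two identical constant samples are reported as t = 0, p = 1.

## Synthetic study conditions

The generator emulates the structure of a curated triage corpus with
defaults: 500 relevant vs 5000 irrelevant documents (1:10), four irrelevant
sub-topics, ~200 words of title+abstract and ~1000 words of captions per
document (Poisson), a shared Zipf-like background vocabulary of 2000 terms
(exponent 1.1, a typical rank-frequency decay), 50 relevant markers and 50
markers per sub-topic with in-group document frequency 0.30 vs 0.10
elsewhere. Markers are injected by per-document Bernoulli *presence*, not
multinomial token sampling, so the planted document-frequency effect sizes
are exact for the selection statistic; background word budgets are reduced
by the number of injected markers so document lengths stay at their
configured means. `signal_location` confines markers to captions or to
title+abstract, which is what makes the caption-ablation experiment
possible.

What passing tests show: the selection statistic is calibrated (≈5% null
selection) and powerful at the planted effect size; cosine K-means recovers
the planted sub-topics (purity ≈ 0.97); the full pipeline recovers the
planted relevance structure (held-out MCC ≈ 0.84 over five seeds) and
clearly beats a single classifier trained on one random under-sample; and
caption features dominate when the signal lives in captions. What they do
not show: performance on real curated corpora, whose background text has
grammar, collocational structure, topic drift and masking errors that the
generator does not emulate — the bag-of-bigram background here is
combinatorially noisier in rare bigrams than natural text, and natural
relevance signal is far richer than 50 marker terms.

## Known limitations

- The masker cannot reproduce context-dependent annotations; multi-word
  lexicon entries must match surface forms up to whitespace and case.
- Per-base feature selection on small training pairs admits a substantial
  number of spurious low-frequency terms; the randomized-split forests are
  robust to this but the selected-term lists should not be read as clean
  marker sets at small sample sizes.
- The number of clusters is a heuristic of the imbalance ratio; no internal
  model selection (silhouette, gap) is attempted — use the override with
  downstream cross-validation instead.
- Welch rather than pooled t-tests are used throughout; with five folds the
  tests are only indicative.
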