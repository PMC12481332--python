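# Methods

`volspan` extracts volumetric-assessment findings from free-text brain-MRI
reports as *labelled token spans*. Six categories are modelled: global,
regional (lobar) and hippocampal/medial-temporal volume loss, each either
present or absent. Span categorisation — scoring every candidate token
interval independently for every label — is used instead of named-entity
recognition because the findings of interest routinely overlap and nest
("no lobar, regional, or hippocampal volume loss" carries both a
regional-absent and a hippocampal-absent finding over the same tokens),
are longer than typical named entities, and are frequently negated at a
distance from the anatomical term, sometimes from a preceding sentence.

## Data model and tokenisation

A report is its raw text plus a token sequence anchored to character
offsets, with one or more named annotation sets (gold, an annotator, a
model), each a set of `(start_token, end_token, label)` spans in half-open
0-based indexing. Duplicate triples are forbidden within a set; identical
intervals with different labels are legal and meaningful (multilabel).
The interchange format is JSON Lines, one report per line, written with a
stable key order so identical corpora serialise to identical bytes.

Tokenisation is deliberately model-free: whitespace splitting with edge
punctuation (`.,;:()/-`) peeled into single-character tokens. Interior
punctuation (hyphenated words, `T2/FLAIR`-style compounds) is preserved.
This makes offsets reproducible anywhere, at the cost of diverging from any
particular learned tokeniser's segmentation. Word counts (for report-length
statistics) count only tokens containing an alphanumeric character, so
punctuation does not inflate report lengths; statistics computed this way
may differ systematically from counts that include punctuation.

## Synthetic corpus generator

Clinical radiology text cannot be redistributed, so training and evaluation
run on a synthetic stand-in built to match the aggregate shape of a
memory-clinic cohort:

- **Prevalences.** Per report, each base category (global / regional /
  hippocampal) is drawn into one of four states — absent finding, present
  finding, no mention, or conflict — with probabilities arranged so the
  marginal probability of each of the six categories equals its configured
  prevalence exactly. Defaults: global-present 46.2%, global-absent 23.8%,
  regional-present 23.8%, regional-absent 40.1%, hippocampal-present 37.1%,
  hippocampal-absent 24.3%.
- **Internal inconsistency.** The per-base conflict probability `q` solves
  `1 - (1 - q)^3 = r` so that the *report-level* conflict rate matches the
  configured `inconsistency_rate` (default 3.5%) in expectation. Conflicts
  are realised exclusively through `inject_inconsistency`, which appends a
  sentence of the opposite polarity; legitimately lateralised
  present/absent co-occurrence (left atrophic, right normal) is deliberately
  not generated, so the inconsistency detector's gold standard is
  unambiguous.
- **Report length.** Words per report are drawn from a lognormal whose
  median is 61/68 of its mean (default mean 68), clipped to [1, 373],
  reproducing the right skew of real report lengths; reports are padded to
  their target length with non-volumetric distractor sentences. Padding by
  whole sentences overshoots the target by roughly half a sentence on
  average, so the empirical mean sits slightly above the nominal target.
- **Phrase banks.** Sentences are authored templates with single-token
  slots (severity, laterality, region); the gold span is fixed by the
  template and includes severity/laterality modifiers but excludes
  age-qualifying language ("... in keeping with the patient's age"),
  mirroring the annotation rule that only the objective phrase is labelled.
  Span lengths are 1–22 tokens by construction. Dedicated templates produce
  one negated sentence covering two categories with identical or nested
  spans (probability `nested_negation_rate`, default 0.4, whenever both
  regional-absent and hippocampal-absent occur), and negation separated
  from the anatomical term by several tokens or a sentence boundary.

What the generator does **not** emulate: discourse structure and section
headers, longitudinal comparison phrases ("no progressive atrophy"),
spelling variation and typos, rare or idiosyncratic anatomical vocabulary,
and correlations between categories beyond the per-base sampling. Model
scores on this corpus therefore demonstrate that the pipeline can learn and
evaluate span categories end-to-end, not that it would reach the same
scores on clinical text, whose phrasing is far more heterogeneous.

## Evaluation

**Matching.** Exact match requires identical `(start, end, label)`;
relaxed match requires the label plus at least one overlapping token.
Matching is one-to-one per category: candidate pairs are ordered by overlap
length (descending), then gold start/end and predicted start/end, taken
greedily, and the greedy assignment is then improved by deterministic
augmenting paths. The augmentation step matters: pure greedy matching is
not maximal on nested same-label configurations (gold `{[0,4), [2,4)}`
versus predictions `{[0,4), [0,2)}` greedily yields one match where two
exist), whereas the augmented matcher always attains the maximum one-to-one
cardinality, verified against brute-force enumeration in the test suite.

**Scores.** Precision, recall and F1 are computed from counts pooled over
reports (micro). The pooled six-category score is a micro-average; a
macro-average (mean of per-category scores) is also reported, since with
balanced per-category support the two agree to rounding and the choice is
a convention. Zero-denominator convention: a category absent from both gold
and prediction scores 1.0 (vacuous success); a zero denominator with errors
on the other side scores 0.0. This keeps pooled averages defined on small
resamples. 95% confidence intervals are percentile bootstrap over reports
(default 1000 resamples, seeded); coverage is checked empirically in the
test suite on a benchmark with known ground truth. Inter-annotator
agreement is the pooled F1 of one annotator scored against the other;
because F1 is symmetric in precision and recall, the direction of the
comparison does not matter.

**Distinctiveness.** Span distinctiveness of a category is the
Kullback–Leibler divergence `Σ P(t) ln(P(t)/Q(t))` between the unigram
distribution `P` of (lower-cased) tokens inside the category's gold spans
and the whole-corpus unigram distribution `Q`. Boundary distinctiveness
uses only each span's first and last token (a length-1 span counts once).
Natural logarithm, so values are in nats. No smoothing is needed: span
tokens are corpus tokens, so `Q > 0` wherever `P > 0`. The convention that
boundary tokens lie *inside* the span (not adjacent outside it) is one of
two defensible readings and is the one implemented.

## Model

The trainable component follows the spancat contract: a **suggester**
enumerates every contiguous interval of 1–25 tokens (25 exceeds the longest
annotated span of 22, so every gold span is a candidate and perfect recall
is attainable), and a **labeller** scores each candidate independently per
category, emitting all candidates whose probability reaches that category's
threshold (default 0.5). Overlapping and nested predictions arise naturally.

The labeller is one L2-regularised logistic regression per category
(scikit-learn, lbfgs) over sparse binary lexical features of the candidate:
the bag of lower-cased span tokens, the first and last span token, three
tokens of context on each side, and a span-length bucket. Candidates that
exactly equal a gold span are positives for that label; every other
candidate is a negative — no partial-overlap soft labels and no negative
subsampling. This objective is a deliberate re-design at desk scale, not a
replication of any transformer pipeline; the contract (suggester +
multilabel labeller, thresholded probabilities) is what is preserved.

Numerical choices that matter:

- **Optimiser tolerance.** Exhaustive suggestion yields on the order of
  1500 candidates per 70-word report, of which a handful are positive. At
  the solver's default stopping tolerance the fit terminates before the
  rare positive class is fitted at all (probabilities plateau near the
  class prior). The default here is `tol=1e-8` with `max_iter=5000`, which
  fits the separable synthetic data essentially exactly.
- **Class weighting** defaults to none, keeping predicted probabilities
  calibrated to the true candidate imbalance so the 0.5 threshold is
  meaningful. Balanced weighting is available but trades precision for
  recall at a fixed threshold.
- **Determinism.** All randomness (splits, folds, bootstrap) flows from
  explicit integer seeds; lbfgs itself is deterministic, so fitting twice
  with the same seed yields identical weights and predictions.

Fitted models serialise to one versioned JSON file (vocabulary, weights,
thresholds, config); reloading reproduces predictions exactly.

`split_corpus` uses round-half-away-from-zero for the development size, so
the 4007-report cohort at 0.8 splits 3206/801. K-fold cross-validation
(default k=5) partitions reports into folds differing in size by at most
one, trains on k−1 folds and reports per-fold and aggregate mean±sd scores.

## Report-level aggregation

A report is labelled with a category iff it contains at least one span of
it; cohort prevalence is the fraction of reports so labelled per category
(categories are not mutually exclusive). A report is internally
inconsistent for a base category when it carries both the present and the
absent label — counted purely at the label level, with no linguistic
adjudication, accepting that some such co-occurrences in real text are
clinically legitimate lateralised findings. Gold annotations are used for
the inconsistency count unless another source is requested.

## Problem sizes used in validation

The bundled checks run the generator at the full cohort size (4007 reports)
for prevalence and inconsistency fidelity, train/evaluate the model on a
1000-report corpus with an 80/20 split, verify the matcher against
brute-force enumeration on over a thousand random instances of up to 8
spans per side, and check bootstrap-CI coverage over 400 trials of an
80-report benchmark. These sizes give stable estimates for a template-based
corpus; scores quoted anywhere in the documentation are outputs of these
runs, not claims about clinical data.

## Known limitations

- The synthetic corpus is far more regular than clinical prose; reported
  model scores are upper bounds on realistic difficulty.
- The rule-based tokeniser will not match a learned tokeniser's
  segmentation on unusual orthography.
- Longitudinal/comparative language is out of scope by design.
- The inconsistency detector intentionally has no access to laterality, so
  on real text it would flag legitimate left/right contrasts as conflicts.
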