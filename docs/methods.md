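# Methods

This note records the mathematical conventions, default parameters and design
decisions behind `raslit`, and the design and limits of the synthetic
benchmark generator.

## Problem setting

Genes are described by how the literature talks about them: each gene's
feature vector is one row of a gene × document TF-IDF matrix built from its
synonym mentions. The learning task is multi-label classification — a gene
may belong to several of the ten disease-related pathways at once — and the
biology-facing outputs are per-pathway gene rankings, the collapse of the ten
pathways into three disease branches, and the set of genes that score highly
in several pathways simultaneously.

## Text features

* **Tokenization** lowercases, splits on `[a-z0-9]+`, and removes a fixed
  English stopword list (`raslit._stopwords`). The list is frozen in the
  package so results cannot drift with library versions.
* **Term frequency**: `tf(t, d) = f_td / (total tokens in d)`. For multi-word
  synonyms, occurrences are counted by a greedy non-overlapping sliding
  window over the token sequence, but the denominator stays the single-token
  count of the document.
* **Inverse document frequency**: `idf(t) = log(N / n_t)` with natural log by
  default (base 2 and 10 are options). A term appearing in no document gets
  `idf = 0`, so absent synonyms contribute nothing rather than infinity; a
  term in every document also scores 0 by construction.
* **Synonym aggregation**: a gene's cell value for a document is the **sum**
  of its (deduplicated) synonyms' TF-IDF scores by default; `max` and `mean`
  are available. Sum is the default because distinct synonyms are distinct
  pieces of evidence; `mean` would let adding a rare synonym *lower* a gene's
  score.

`TfidfGeneFeaturizer` computes this with an inverted token index so only
documents that can contain a synonym are scanned; tests verify exact
(≤ 1e-12) agreement with a nested-loop brute-force implementation.

## Dimension reduction

`StandardizedPCA` implements classical PCA on standardized features:

1. standardize each column with the sample standard deviation (`ddof = 1`);
   constant columns are mapped to 0 (divisor replaced by 1) and flagged;
2. eigendecompose `Σ = ZᵀZ/(n−1)`; components are the top-k eigenvectors and
   scores are `T = Z V_k`.

Numerically the decomposition is computed through a thin SVD of `Z`
(`λ_i = s_i²/(n−1)`), which is faster and better conditioned than forming the
d × d covariance when genes ≪ features; a dense `eigh` oracle in the tests
confirms agreement to 1e-8. Deterministic sign convention: the
largest-magnitude loading of every component is made positive. Requesting
more components than the matrix rank clips with a warning. Either a fixed
`n_components` or a `variance_target` (default 0.95) may be given, never
both. The sum of all eigenvalues equals the number of non-constant features,
which the tests check.

## Models

**`MultiLabelMLP`** (the package's own contribution, pure NumPy): one shared
hidden stack (default one layer of 128 ReLU units) and an independent sigmoid
output per pathway. The loss is class-weighted binary cross-entropy summed
over labels with L2 regularization; the positive term of label *j* is scaled
by `w_j = (#negatives_j) / (#positives_j)` so rare pathways are not drowned
out (labels with no positives get `w_j = 1` with a warning). Training is
full-batch Adam (default learning rate 3e-3, ≤ 1000 epochs) with early
stopping on an internal 10% validation split (patience 50, tolerance 1e-5);
the best-validation weights are restored. All randomness flows from one
`random_state`, making training bit-deterministic. A non-finite loss raises
`FloatingPointError` rather than silently degrading.

**`MultiLabelOvR`** wraps per-label one-vs-rest baselines: RBF-kernel SVM
(probabilities via the logistic of the decision function, avoiding Platt
scaling's extra CV nondeterminism), random forest (100 trees), and XGBoost
(depth 4, learning rate 0.1, `scale_pos_weight` when class weighting is on).
A label with only one class in the training data falls back to a constant
predictor. By family default the MLP trains class-weighted and the baselines
unweighted; `ModelConfig(class_weighting=...)` overrides either way.

## Metrics

With per-pathway confusion counts over genes:

* macro precision/recall/F1 are unweighted means over pathways, and a
  pathway with a zero denominator contributes **0** to the mean (it is not
  skipped). This makes scores on degenerate splits conservative.
* **ranking loss** is the mean of `ln(1 + exp(−(s_pos − s_neg)))` over all
  (true-label, false-label) score pairs within each gene, pooled across
  genes. A tied pair costs `ln 2`; the loss is smooth and never exactly zero.
  Computed with `logaddexp` for overflow safety.
* **macro ROC-AUC** uses the Mann–Whitney rank form with half credit for
  ties; pathways lacking positives or negatives are skipped (and counted),
  and if every pathway is degenerate the AUC is an error, not a default.

All three have plain-loop oracle implementations in the test suite; the
vectorized versions agree to ≤ 1e-10 on thousands of random instances.

## Evaluation protocol

`evaluate_protocol` draws one seeded permutation of the genes, holds out 10%
as a test set, splits the remaining 90% into 10 cross-validation folds
(`np.array_split`, so fold sizes differ by at most one), reports the
unweighted mean of the per-fold metrics, then retrains on the full 90% and
scores the held-out 10%. Fold memberships and split sizes are recorded in the
returned reports, and the whole procedure is bit-reproducible under a fixed
seed. `evaluate_holdout` reuses the identical split to produce just the
held-out report (one fit instead of eleven) for model comparisons.

## Biology-facing outputs

* **Branch reduction**: binary labels collapse by OR over a branch's member
  pathways, probability scores by MAX — a gene belongs to / hits a branch if
  any member pathway does. The default map sends RAS, RS, AS, ARSR, ESP and
  VRWR to *hypertension*; HCM and DCM to *cardiac*; DiCM and AGE-RAGE to
  *diabetes*. An unmapped pathway is a hard error.
* **Gene ranking**: per pathway, genes sort by predicted probability
  descending with lexicographic tie-breaks, so the ranking is a deterministic
  permutation.
* **Shared-high-score filter**: genes with probability ≥ 0.9 in at least 3
  pathways, thresholds configurable; inclusive boundary.

## Synthetic benchmark generator

`generate_dataset` plants a known structure:

* every gene gets one uniform primary pathway plus Poisson-many extras
  targeting a label cardinality of 1.8 — except the first `n_pathways` genes,
  which are single-label *marker* genes, one per pathway. Each marker doubles
  as its pathway's **hallmark** gene. Keeping hallmarks single-label is
  deliberate: a multi-label hallmark would be mentioned under several topics,
  eroding the IDF of its synonyms and making rank recovery ambiguous.
* every document draws one topic pathway uniformly and a Zipf-distributed
  filler stream (Poisson length, default mean 120 tokens over a 2,000-word
  vocabulary). Gene mentions are Poisson: rate `background_rate` (0.08)
  off-topic, × `signal_strength` (5) for the topic pathway's member genes,
  and additionally × `top_gene_boost` (3) for the hallmark. Mentions insert
  one randomly chosen synonym at a random position.
* `signal_strength = 1` is an exact null: topic membership has no effect on
  the text, so any pipeline should score at chance. Tests confirm the
  realized per-document mention rates match these Poisson rates and that
  null-corpus CV ROC-AUC stays near 0.5.
* a configuration whose expected in-topic mention count per gene falls below
  0.5 corpus-wide warns that the signal may be unrecoverable.

Everything derives from one seed; the serialized dataset files are
byte-identical across runs.

**What the generator does and does not emulate.** It reproduces the
*structure* of a literature-mining dataset — multi-label pathway membership,
synonym variation, topic-dependent mention frequency, shared genes across
pathways — at desk scale (200 genes × 2,000 documents versus a real corpus
orders of magnitude larger). It does not model real linguistic phenomena:
polysemous gene symbols, negation, section structure, citation bursts, or
correlated topics within one article. Absolute metric values on the benchmark
therefore do not transfer to real corpora; the benchmark validates the
pipeline's mechanics (signal in → labels out, null in → chance out), not its
field performance.

## Default parameters

| parameter | default | rationale |
|---|---|---|
| TF-IDF log base | e | natural log; base only rescales columns jointly |
| synonym aggregation | sum | each synonym is extra evidence |
| PCA `variance_target` | 0.95 | library default when no k is given |
| benchmark PCA k | `n_pathways` | the generated corpus has exactly one latent topic per pathway, so the informative subspace has that dimension; trailing components are sampling noise |
| MLP hidden layers | (128,) | small corpus, one nonlinear mixing layer suffices |
| MLP learning rate / epochs / patience | 3e-3 / 1000 / 50 | full-batch Adam on ≤ a few hundred genes; early stopping prevents overfit while the budget lets slow labels converge |
| decision threshold | 0.5 | sigmoid midpoint; configurable in `ProtocolConfig` |
| shared-gene filter | ≥ 0.9 in ≥ 3 pathways | the package's cross-pathway gene readout |
| split / folds | 90/10, 10-fold | the evaluation protocol implemented here |

## Open design choices and limitations

* The MLP validation split for early stopping is carved from the training
  data of each fold; with very few genes this can leave noisy validation
  estimates. Setting `validation_fraction=0` disables early stopping.
* CV headline numbers are unweighted means over folds; fold sizes differ by
  at most one gene, so this is nearly identical to pooling but not exactly.
* The SVM baseline's probabilities are a logistic squash of the margin, not
  calibrated probabilities; its AUCs are meaningful, its thresholded metrics
  less so.
* The zero-denominator convention (count as 0 in the macro mean) depresses
  scores on tiny test sets where a pathway may lack positives; this is
  intentional conservatism, but it means small-n macro-F1 values are not
  comparable with implementations that skip such classes.
* Ranking loss on well-separated data converges to ~`ln(1+e^{-1}) ≈ 0.31`
  when scores saturate at 0/1 with unit margins — it is a relative, not an
  absolute, quality measure.
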