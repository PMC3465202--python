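# Methods

## Model and procedure

genebeam treats gene selection as a wrapper problem: a candidate subset
*T* is scored by the cross-validated accuracy Acc(*T*) of a classifier
restricted to its columns, and the goal is the collection A\* of
minimum-size subsets with the highest (or nearly highest) Acc.  The
pipeline has four stages.

**Pre-filter.**  Each gene is scored by the Kruskal-Wallis rank sum test
(tie-corrected H statistic, chi-square p-value with k−1 degrees of
freedom); the *p* genes with the smallest p-values become the search
candidates.  The chi-square approximation rather than exact small-sample
tables is used because only the ranking matters downstream; the test
suite checks it against an exhaustive permutation distribution at n = 8.
For two classes the statistic is the square of the Wilcoxon rank-sum
z-score, so the p-value matches the two-sided normal-approximation
Wilcoxon test.  A gene constant across all samples gets p = 1.  Ties in
p are broken by original column index.

**Beam search.**  Layer 1 holds all *p* singletons (the beam width is
ignored there).  Each expansion scores the classification matrix
CM = (aᵢⱼ) with aᵢⱼ = Acc(Row[i] ∪ Column[j]); the first expansion is
symmetric, so only the lower triangle is evaluated and mirrored.  Cells
whose column gene is already in the row subset, and unions already
evaluated on another path (closed nodes), carry a *negative* sentinel —
negative rather than zero so it can never collide with a genuinely
zero-accuracy open subset.  Open cells are ranked by accuracy
descending, then by the sum of the members' KWRST ranks ascending
(favoring stronger marginal genes), then by the canonical gene tuple;
the top *w* become the next beam.  Stopping: best accuracy ≥ acc_max,
layer = depth, or (optionally) a layer-to-layer gain below δ; δ is off
by default.  Per-layer beam widths and accuracy thresholds can be
scheduled, but fixed values are the default.  The final beam is A\*; an
optional tolerance τ keeps only subsets within τ of the best final
accuracy (default: keep all).

One CV partition is fixed per run and reused for every cell, which makes
the per-layer accuracy trace comparable across layers and the whole run
deterministic given its seed.  The layer maximum is *not* guaranteed to
be non-decreasing — extending every beam subset can lower CV accuracy —
so a decrease is logged rather than treated as an error.  Evaluation
cost is bounded by depth × w × p calls to Acc, and the closed-node
registry guarantees no subset is ever scored twice.

**Ensemble.**  Each subset in A\* trains one classifier on the full
training set (no bagging or resampling; the diversity comes from the
subsets themselves).  A test sample's label is the simple majority of
the N votes, with ties going to the first class in the training label
order; its reliability is conf = m_max/m_sec, set to N when the vote is
unanimous, so conf ∈ [1, N].  For cross-platform test sets, only
subsets whose every gene exists on the test platform may vote.  For the
SVM ensemble, hyperparameter selection has an *unbiased* mode (each
classifier's (C, γ) maximizes training CV accuracy, ties broken by grid
order: γ ascending, then C ascending) and a *biased* mode that resolves
those same training-CV ties by test-set accuracy.  The biased mode
exists to quantify selection bias — its accuracy can only be ≥ the
unbiased mode's on any draw — and is refused for KNN, which has no
hyperparameter grid to overfit.

**Ranking.**  A gene's score is its occurrence count over all subsets of
all supplied runs (the KNN-wrapped search is partition-sensitive and is
conventionally run five times; counts accumulate per run).  Ties are
broken by KWRST p-value ascending, then gene id.  The power-law
diagnostic is an ordinary least-squares line through
(log rank, log frequency), rank = 1..#genes in table order; no
maximum-likelihood exponent estimation is attempted, since the fit is a
visual diagnostic, not an inference.  Accuracy-vs-top-k curves train the
configured classifier on the top-k ranked genes and score the test set;
genes missing from the test platform are skipped with the next-ranked
gene substituted, and every substitution is logged.

## Evaluation statistics

Acc(T) is stratified k-fold CV accuracy (10 folds by default), seeded.
Stratification requires at least one member of each class per fold; for
fold counts beyond the smallest class — the high-k end of Full-fold CV,
up to leave-one-out — a plain shuffled partition is used.  Full-fold CV
summarizes CV(k) for every k = 2..m as mean = Σ CV(k)/(m−1) and
std = √(Σ (CV(k) − mean)²/(m−2)); it is applied to the resulting
subsets only, never inside the search, where it would multiply the cost
by m.  The subset-size guideline returns floor(m_t/(5k)) for m_t
training samples and k classes — the largest size honoring five samples
per class per feature — warning when the value sits exactly on the
strict-inequality boundary.  Confusion-matrix rates with a zero
denominator are reported as None, never 0.  AUC uses the midrank tie
convention (ties count one half).

## Normalization

Per-gene z-scoring (denominator m−1; constant columns → 0) and 0–1
min-max scaling (constant columns → 0.5) are provided.  Train and test
platforms are normalized independently by default, which is the
conventional cross-platform protocol; `zscore_normalize` accepts a
reference dataset for the leakage-free alternative of applying
training-set statistics to the test set.  Inside CV the default is to
assume the caller normalized the training set once before the search; a
leakage-safe per-fold mode (`normalize_per_fold`) re-z-scores the
restricted column block on fold-training statistics and is off by
default.  Cross-platform alignment restricts both datasets to their
shared gene ids in lexicographic order.

## Synthetic data

The generator draws a class-conditional Gaussian model: noise genes are
Normal(0, σ) identically across classes; each planted informative gene
receives class means at Δ·(0, 1, …, k−1), permuted per gene so
multi-class problems are separable without symmetry artifacts.  Optional
consecutive blocks share a latent factor giving pairwise correlation ρ
(x = σ(√ρ·z + √(1−ρ)·ε)), mimicking co-regulated genes.  A
cross-platform companion draws new samples from the same model,
restricted to a random fraction of gene ids, affinely distorted
(x·scale + shift), and padded with platform-only noise genes.

Defaults — two classes of 30 samples, 200 genes, 4 informative at
Δ = 3σ — describe a clearly differentially expressed marker panel in a
small cohort, the regime the method targets.  Real microarray data are
heavier-tailed and batch-structured than this Gaussian model, so passing
tests demonstrate correctness of the machinery and recoverability of
planted signal, not performance on any particular real dataset.

## Numerical and design choices

* Accuracies are fractions in [0, 1] internally; reports and the CLI
  render percentages, and confidence levels print to 4 decimals.
* Exact-equality subset filters ("10-fold = 100%") compare with a 1e-9
  tolerance to absorb float CV arithmetic.
* KNN is implemented directly (distances via scipy) because the
  multi-class tie rule — the class of the nearest neighbor among the
  tied classes — is not expressible in scikit-learn's KNN; binary
  problems with odd k never tie.  Neighbor-distance ties are resolved by
  training-sample order.
* The SVM grid defaults to C ∈ {200, 400} and γ ∈
  {a·10ᵉ : a = 1..9, e = −5..−1} ∪ {1..10}; the reported Acc is the
  grid maximum, so enlarging the grid can only raise it.
* The search's depth parameter is the maximum subset size explored
  (depth 1 returns the accuracy-ranked singletons).
* Enrichment exposes both hypergeometric tails — lower P(X ≤ x) and
  upper P(X ≥ x) — with the upper tail as the enrichment default, plus
  the Binomial(K, M/N) upper-tail approximation for large universes;
  scipy computes both in log space.
* Test problem sizes (p ≤ 50, w ≤ 50, ≤ 60 samples, reduced SVM grids
  in the ensemble comparisons) were chosen so every property is
  exercised at desk scale; the properties themselves — beam-vs-
  exhaustive equivalence, bias ordering, planted-gene recovery — do not
  depend on these sizes.

## Known limitations

* The wrapper objective overfits by construction: subsets with 100%
  training CV accuracy routinely generalize poorly, which is precisely
  why the ensemble and the frequency ranking, not individual subsets,
  are the recommended outputs.
* The beam is lossless only when w is at least the number of reachable
  subsets per layer; real runs with w ≪ C(p, t) are heuristic.
* No batch-effect correction, probe-to-gene mapping, or pathway-database
  retrieval; enrichment expects the caller's own (N, M, K, x) counts and
  applies no multiple-testing correction.
* The generator does not imitate platform-specific probe-level
  artifacts.  A standardized log-normal noise option
  (``noise="lognormal"``) provides heavy right tails for robustness
  checks, but the defaults stay Gaussian so planted effect sizes remain
  exactly interpretable in within-class SD units.
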