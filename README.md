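# genebeam

Minimum gene-subset selection for tumor classification from gene
expression profiles (GEP), with an ensemble classifier and an
occurrence-frequency gene ranking built on top of the selected subsets.

## The problem and who this is for

A bulk or single-cell expression study yields a matrix *X* = (*x*ᵢⱼ) of
*m* samples by *n* genes with class labels *L* = {*c*₁, …, *c*ₖ} (tumor
vs. normal, or tumor subtypes), where *n* ≫ *m*.  For diagnosis and
biomarker discovery one wants the *smallest* gene subsets *T* ⊂ *G* that
still classify accurately:

  minimize |*T*|   while maximizing Acc(*T*),

where Acc(*T*) is the cross-validated accuracy of a classifier trained on
the columns of *T*.  Because exhaustive search over 2ⁿ subsets is
hopeless and greedy forward selection finds only one subset, genebeam
uses a heuristic breadth-first **beam search**: genes are pre-ranked by
the Kruskal-Wallis rank sum test (KWRST), the top *p* enter the search,
and each layer grows every surviving subset by one gene, scoring the
classification matrix CM with cells aᵢⱼ = Acc(Row[i] ∪ Column[j]) and
keeping only the *w* best subsets ("open nodes"); duplicated subsets are
closed and never re-scored.  The search stops at a target accuracy, a
depth bound, or an accuracy plateau, and returns the final beam as the
optimal subsets **A\***.

Two constructions sit on top of A\*:

* an **ensemble classifier** — one classifier per subset, simple majority
  vote, with a per-sample confidence level
  conf = m_max / m_sec (ratio of the two largest vote counts; conf = N
  for a unanimous vote of N classifiers);
* a **gene ranking** — a gene's importance is its occurrence frequency
  across all subsets of all runs; empirically the frequencies decay
  roughly as a power of the rank, so a handful of top genes carries most
  of the signal.

Wrapped classifiers: 5-nearest-neighbors (Euclidean) and an RBF-kernel
SVM grid-searched over C ∈ {200, 400} and γ ∈ [10⁻⁵, 10].  Evaluation
utilities include stratified k-fold CV, the Full-fold CV statistic
(mean and SD of CV(k) over every fold count k = 2..m), confusion-matrix
rates, ROC/AUC, the five-samples-per-feature subset-size guideline
(m_t/k)/n_s > 5, and hypergeometric/binomial pathway-enrichment
p-values.  A seeded synthetic-data generator with planted informative
genes makes the whole pipeline testable without any external download.

## Worked example

Simulate a two-class cohort (30 samples per class, 200 genes, 4 planted
informative genes shifted by 3 within-class SDs), pre-filter, run the
KNN-wrapped search five times with different CV partitions, and rank
genes by occurrence frequency:

```sh
genebeam simulate --classes 2 --per-class 30 --genes 200 \
    --informative 4 --effect 3.0 --seed 7 --out demo
genebeam prefilter --expression demo_expression.tsv \
    --labels demo_labels.tsv --top 50 --out pvalues.tsv
genebeam search --expression demo_expression.tsv --labels demo_labels.tsv \
    --classifier knn --top 50 --width 50 --depth 4 \
    --seeds 0,1,2,3,4 --out subsets.jsonl
genebeam rank --subsets subsets.jsonl --expression demo_expression.tsv \
    --labels demo_labels.tsv --out frequency.tsv
```

which prints

```
wrote 60 samples x 200 genes (4 informative) to demo_*.tsv
wrote 50 genes to pvalues.tsv
wrote 250 subsets from 5 run(s) to subsets.jsonl
power-law fit: slope -1.573, r^2 0.908
wrote 34 ranked genes to frequency.tsv
```

and the head of `frequency.tsv` reads

```
rank  gene_id  count  kwrst_p
1     g0124    173    3.17522e-11
2     g0187    136    5.22832e-11
3     g0137    108    8.56299e-11
4     g0180    86     1.61897e-09
5     g0168    25     0.00623578
```

The four top-ranked genes are exactly the four planted informative genes
(`demo_truth.tsv`), each appearing in far more optimal subsets than any
noise gene, and the log-log slope of −1.57 with r² = 0.91 shows the
frequency-vs-rank decay that motivates using only the few top-ranked
genes as markers.  The same pipeline runs from a single YAML config via
`genebeam run config.yaml`, and `genebeam ensemble` scores an
independent test set with per-sample vote counts and confidence levels.

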