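# Methods

## Model and assumptions

The estimator treats chronological age as a discrete latent label ranging
over the training cohort's age thresholds (midpoints between adjacent
distinct ages) and every gene as a noisy binary sensor of "older than δ".
This is a deliberate trade: a dichotomized gene loses the magnitude of its
expression change but gains sensitivity to abrupt, age-localized shifts
that a linear age–expression model averages away. The naïve Bayes
combination assumes classifier responses are conditionally independent
given the age bracket — certainly false for co-regulated genes — but the
posterior argmax is robust to moderate violations, which is the usual
justification for naïve Bayes in high-dimensional expression work.

Further assumptions worth stating explicitly:

* **Complete matrices.** Missing expression values are a hard error, never
  imputed: every downstream statistic is a function of exact 2×2 counts,
  and silent imputation would quietly change them.
* **Tied ages** collapse to a single grid point, so co-aged subjects fall
  on the same side of every threshold. The threshold grid needs at least
  three distinct ages.
* **Predicted ages are thresholds.** The posterior ranges over the
  training δ grid; no interpolation is done, so the resolution of a
  prediction is one age gap in the training cohort.

## Screening conventions

* Contingency counting uses `≤` on the low side for both dichotomies:
  `g ≤ θ` is "low", `age ≤ δ` is "young".
* The two-sided Fisher p is the sum of hypergeometric probabilities of all
  tables with the observed margins whose probability is at most the
  observed table's, with relative tolerance 1e-7 on the comparison (the
  convention used by standard exact-test implementations). A zero margin
  returns p = 1: no association is testable. The vectorized screen
  precomputes, per threshold, a (row-margin × C00) lookup table of these
  p-values, which is what makes in-fold re-screening cheap.
* θ candidates are the gene's observed expression values themselves. The
  best candidate minimizes p; ties prefer the larger |log2 OR|, then the
  smaller θ. Two candidates whose p differs only in the final float bit
  are an exact tie for any practical purpose; the scalar and vectorized
  paths may then differ in which they report, with identical p and |OR|.
* The log2 odds ratio applies the Haldane–Anscombe +0.5 (all four cells)
  only when some cell is zero, and only for the odds ratio — p-values
  always use the raw counts. Perfect separations (the best screeners) thus
  stay finite and rankable for the greedy step. A constant gene scores
  p = 1, log2 OR = 0, direction flat.
* Positive log2 OR means high expression co-occurs with older subjects
  ("up with age"); the sign at a gene's transition point is its direction
  of regulation.

## Greedy assignment and the fitted model

The greedy pass iterates thresholds from youngest to oldest, each column
taking the unused gene with the largest |log2 OR| (ties: smaller p, then
lexicographic gene id), and retires a chosen gene from *all* columns, so
each gene backs at most one threshold. After `N` rounds every threshold
holds `N` genes, unless genes run out, in which case later rounds assign
fewer and a warning is issued. Because younger columns pick first, a gene
can be consumed by a threshold other than its own best one when the gene
pool is small relative to `N × #thresholds`; with thousands of genes this
is immaterial, but tiny fixtures should supply at least one strong gene
per threshold.

Conditional probabilities use add-one (Laplace) smoothing so that
perfect-separation tables contribute large but finite log-likelihood
ratios. A candidate age exactly equal to a classifier's own δ uses the
"younger" branch (the `δ_k > δ_i` comparison is strict), which makes the
posterior deterministic on the grid. All posterior arithmetic is in log
space with log-sum-exp normalization; posteriors sum to 1 within 1e-9, and
argmax ties resolve to the smallest threshold.

`N` (genes per threshold, default 20) is the one tuning parameter that
matters. More genes add weakly informative classifiers whose noise
accumulates; fewer genes waste signal. `select_N` picks from a grid by
cross-validated error on the given data only, preferring the smaller `N`
on ties.

## Evaluation protocol

Cross-validation uses a seeded random partition into k folds (default 5).
The error is the macro average: mean over folds of the fold's mean
absolute error in years; the SD across subjects and across folds are both
reported, since summaries of the form "error ± spread" are ambiguous
between the two. **Feature selection happens inside each training fold**
— thresholds, screen, greedy assignment and conditionals are all refit on
the training subjects only. The permissive variant (`leaky_selection`)
keeps the full-data screen and greedy choice and refits only the
conditional probabilities per fold; it exists to quantify the optimism of
out-of-fold selection, not as a default.

Permutation significance shuffles ages across subjects and reruns the
entire cross-validation per replicate. The p-value is the proportion of
permuted errors *strictly* lower than the observed error, with no
pseudocount — so p = 0 is reportable as "< 1/n_perm".

Baselines: the age-spread baseline (mean |age − median age|, the constant
predictor's error); per-gene OLS of expression on age with gender
adjustment (`Y = β0 + β1·age + β2·male + β3·age·male`, sex terms dropped
with a flag when only one sex is present); lasso regression of age on all
genes via the LARS path with the penalty tuned by nested k-fold CV on the
training fold; and greedy forward-stepwise selection capped at half the
training subjects, its step count tuned the same way. A piecewise
polynomial spline baseline is left as an extension point and not
implemented.

## Transition-age analysis

A gene's transition age point is its minimum-p threshold (ties: larger
|log2 OR|, then the smaller δ) — "most significant" rather than "largest
odds ratio", so that the significant-gene counts are defined by the same
p cutoff that filters them. Significance keeps `p < α` (default 0.005)
and reports Benjamini–Hochberg q-values computed over *all* genes'
transition p-values, summarized as the maximum q among retained genes.
Decades are half-open, `[40, 50) → "40s"`; age groups are young (< 40),
middle `[40, 60)`, old `[60, 80)` and very old (≥ 80), all with inclusive
lower bounds. Set overlaps between datasets use the one-sided
hypergeometric enrichment tail over a user-supplied universe (defaulting,
at the CLI, to the genes present in all compared sets).

**Known inflation of per-gene calls.** Selecting the minimum p over ~n
thresholds with an exhaustive θ search is a maximally-selected statistic:
on pure-noise genes the per-gene call rate at p < 0.005 is roughly 16% for
a 29-subject cohort and 37% for a 60-subject cohort (measured on the
synthetic null; the per-(gene, threshold) cell rate is ≈ 3.5%). The
per-gene significant list is therefore a screening ranking, not an
FDR-controlled discovery set — the reported BH q-values inherit the same
optimism because they are computed from the selected minima. The
estimator's predictive claims do not rely on these calls: accuracy is
measured out-of-fold and calibrated by the permutation test, which
reshuffles ages through the entire selection pipeline.

## Network topology

Statistics are defined on an undirected simple graph restricted to its
largest connected component (component ties broken toward the
lexicographically smallest member node). Degree, betweenness (normalized
by `(N−1)(N−2)/2`, endpoints excluded), closeness (`(N−1)/Σd`, the
reciprocal form, so compact graphs score near 1) and the local clustering
coefficient come from networkx; characteristic path lengths are the mean
shortest-path distance over unordered pairs within a set, or over cross
pairs between two sets with same-node pairs excluded. Genes absent from
the component are dropped with a logged count. Permutation z-scores draw
random node sets of the same size uniformly from the network (optionally
from a restricted background pool); a zero permutation SD yields z = NaN
with a warning. Path-length statistics are much costlier per replicate
than mean centralities, so the CLI caps their default replicate count at
100 where centralities use 1000.

## Synthetic data

The generator emulates a cross-sectional cortical aging cohort: by default
29 subjects with continuous ages uniform on 25–95 years (a `round_years`
flag introduces ties), ~60% male, log2 expression with per-gene baselines
`Normal(6, 1.5)` and per-sample noise sd 0.5 — values chosen once to look
like GCRMA-scale microarray summaries of a small postmortem brain cohort.
Informative genes are steps (`effect · 1[age > τ]`, direction up, down or
random per gene) or linear trends (slope per year); null genes are noise
only. The step/trend/null mixture gives both the dichotomized estimator
and the linear baselines a regime where each is favored. The network
generator grows a preferential-attachment graph (each new node attaches to
`m` existing nodes proportionally to degree) and plants the `m` earliest —
hub-tending — nodes, padded with random nodes, as a central gene set.

What the fixtures do *not* model: probe-level noise structure, batch
effects, correlated co-expression modules, non-uniform age sampling, and
any real biological pathway structure in the network. Passing tests on
these fixtures demonstrate algorithmic correctness and the stated
statistical properties, not performance on real cohorts.

## Problem sizes and numerical choices

The test suite and the acceptance script run at deliberately modest
scale, chosen to exercise every code path at stable statistics: planted
cohorts of 60 subjects × 2000 genes (10 seeds), null calibration on 50
cohorts of 20 subjects × 60 genes with 100-shuffle permutation tests, and
networks of a few hundred nodes with 200 permutation replicates.
Tolerances: exact-test agreement with enumeration to 1e-9; posterior
normalization and log-space/direct-product agreement to 1e-9; centrality
agreement with brute-force oracles to 1e-9. Degenerate inputs are defined,
not special-cased ad hoc: zero-margin tables give p = 1, constant genes
are flat, empty greedy assignments and empty universes raise, and
disconnected graphs direct the caller to the largest component.
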