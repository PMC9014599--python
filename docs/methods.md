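# Methods

## Problem and model

Competing endogenous RNAs (ceRNAs — mRNAs, lncRNAs and pseudogenes sharing
miRNA response elements) compete for miRNA binding, so the miRNA–ceRNA
correlation structure of a tissue is a functional readout of its regulatory
state. `cernapert` asks how far a single tumor sample displaces that
structure relative to a normal reference cohort, and uses the displacement to
predict lymph-node metastasis and stratify survival.

The procedure:

1. **Gene filtering and normalization.** Genes with mean raw count < 1
   across all samples are removed as unexpressed. Counts are normalized by
   the trimmed mean of M-values (TMM): per sample, gene-wise log2 expression
   ratios (M) against a reference sample (the one whose 75th-percentile
   count/library-size ratio is closest to the cohort mean) are doubly
   trimmed — 30% from each tail of M and 5% from each tail of the average
   log abundance A — and combined with asymptotic binomial precision
   weights; factors are centred to geometric mean 1. Correlation work uses
   log2 CPM on the TMM-effective library sizes with a 0.5 prior count.
   miRNA and ceRNA matrices are normalized separately (different assays).
   Whether to correlate log or linear CPM is not dictated by the procedure
   itself; we default to log-CPM (Pearson on raw counts mostly measures
   depth) and the choice is a single call-site argument.

2. **MIC screening.** For every (miRNA, ceRNA) combination the maximal
   information coefficient is computed separately in the normal and tumor
   cohorts:

       MIC(X,Y) = max_{n_X·n_Y < B} I(X;Y) / log2 min(n_X, n_Y),  B = ⌊n^0.6⌋

   maximized over grid partitions of the rank scatter. Pairs with
   MIC ≥ 0.5 (the midpoint of the [0,1] range) in *either* cohort are kept.
   The grid search is the ApproxMaxMI heuristic: for each admissible row
   count the row axis is equipartitioned (ties never split), the column axis
   is pre-segmented into clumps (maximal single-row runs), coarsened to at
   most c·n_X superclumps (c = 15), and dynamic programming over clump
   boundaries maximizes mutual information per column count; both axis
   orientations are searched. The strict bound `n_X·n_Y < B` is the default
   (clamped so a 2×2 grid is always admissible); the `inclusive_b` flag
   switches to the `≤ B` convention. An exhaustive search over all cut
   placements between distinct values is included for small n as the test
   oracle; the heuristic can only search a subset of its grids, so it never
   exceeds the exhaustive optimum and matches it when the optimum lies on
   clump boundaries. ApproxMaxMI misses optima requiring strongly
   unbalanced row splits — an inherent property of the estimator, exercised
   deliberately in the tests.

3. **Single-sample perturbation (ΔPCC).** For each kept pair, the Pearson
   correlation PCC_n over the n normal samples is the reference; adding one
   tumor sample s gives PCC_{n+1}, and ΔPCC(pair, s) = PCC_{n+1} − PCC_n
   ∈ [−2, 2] is that patient's perturbation of the pair. All normal samples
   form the reference for every tumor sample (no leave-one-out, no
   LIONESS-style n-scaling). The matrix is computed from per-pair sufficient
   statistics updated in O(1) per (pair, sample); if a perturbed variance
   falls below 1e-12 the perturbed correlation is treated as 0 (ΔPCC =
   −PCC_n) with a warning rather than aborting a large run. ΔMIC is not
   offered: a one-sample change of a grid-based statistic has no comparable
   interpretation.

4. **Feature selection.** Pairs whose ΔPCC distributions differ between
   metastatic (N1–3, M0) and non-metastatic (N0, M0) tumors at two-sided
   Wilcoxon rank-sum p < 0.01 are retained. The threshold is applied to raw
   p-values (a Benjamini–Hochberg column is reported for information only).
   The retained pairs × samples ΔPCC block is reduced by centered PCA
   (features are not variance-scaled — they already share the [−2,2] scale).
   The number of components defaults to the smallest explaining 90% of the
   variance and can be fixed explicitly. By default both the rank-sum filter
   and the PCA are fitted on the 70% training split only, so test metrics
   are honest; `paper_mode=True` fits them on all tumor samples, the variant
   that reports one feature count per cohort.

5. **Classification.** A stacking ensemble with an SVM and a logistic
   regression as base learners and a logistic-regression meta-learner.
   Meta-features are out-of-fold base probabilities from 5 stratified inner
   folds; SVM probabilities come from sigmoid (Platt) calibration fitted on
   out-of-fold decision values. Hyperparameters (SVM kernel ∈ {RBF, linear},
   C ∈ {0.1, 1, 10, 100}, γ ∈ {scale, 0.01, 0.001}; LR C ∈ {0.1, 1, 10})
   are chosen by 5-fold grid search maximizing AUC on the training split
   only; the 30% test split is touched once. The decision threshold is fixed
   at 0.5. Reported metrics: SN, SP, ACC, PPV, NPV from the confusion
   matrix and AUC from the trapezoidal ROC (a rank-statistic AUC is
   implemented independently as a cross-check; the two agree to 1e-12).
   Five-fold CV metrics are computed on the training split by refitting the
   selected configuration per fold and pooling out-of-fold predictions.

6. **Survival.** Per pair, tumor samples are split at the median ΔPCC
   (ties to the low group — the grouping convention is configurable since
   only "high vs low" is inherent to the method) and overall survival is
   compared by the log-rank test; pairs are ranked by raw p, and each pair's
   individual miRNA and RNA expression (median split) are tested alongside
   for the pair-vs-single-gene comparison. Kaplan–Meier estimation and the
   log-rank statistic come from `lifelines`; hand-computed product-limit and
   O−E/variance sums are the test oracles.

7. **Networks.** The global ceRNA network has one edge per selected pair
   (bipartite: miRNA vs ceRNA). A patient-specific network keeps pair p iff
   |ΔPCC[p, patient]| is strictly greater than the median of |ΔPCC[p, ·]|
   over all tumor samples — by the strict-majority property of the median,
   no pair can appear in half or more of the patient networks. Edge weights
   store the *signed* ΔPCC while thresholding on the absolute value, so the
   direction of the correlation change is preserved at no cost to the
   selection rule. A top-k miRNA hub (degree) report accompanies every
   global network.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, with
known ground truth: per sample a latent standard-normal vector in which each
planted miRNA–ceRNA pair has correlation `rho_normal` (normals and
non-metastatic tumors) or `rho_met` (metastatic tumors), all other genes
independent, is pushed through the negative-binomial quantile function
(Gaussian copula; variance = μ + 0.3·μ², gene base means log-normal around
e⁴ ≈ 55 counts). The copula preserves rank correlation — what MIC and
PCC-on-log-CPM respond to — while the count transform and the independent
per-assay library sizes attenuate the observed value; on the TMM log-CPM
scale the pipeline correlates, a latent 0.8 comes out around 0.67–0.75
(mean within ±0.1 of the latent value, tested at 500 samples).  The
attenuation is accepted and documented rather than inverted analytically.
Library sizes are log-normal with CV 30% so TMM has composition work to do.
TNM stages are drawn consistently with the group (positives T1–4/N1–3/M0,
negatives T1–4/N0/M0). Survival is exponential with hazard 1/1500 per day,
multiplied by `survival_effect` = 2.5 for metastatic samples, with
administrative censoring at 2000 days (the horizon is our own addition so
the event indicator is non-trivial).

The fixed default cohort used by the end-to-end checks is 100 normals,
80 metastatic and 80 non-metastatic tumors, 50 miRNAs, 600 ceRNAs (200 per
biotype), and 40 planted pairs with rho 0.8 → 0.0 (seed 20220417). These
sizes sit at the small end of the real cohorts the method targets and keep
a full run around a minute on one CPU.

What the generator does **not** emulate: real miRNA-target topology (planted
pairs are disjoint), gene–gene correlation beyond the planted pairs,
covariate-dependent library sizes, batch effects, or TCGA-scale gene counts
(~10⁵–10⁶ candidate pairs). Passing tests therefore demonstrate that the
machinery recovers the assumed signal structure at realistic noise levels —
not that the biological findings on any real cohort would replicate.

## Numerical and design notes

- MIC: B is clamped so a 2×2 grid is always admissible (otherwise small n
  admits no grid under the strict bound); constant input returns 0 with a
  warning; cuts are only placed between distinct sorted values, so the score
  is exactly invariant under strictly increasing transforms. With an odd
  sample count a 2×2 equipartition cannot be balanced, so noiseless monotone
  data scores H(⌊n/2⌋/n) < 1; at even n it is exactly 1.
- TMM: the edgeR reference implementation is matched to ~1e-6 (verified
  against `calcNormFactors` in a test); a zero-total-count sample is a hard
  error.
- Rank-sum: exact enumeration when |a|+|b| ≤ 12 without ties, tie-corrected
  normal approximation with continuity correction otherwise.
- Determinism: one run seed fans out to per-stage seeds (split, grid search,
  CV, simulation) through `numpy.random.SeedSequence`, so each stage is
  independently reproducible and a rerun with the same config is
  bit-identical. Pipeline stages cache their outputs as TSV/JSON in the run
  directory and resume from cache.
- How many principal components a real cohort needs is not derivable from
  the method itself; the 90%-variance default is our choice and per-cohort
  values can be supplied as configuration.

## Known limitations

- ApproxMaxMI is a heuristic: scores can fall below the true MIC when the
  optimal grid is not clump-aligned (documented above, bounded in tests).
- The survival screen uses a median ΔPCC split; an optimized cutpoint would
  inflate type-I error and is deliberately not offered.
- No multiple-testing correction is applied in selection or survival
  ranking (BH columns are informational), matching the method's design; at
  genome scale users should expect the selected-pair count to include
  roughly alpha × (kept pairs) false positives.
- The pair universe is the full miRNA × ceRNA cross product; no
  sequence-based target filtering is attempted.
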