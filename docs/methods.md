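# Methods note

This note records the statistical model implemented by `glycofuse`, the
default parameters, what the synthetic generator does and does not
capture, the numerical choices that matter for reproducing results, and
the known limitations. Empirical statements below are ones actually
measured by the test suite or the reproduction script.

## 1. Data model

The pipeline operates on a factorial mouse feeding study: samples are
grouped by strain × diet × time-on-diet (default 3 × 2 × 3 = 18
groups), each sample contributing per-tissue omics blocks (RNA-seq
counts, lipidomic intensities) and a continuous phenotype (fasting
glycemia, mg/dL). All supervised modelling happens at the group level:
features are condensed to module eigengenes, eigengenes are averaged
within groups, and the group-mean phenotype is the regression target.
With 18 groups the supervised problem is deliberately low-n; the
permutation machinery exists precisely because asymptotic inference is
unusable at this size.

## 2. Preprocessing

**Counts.** Genes below 1 CPM in every sample are removed (the least
destructive reading of a "< 1 CPM" filter; a stricter
`min_fraction_samples` is available). TMM normalization factors follow
the weighted trimmed-mean-of-M-values construction: the reference
sample is the one whose upper-quartile CPM is closest to the mean
upper-quartile; genes are two-tail trimmed by rank at 30 % on M (log
ratio) and 5 % on A (log abundance); remaining M-values are averaged
with inverse asymptotic-variance weights; factors are rescaled to
geometric mean 1. The implementation was checked against the reference
edgeR implementation during development (agreement ~5e-13); the test
suite re-derives the factor for a two-sample case from an independent
hand-coded oracle. Note the factors are *not* exactly invariant to
library-depth rescaling — the precision weights depend on library
sizes — which matches the published estimator; the test suite asserts
invariance only to 2 %. log2-CPM uses a 0.5 prior count.

**Lipids.** Species missing in at least `max_missing` (default 25 %)
of samples are removed (boundary inclusive: exactly 25 % missing is
removed). Remaining gaps are imputed by round-robin random-forest
regression (missForest-style, via scikit-learn's iterative imputer
with a random-forest estimator); observed cells are never modified.
Samples are then normalized to a total signal of 100; the column sums
are exact to < 1e-9 by construction. Lipids stay on the raw intensity
scale (no log transform) through module detection.

## 3. Module detection

Signed adjacency `a_ij = ((1 + cor_ij)/2)^beta` with `beta = 6` by
default (the transcript setting; lipid blocks typically use higher
powers at the caller's discretion), then the topological overlap
matrix, then average-linkage hierarchical clustering of `1 − TOM`.

The tree is cut statically at `0.995 ×` the maximum merge height, and
the resulting branches are refined with three Marchenko–Pastur (MP)
random-matrix checks on the member-correlation spectrum. For `m`
features over `n` samples the MP bulk edge is `(1 + sqrt(m/n))²`:

* **Split check.** A branch whose second eigenvalue exceeds
  `1.05 ×` the edge contains more than one latent factor and is split
  recursively along its dendrogram children.
* **Coherence check.** A branch whose *first* eigenvalue does not
  clear `1.05 ×` the edge is indistinguishable from noise and is not
  promoted to a module.
* **Membership pruning.** Assigned features whose module membership
  (correlation with the eigengene) falls below
  `min(3/sqrt(n_samples), 0.5)` — roughly three standard errors of a
  null correlation — are released to unassigned; modules that fall
  below the minimum size after pruning are dissolved.

This construction is a deterministic stand-in for the adaptive
dynamic-tree-cut used by WGCNA in practice: the static cut alone
merges distinct planted modules whenever their merge height sits just
under the cut, and average linkage attaches loosely-correlated
background features to real modules. The factor-counting criterion was
chosen from its spectral property, not tuned: on planted two-module
branches the ratio `lambda_2 / edge` is ~4–5 (split signal), on a
module-plus-background branch ~0.6 (no split), and on pure noise
`lambda_1 / edge` is below 1 (no module).

Module labels are ordered by decreasing size (ties by detection
order). Eigengenes are the unit-norm first right singular vector of
the standardized member matrix, sign-oriented towards the mean member
profile. Module membership `MM_ij = cor(feature_i, eigengene_j)` is
computed for all features against all modules.

## 4. Consensus kernel-OPLS

Each block's group × module eigengene table is column-centered and
turned into a linear kernel `K_b = X_c X_cᵀ / ||X_c X_cᵀ||_F`. Block
weights are proportional to `max(RVmod(K_b, y yᵀ), 0)` — the
RV-modified coefficient zeroes the diagonal so self-similarity does
not inflate the weight — and the consensus kernel is the weighted sum.

The kernel-OPLS fit extracts one predictive component
(`t_p ∝ K y_c` after orthogonal deflation) and up to three orthogonal
components generated by `c = t/(tᵀt) − y_c/(y_cᵀ t)` with projection
deflation of the kernel. For linear kernels this is exactly equivalent
to direct NIPALS-OPLS on the concatenated weighted blocks; the test
suite verifies agreement with an independently coded NIPALS oracle to
1e-8 at every orthogonal order 0–3.

The number of orthogonal components is selected by cross-validated Q2
(default 14 folds over 18 groups, deterministic seeded partition),
ties resolved towards fewer components. Block weights are recomputed
inside every training fold and every permutation refit, so no
information from held-out groups or from the unpermuted outcome leaks
into the weighting. Degenerate weightings (no block with positive RV,
which occurs routinely in permutation refits) fall back to uniform
weights rather than aborting. Significance is
`p = (1 + #{Q2_perm ≥ Q2_obs}) / (N + 1)`.

VIP for module `j` of block `b` is normalized per block so
`sum_j VIP_j² = P_b` (the block's module count); sVIP carries the sign
of the predictive loading. The full sVIP vectors of every permutation
are archived, because the gene-score null consumes them.

## 5. Gene scores and enrichment

`V_i = sum_j MM_ij · sVIP_j` over the gene's own tissue's transcript
modules. The per-gene null contracts the *same* MM row with each
permuted sVIP vector — MM is not recomputed under permutation, so the
null isolates the importance-assignment step. `Z_i` standardizes V
against this null (ddof = 1); since a gene correlated with a predictive
module has both large |MM| and a large-|sVIP| module, Z concentrates
sign-consistently in driver members. Ranked lists order by decreasing
Z with a lexicographic tie-break for determinism.

Preranked GSEA uses the weighted Kolmogorov–Smirnov statistic (|Z|^p
hit increments with p = 1, uniform `1/(N − N_hit)` miss decrements; ES
is the extremum of largest magnitude). The null draws `n_perm` random
same-size gene sets from the universe (cached per set size);
NES = ES / mean(|ES_null| of the same sign); p-values are one-sided
within the same-sign null with the +1 correction; BH adjustment is
applied per tissue. Cross-tissue selection keeps terms with adjusted
p ≤ alpha in at least one tissue and annotates every tissue's NES with
significance tiers (`***`/`**`/`*` on adjusted p, `ooo`/`oo`/`o` on
raw p).

## 6. Synthetic generator: what is and is not realistic

Counts are negative-binomial with per-gene dispersions log-uniform in
[0.05, 0.5] and library sizes log-uniform in [5e5, 2e6] — a reasonable
match to bulk RNA-seq marginals. Module structure is a single latent
eigengene per module with homogeneous loadings plus Gaussian noise on
the log scale; real modules have heterogeneous loadings and overlapping
membership. `group_icc` controls how much of the eigengene variance
sits at the group level; calibration work uses ICC 0 (exchangeable
samples — the correct null), the driver study uses ICC 0.8 so
group-mean summaries retain the signal. Lipids are log-normal with
MCAR missingness; real lipidomics missingness is abundance-dependent
(left-censored), so the imputation is exercised under an easier regime
than production data. The phenotype is linear in eigengenes with
Gaussian noise — no nonlinearity, no strain-by-diet interaction beyond
what the baseline map encodes. Each (seed, block-name) pair hashes to
an independent RNG stream, so adding a block never perturbs another
block's draws.

## 7. Numerical choices for reproducibility

* All stochastic steps take explicit seeds; the pipeline derives
  per-stage seeds by fixed offsets (+1000 for fusion permutations,
  +2000 for GSEA) from the config seed.
* Text outputs are written with `float_format="%.10g"`, which is what
  makes two runs of one config byte-identical (verified file-by-file
  in the test suite).
* Eigengene sign, module label order, gene-rank tie-breaks and fold
  assignment are all made deterministic explicitly; nothing depends on
  dict iteration order of user input beyond the documented
  block-name ordering.
* The manifest stores SHA-256 of every output; resume recomputes a
  stage iff any recorded output is missing or its digest changed.

## 8. Measured behaviour

From the test suite and `scripts/acceptance.py` (seed 1):

* Null-model permutation p-values are uniform to KS ≤ 0.15 over 100
  independent null datasets (99 permutations each).
* Null gene Z-scores pooled over six replicate datasets (499-draw
  nulls, 200 genes each) have mean within ±0.1 and SD within
  [0.85, 1.15].
* The planted-driver module attains its block's top VIP and its gene
  set reaches adjusted p ≤ 0.05 with positive NES in ≥ 90 % of 50
  simulation seeds (observed: 100 % on both arms at 20 and 50 seeds).
* TOM, the enrichment score, OPLS and BH agree with independently
  coded brute-force oracles to 1e-12 / 1e-8 as appropriate.

## 9. Limitations

* The group-level regression cannot model within-group covariates;
  mouse-level variation only enters through group means.
* The MP-based module refinement assumes approximately i.i.d. noise
  when calibrating the bulk edge; strongly autocorrelated noise would
  shift the edge and could over-split.
* The gene-score null holds MM fixed, so it calibrates the importance
  step only; uncertainty in module detection itself is not propagated.
* RV-based block weights are nonnegative by construction; a block
  anti-associated with the outcome as a whole contributes nothing
  rather than negatively.
* GSEA's gene-label null ignores inter-gene correlation within the
  ranked list; since module co-members are correlated by construction,
  raw p-values for sets overlapping a module are anti-conservative in
  the same way as standard preranked GSEA. The decoy-set false-positive
  rate measured in the tests (≤ 2 % at adjusted p ≤ 0.01) bounds the
  practical effect under the generator.
* Runtime targets assume a single CPU; the permutation loops are
  vectorized per block but not parallelized.
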