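# Methods

## Model

Each of the three binary tasks is a polynomial-kernel support vector
classifier

    K(x, x') = (γ ⟨x, x'⟩ + 1)^d

over z-normalised gene-level features, with Platt (sigmoid) calibration
fitted by internal 5-fold cross-validation inside the training data to turn
decision values into class probabilities. The class-priority rule defines
outcomes: a gene annotated with the task's primary mechanism is a primary
case regardless of its other annotations; secondary cases carry the
secondary class and not the primary; all other genes are excluded. For the
LOF vs non-LOF task the secondary pool is (DN ∪ GOF) \ LOF.

The three probabilities are combined proteome-wide by rank: for each model
the fractional rank (average rank / N, ties averaged) of every protein's
probability is computed over all scored proteins, the mechanism with the
highest rank fraction wins (ties broken DN > GOF > LOF), and with the
cutoff active the winner must have raw probability strictly above its
model's t50 or the protein is left unclassified. Because the assignment
depends only on ranks, it is invariant to any strictly increasing transform
of one model's probabilities — the property that motivates the design, since
the three models' probability distributions are not comparable on the raw
scale.

## Tunable parameters

| parameter | default | units / range | role |
|---|---|---|---|
| cost C | tuned, 10^[-3, 2] | — | SVM regularisation |
| degree d | tuned, 1–5 | integer | kernel degree |
| scale factor γ | tuned, 10^[-3, 0] | — | kernel inner-product scale |
| margin | tuned, 0–0.2 | probability | accepted and logged; inert for a classification SVM (it parametrises the ε-band of the regression form) |
| split proportion | 0.75 | fraction | train share of the stratified split |
| CV | 3 × 10-fold | — | stratified repeated k-fold on training rows |
| spearman_threshold | 0.9 | \|ρ\| | redundancy filter cutoff |
| knn_k | 5 | neighbours | imputation |
| identity_cutoff | 0.5 | fraction identity | within-outcome homology dedup |
| n_embeddings | 20 | dims | embedding dims kept per task by Wilcoxon r |
| rsa_threshold | 0.05 | RSA fraction | surface residue definition |
| ddg_epsilon | 0.01 | kcal/mol | \|ΔΔG\| clamp before ratio features |
| t50 | derived | probability | largest grid θ with test sensitivity ≥ 0.5 |
| pLDDT cutoff | 70 | — | residue confidence floor for EDC and ΔΔG analyses |
| enrichment filters | FDR < 0.01, n > 50, fold > 1.5 | — | reported-term criteria |

Hyperparameter search: a random grid of 10 configurations seeds a Gaussian
process (Matérn 5/2 + white noise on inputs scaled to the unit box,
normalised objective), then up to 20 iterations propose the candidate (from
500 random draws) maximising expected improvement of mean cross-resample
AUROC, with early stop after 10 stalled iterations. The tuning objective
uses the SVM decision function rather than calibrated probabilities: AUROC
is rank-based, so calibration cannot change it, and this avoids nested
calibration fits.

The stated cross-validation protocol ("10-fold, itself split 75/25") is
internally inconsistent — a 10-fold partition implies 90/10 analysis/
assessment splits. The default here is standard stratified repeated k-fold;
a Monte-Carlo mode (the same number of stratified 75/25 resamples) is
available behind `make_resamples(..., mode="mc")` so both readings are
supported.

## Feature engineering choices

* **Max-ASA reference.** RSA divides observed residue ASA by the theoretical
  Gly-X-Gly maximum of Tien et al. (2013); the 20 values are bundled as
  `MAX_ASA_GXG`. RSA above 1 is preserved, not clamped.
* **ΔΔG ratio features.** The median ESM-1v/ΔΔG ratio is computed with the
  denominator clamped to ±0.01 kcal/mol (sign preserved) so near-zero
  stability changes give bounded ratios; the companion feature uses |ΔΔG|.
* **Effect size.** Wilcoxon effect size is r = |Z|/√(n₁+n₂) from the
  tie-corrected normal approximation of the rank-sum statistic without
  continuity correction; rank-biserial correlation was rejected to keep one
  convention throughout.
* **Leakage.** Embedding selection is refit on training rows only, inside
  each task, because selecting on the full dataset would leak outcome
  information into the feature set.

## Preprocessing order and tie-breaks

Pipeline order: task labelling → correlation filter → homology dedup →
stratified split → normalise/impute (fitted on the training split). The
correlation filter greedily resolves the worst offending pair, dropping the
member with the larger mean absolute correlation to the remaining features
(ties: later column). Homology dedup resolves offending same-outcome pairs
in descending identity order, removing by preference (1) the member whose
label set spans multiple mechanism classes, (2) the member with more
remaining conflicts, (3) the lexicographically later id — a deterministic
greedy procedure; exact minimum vertex cover is NP-hard and nothing suggests
the original procedure solved it exactly. Imputation is k-NN over
nan-aware Euclidean distances on mutually observed normalised features
(scikit-learn `KNNImputer` fitted on training rows); a row with no observed
features degenerates to training column means.

## EDC

The clustering metric is implemented as

    EDC = ln( mean over non-variant residues of the distance to the nearest
              variant Cα  /  mean over variant residues of the distance to
              the nearest other variant Cα )

after excluding residues with pLDDT < 70 and requiring ≥ 5 surviving variant
positions. This nearest-neighbour ratio formulation is an interpretation:
the metric's defining publication was not reimplemented line-by-line, so
correctness is anchored by order properties (clustered > scattered, rigid-
motion invariance) rather than absolute values, and the function is a single
seam that an exact formula can replace.

## Explainability

Global importance is AUROC loss over 10 column shuffles per feature. Local
attribution is the sampling Shapley estimator: 20 random feature orderings,
one background row per ordering, marginal contributions accumulated along
the walk from all-background to all-instance. With the baseline defined as
the mean model output over the sampled background rows, additivity
(Σφ = prediction − baseline) holds exactly for the estimator; the test
tolerance of 0.02 covers numerical noise only. The background set is the
training set, subsampled to 200 rows with the report's seed.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical structure* the pipeline assumes:
a 1,270-gene label collection with the 874/318/78 unique/double/triple
mixture (largest-remainder deterministic rounding by default, multinomial
optionally); Gaussian class-conditional features whose informative members
shift by a configurable standardised effect along a class contrast; a
near-duplicate of `s_het` (`oe_lof`, |ρ| ≈ 0.95) as a realistic target for
the redundancy filter; MCAR missingness over interpretable features (5 %
default; embedding stores are complete in practice); block-structured
identity matrices with homolog families straddling the 50 % cutoff; jittered
self-avoiding-walk backbones at 3.8 Å Cα spacing with a contiguous
low-pLDDT segment (20 % of length); clustered pathogenic variant placement
with milder ΔΔG and weaker VEP separation for non-LOF proteins versus
scattered, destabilising, well-predicted variants for LOF proteins.

Default feature contrasts follow the biology of the real panel: constraint
metrics (s_het, pLI) load on the LOF axis, "recessive-likeness" and paralogy
(pRec, paralogue count) on the non-LOF axis. Real features are non-Gaussian
with richer covariance; embeddings carry no semantics beyond their planted
effects; backbone geometry is not protein-like beyond pairwise distances.
Passing tests on this cohort therefore demonstrates that the pipeline
recovers known structure at the configured effect sizes and respects its own
contracts — not that real-data performance matches any published figure.

## Problem sizes used in automated checks

Parameter-recovery checks use 1,200-gene cohorts (600 for the ten-seed
importance loop) with 3 informative features at d = 2 among 40, unique-class
genes, and the informative contrasts spread over the three tasks
(LOF/non-LOF/non-LOF) so each binary outcome receives the nominal effect;
with the realistic mixed-class mixture the task-level separation is diluted
below the nominal d (mixed genes carry both shifts), which is a property of
the labels, not of the estimator. The null-effect check reports the mean
held-out AUROC over five seeds to keep the sampling noise of a single
~300-row test set from dominating. The acceptance script runs the full
cohort at n = 1,270 with 128 embedding dimensions and a 250-protein
structural subset.

## Known limitations

* The probability calibration (Platt within training data) differs in fold
  structure from any specific original implementation; probabilities near 0
  and 1 are the least comparable across implementations.
* The `margin` hyperparameter is searched but inert (classification SVM);
  it is retained for protocol fidelity and artefact completeness.
* EDC absolute values depend on the formula interpretation above.
* The enrichment redundancy collapse uses Jaccard > 0.5 on foreground
  membership as the definition of "similar terms"; ontology-aware grouping
  is out of scope.
* Gene↔protein identifier mapping is taken as given (canonical isoform per
  gene); multi-isoform handling is not modelled.
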