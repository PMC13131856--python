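# Methods

## Overview

`voxalign` implements a multimodal momentum-contrast framework for paired
volumetric images and the downstream pipeline that turns the learned
representations into latent imaging phenotypes, quantifies cross-modal
alignment at the feature level (linear CKA, CCA), and compares genetic
signal across modalities (per-SNP association scans, minP aggregation,
LD/distance clumping, padded interval overlap). Everything is exercised
end-to-end on a built-in synthetic cohort with known ground truth, so each
stage admits parameter-recovery tests.

## Contrastive model

Two encoders with identical volumetric-transformer architecture — a query
encoder and a key encoder — are initialized with the same weights. A volume
is zero-padded (extra voxel on the high side of an odd remainder) to a shape
divisible by the patch size and tiled into non-overlapping patches,
enumerated x-fastest; each flattened patch is linearly projected to the
token width, a learned positional encoding is added, and a stack of pre-norm
transformer blocks (multi-head self-attention, GELU MLP, residual
connections) followed by a final layer norm produces per-patch embeddings.
A projection head (mean pool over patches → 2-layer MLP → L2 normalization)
maps each volume to a unit vector used only during training.

Training forms cross-modal positive pairs: the query encoder embeds one
modality of a subject, the key encoder embeds the paired modality, and the
InfoNCE loss

    L = −log [ exp(q·k⁺/τ) / ( exp(q·k⁺/τ) + Σ_j exp(q·k⁻_j/τ) ) ]

contrasts the positive similarity against all entries of a FIFO queue of
past key embeddings (log-sum-exp stabilized; keys carry no gradient). The
objective is symmetric: both modalities take the query role and the two
directional losses are averaged, so neither modality is privileged. After
each step the key encoder is updated as an exponential moving average
θ_k ← m·θ_k + (1−m)·θ_q, and the fresh key embeddings are enqueued while the
oldest are dequeued.

Design choices where the published description leaves room:

* **Per-modality queues.** Negatives are drawn from the queue matching the
  key's modality. With a single mixed queue the loss could be lowered by
  trivially separating modalities; same-modality negatives remove that
  shortcut.
* **Pooling point.** The projection head consumes the mean-pooled volume
  representation (instance-level discrimination); per-patch embeddings are
  kept pre-pooling for extraction.
* **Patch size.** At full scale, 14×16×14 is the near-isotropic
  factorization of a 182×224×182 padded volume that yields a 13×14×13 =
  2,366-patch grid; the workstation default is 8×8×8 on 32³ volumes.
* **Queue initialization.** Queues start as random unit vectors so the loss
  is well defined from the first step. A consequence worth knowing: random
  vectors in high dimension are nearly orthogonal to everything, so they are
  *easy* negatives, and the loss typically **rises** while the queue turns
  over (first ceil(K/n) epochs) before the usual decrease. Training-progress
  checks therefore compare the final epoch against the first post-turnover
  epoch. For the same reason, on small cohorts the queue quickly fills with
  stale keys of the very subjects in the current batch (near-positives), so
  single-step optimization checks hold the queue fixed.

Default hyperparameters are the published full-scale ones: temperature
τ = 0.07, momentum m = 0.999, queue K = 65,536, AdamW with initial learning
rate 1e-4 and a cosine-annealing warm-restart schedule (T₀ = 10, T_mult = 2,
η_min = 1e-6), 300 epochs, encoder of 12 layers, 6 heads, width 384,
projection 256. The `desk` profile overrides only the sizes (depth 2,
heads 4, width 64, projection 64; K = 1,024; 20 epochs; batch 32), never the
statistical conventions. AdamW decays only matrix-valued parameters
(decay 0.01); biases, gains and the positional table are exempt.

The tensor backend is a small reverse-mode automatic-differentiation engine
over NumPy arrays (float32 training dtype; float64 preserved when supplied,
which lets the loss identities be verified at double precision). Gradients
of every primitive are tested against central finite differences, and the
full encoder–head–loss chain is gradient-checked in the test suite.
Training is single-threaded deterministic: identical seeds give bit-identical
parameters.

## Embedding extraction and latent imaging phenotypes

After training the projection head is dropped and the frozen query encoder
produces per-patch embeddings per subject and modality. Each subject's
(patches × width) matrix is flattened patch-major (row-major) — the order is
fixed so PCA bases in checkpoints stay portable — and a PCA basis fitted
jointly on the stacked rows of both modalities (mean-centering only, no
variance scaling) projects both modalities into one coordinate system,
giving K latent imaging phenotypes (UDIPs) per modality with per-component
explained variance. A per-modality fit is available as an alternative.

Quality control masks individual entries whose value lies strictly more than
`z_thresh` (default 5) standard deviations from the column mean. Column
statistics are computed once on unmasked data and cached, so masking is
idempotent; per-UDIP analysis sample sizes may therefore differ downstream.

## Alignment metrics

Linear CKA is computed in the feature-space form
‖Yᶜᵀ Xᶜ‖²_F / (‖Xᶜᵀ Xᶜ‖_F ‖Yᶜᵀ Yᶜ‖_F), equal to the centered-Gram form; the
biased (standard) HSIC estimator is used. Rows with missing values in either
representation are removed first. The positive-pair distribution comes from
bootstrap resamples of matched subjects; the negative-pair null from random
permutations of the modality-b assignment, redrawn whenever a permutation
contains a fixed point so no true pair leaks into the null.

A caveat the test suite documents: bootstrap resampling duplicates subjects,
and a duplicated subject matches itself exactly in both modalities, so under
*independent* modalities the positive-pair mean sits slightly above the
permutation null (≈0.06 vs ≈0.03 at n = 500, p = q = 16). The bias shrinks
with n and is negligible next to the trained-model signal (positive-pair CKA
above 0.8 at desk scale).

CCA standardizes both sides, whitens via thin SVD, and reads the canonical
correlations off the singular values of Uₓᵀ U_y; the component count is
min(n − 1, min(p, q)), reduced with a warning under rank deficiency. No
regularization is applied; a warning is emitted when n < 5·max(p, q)
because unregularized in-sample correlations inflate. Summaries report the
mean (equivalently the normalized area under the sorted-ρ bar profile), the
maximum, and the counts of components with ρ strictly above 0.3 and 0.5.

## Genetic analyses

The association scan is ordinary least squares: for each latent phenotype,
the phenotype and every retained dosage column are residualized on the
covariates plus intercept and the residuals regressed against each other —
by the Frisch–Waugh theorem identical to the full multiple regression —
with two-sided p-values from the t distribution on n − c − 2 degrees of
freedom. OLS is a deliberate simplification of a linear mixed model with a
genetic-relationship random effect: the synthetic cohort is unrelated by
construction, so the random effect would be superfluous. SNPs below the MAF
threshold (default 0.01) are dropped; QC-masked entries are excluded per
phenotype.

Per SNP, the most significant p-value across phenotypes (minP) is kept, with
ties broken toward the lowest phenotype index. Significant SNPs
(minP < α, default 5e-8/128) are clumped greedily: the best remaining SNP
becomes a lead; every remaining significant same-chromosome SNP with
r² > 0.1 to the lead joins its locus; the locus spans its members'
positions; finally same-chromosome loci separated by less than 250 kb are
merged (merged lead = smallest minP). This is a single-tier simplification
of the two-tier r² = 0.6/0.1 clumping used by standard annotation servers —
only the overlap logic downstream depends on it. Coordinates are 1-based
inclusive internally; BED export converts to 0-based half-open. Ties break
by ascending position, then SNP id.

For cross-analysis comparison every locus is extended by 125 kb per side
(floored at position 1; synthetic chromosomes have no length ceiling),
per-chromosome interval trees index the extended intervals, and union–find
over pairwise intersections forms transitive clusters. A cluster with
members from both sets is shared; the partition identity
shared + unique_a + unique_b = total holds on every input and the
interval-tree result is tested against an O(n²) all-pairs oracle. Novel loci
are target loci whose extended interval intersects no extended reference
locus.

## Trait annotation

PheWAS regresses each trait on each latent phenotype with covariates entered
directly (numerically equivalent to pre-residualization under
Frisch–Waugh); the Bonferroni threshold is 0.05 divided by the tested matrix
dimensions. Incremental R² compares covariate-only and covariate-plus-all-K
OLS fits, with the partial (omnibus) F statistic
[(RSS_red − RSS_full)/K] / [RSS_full/(n − c − K − 1)]. Per canonical
component, trait regressions on the component score are summarized by the
95th percentile of −log10 p over traits — the strong-association tail; the
alternative reading (a percentile of p itself) would track the weak tail and
is not used. P-values are floored at 1e-300. Missing entries are handled
pairwise-complete with per-pair n reported.

## Synthetic cohort

The generator emulates, at workstation scale, the structure the method
needs: (i) Hardy–Weinberg genotypes of unrelated subjects, dosage ~
Binomial(2, p) with p uniform over a MAF range (default 0.05–0.5), laid out
at 10 kb spacing on 2 synthetic chromosomes; (ii) a d = 8 dimensional
subject latent z = standardize(G[:, causal])·β + ε with 8 planted causal
SNPs (one per latent dimension, β = 1, latent noise SD 0.25), shared by both
modalities — pleiotropy by construction; (iii) per modality a fixed
seed-derived linear map from latent to voxels, Gaussian smoothing (σ = 1)
and i.i.d. voxel noise (SD 0.5) on 32³ volumes for 200 subjects; (iv) trait
tables that are linear functions of z plus noise (SD 0.5) with standardized
age/sex covariates. One master seed spawns independent sub-streams per
component. Latent dimensions can be made private to one modality; with
`private_fraction = 1` the causal SNPs drive disjoint modality-private
latents, giving the contrast condition for locus-overlap recovery tests.

What the generator does **not** emulate: MRI contrast physics, bias fields,
registration artifacts, spatial anatomy, linkage disequilibrium beyond
planted blocks in tests, relatedness, or population structure. Passing tests
therefore demonstrate that the machinery recovers planted cross-modal
structure under its own model assumptions, not that it reproduces any
cohort-specific result on real images or genotypes.

## Problem sizes for automated checks

The end-to-end recovery check trains at the workstation scale above
(200 subjects, 32³ volumes, 20 epochs, queue 1,024, 32 principal
components) for three paired seeds — each seed once with shared-latent and
once with modality-private causal SNPs — and asserts (a) the loss decreases
from the first post-queue-turnover epoch to the last, (b) the
positive-minus-negative CKA gap exceeds 0.3, and (c) cross-modality locus
overlap is strictly higher under shared than under private causal latents.
The acceptance script (`scripts/acceptance.py`) repeats the two conditions
at the same scale for one seed and writes every headline quantity it
computes.

## Known limitations

* Unregularized CCA inflates in-sample at small n relative to feature count;
  the warning threshold (n < 5·max(p, q)) is a heuristic.
* The greedy single-tier clumping surrogate can split or merge loci
  differently from two-tier schemes in dense LD; conclusions about overlap
  percentages should be read within this convention.
* The OLS association model is only appropriate for unrelated samples.
* Training on CPU limits practical encoder sizes; the full-scale profile is
  recorded in configuration but is not expected to be run as-is.
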