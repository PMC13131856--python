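# voxalign

Multimodal momentum-contrast representation learning for paired volumetric
images, with the downstream pipeline that turns learned representations into
latent imaging phenotypes and measures how well two modalities agree — at
the feature level and at the genetic level.

## Who this is for

Imaging-genetics groups working with paired per-subject 3D acquisitions
(e.g., two structural MRI contrasts of the same brain) who want
*unsupervised* subject-level phenotypes that are consistent across
modalities, and who then run those phenotypes through association scans.
The package provides:

* **Contrastive training** (`voxalign.contrast`): a volumetric transformer
  encoder trained with a symmetric momentum-contrast objective. The two
  modality volumes of one subject are the positive pair; negatives come from
  per-modality FIFO queues of past key embeddings; the key encoder is an
  exponential moving average of the query encoder. The InfoNCE loss

      L = −log [ exp(q·k⁺/τ) / (exp(q·k⁺/τ) + Σ_j exp(q·k⁻_j/τ)) ]

  is averaged over both query/key role assignments, so neither modality is
  privileged. Defaults: τ = 0.07, momentum 0.999, queue 65,536, AdamW at
  1e-4 with cosine warm restarts. The tensor backend is a compact NumPy
  reverse-mode autodiff engine, so no GPU stack is required.
* **Latent imaging phenotypes** (`voxalign.embed`): frozen-encoder patch
  embeddings, flattened per subject and reduced by a *jointly fitted* PCA so
  both modalities land in one coordinate system (UDIPs); per-entry 5-SD
  outlier QC.
* **Alignment metrics** (`voxalign.align`): linear CKA
  (‖Yᶜᵀ Xᶜ‖²_F / (‖Xᶜᵀ Xᶜ‖_F ‖Yᶜᵀ Yᶜ‖_F)) with bootstrap positive-pair and
  derangement-permutation negative-pair distributions, and SVD-based CCA
  with mean/max/threshold-count summaries.
* **Genetics** (`voxalign.genetics`): covariate-adjusted per-SNP OLS scans
  over all UDIPs, per-SNP minP aggregation, Bonferroni thresholding
  (5e-8/128 by default), greedy LD/distance clumping (r² ≤ 0.1, 250 kb
  merge), 125 kb locus extension, and interval-tree cross-set overlap with
  the partition identity shared + unique_a + unique_b = total.
* **Trait annotation** (`voxalign.phenoassoc`): UDIP–trait regressions with
  Bonferroni correction, incremental R² with partial F omnibus tests, and
  per-CCA-component association summaries (95th percentile of −log10 p).
* **Synthetic cohort** (`voxalign.simdata`): Hardy–Weinberg genotypes,
  planted causal SNPs driving a latent shared by both modality renderings
  (optionally modality-private), trait tables — every downstream stage is
  testable against known ground truth.

## Worked example

```python
import numpy as np
from voxalign.simdata import simulate_cohort
from voxalign.contrast import (PatchSpec, EncoderConfig, ContrastiveConfig,
                               train_contrastive)
from voxalign.embed import extract_embeddings, pca_reduce, outlier_mask
from voxalign.align import cka_bootstrap
from voxalign.genetics import gwas_scan, clump_loci, overlap_loci

# 200 subjects, paired 32^3 volumes rendered from one genetic latent
panel, latent, volumes, traits = simulate_cohort(n_subjects=200, seed=1)

enc = EncoderConfig(depth=2, heads=4, width=64, proj_dim=64)
con = ContrastiveConfig(queue_size=1024, epochs=20, batch_size=32, seed=1)
spec = PatchSpec((8, 8, 8), (32, 32, 32))
state, trace = train_contrastive(volumes, enc, con, spec)

emb_a = extract_embeddings(state.query_params, volumes, "a", spec, enc)
emb_b = extract_embeddings(state.query_params, volumes, "b", spec, enc)
udip_a, udip_b = pca_reduce(emb_a, emb_b, k=32)          # joint PCA
udip_a, udip_b = outlier_mask(udip_a), outlier_mask(udip_b)

pos, neg = cka_bootstrap(udip_a, udip_b, n_boot=50, seed=1)
print(f"CKA positive pairs {pos['mean']:.3f}, negative pairs {neg['mean']:.3f}")

cov = traits.covariates.to_numpy()
loci_a = clump_loci(gwas_scan(panel, udip_a, cov), panel)
loci_b = clump_loci(gwas_scan(panel, udip_b, cov), panel)
ov, _ = overlap_loci(loci_a, loci_b)
print(f"loci: {len(loci_a)} (a) / {len(loci_b)} (b), "
      f"{ov.shared}/{ov.total} shared = {ov.percent_shared:.1f}%")
```

Output from this exact script:

```
CKA positive pairs 0.842, negative pairs 0.082
loci: 8 (a) / 8 (b), 8/8 shared = 100.0%
```

Matched subjects are far more similar than permuted ones (0.842 vs 0.082
CKA), and both modalities recover the same 8 planted causal loci, so every
locus cluster is shared. Re-running the same cohort with
`simulate_cohort(..., private_fraction=1.0)` — causal SNPs driving
modality-*private* latents — drops the CKA gap to ≈0.08 and the locus
overlap to 0%: the cross-modal agreement is genuinely genetic, not an
artifact of the pipeline.

## Command line

```
voxalign simulate|train|embed|align|gwas|overlap|phewas|run-all --help
```

Each subcommand is a thin wrapper over the library (`run-all` executes the
whole pipeline and writes a manifest with seeds and artifact hashes for
exact re-runs). Volumes are NIfTI-1 (`<iid>_<modality>.nii.gz`), tables are
CSV keyed by an `IID` column, summary statistics are fastGWA-style TSV, loci
are BED (0-based half-open) plus a JSON sidecar.

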