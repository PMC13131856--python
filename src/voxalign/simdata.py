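"""Synthetic multimodal imaging-genetics cohort with known ground truth.

The generative model is deliberately simple and fully controlled so that
every downstream stage (contrastive training, latent-phenotype extraction,
association scans, locus overlap) admits parameter-recovery tests:

1. Genotypes: unrelated subjects, Hardy-Weinberg dosages ``Binomial(2, p)``
   with ``p`` drawn per SNP from a uniform MAF range; SNPs laid out at
   regular spacing on a configurable number of synthetic chromosomes.
2. Subject latent: ``z = standardize(G[:, causal]) @ beta + noise`` — a
   small set of planted causal SNPs drives a d-dimensional latent shared by
   both imaging modalities (pleiotropy by construction).
3. Paired volumes: each modality is a distinct fixed linear rendering of
   ``z`` into voxel space, Gaussian-smoothed, plus i.i.d. voxel noise. The
   two modalities are therefore different views of the same underlying
   anatomy, which is exactly the structure the contrastive objective is
   meant to exploit. Latent dimensions may be made private to one modality
   to create modality-unique genetic signal.
4. Traits: linear functions of ``z`` plus noise, standing in for
   conventional imaging-derived phenotypes; age/sex covariates included.

All generators are pure functions of their arguments and a seed. A master
seed spawns independent sub-streams per component so each piece can be
regenerated on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "GenotypePanel",
    "LatentCohort",
    "PairedVolumeCohort",
    "TraitTable",
    "gen_genotypes",
    "gen_latent",
    "render_paired_volumes",
    "gen_trait_table",
    "simulate_cohort",
    "write_genotypes",
    "write_traits",
]


@dataclass
class GenotypePanel:
    """Additive dosage matrix with per-SNP genomic metadata."""

    dosages: np.ndarray          # (n_subjects, n_snps) int8 in {0,1,2}
    chrom: np.ndarray            # (n_snps,) str chromosome labels
    pos: np.ndarray              # (n_snps,) int64, 1-based positions
    maf: np.ndarray              # (n_snps,) realized minor-allele frequency
    snp_id: np.ndarray           # (n_snps,) unique str identifiers
    subject_id: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must be in {0, 1, 2}")
        if len(set(self.snp_id.tolist())) != len(self.snp_id):
            raise ValueError("snp_ids must be unique")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


@dataclass
class LatentCohort:
    """Shared subject latent plus causal-SNP bookkeeping."""

    z: np.ndarray                # (n_subjects, d)
    causal_idx: np.ndarray       # indices into the SNP axis
    beta: np.ndarray             # (n_causal, d) effects onto latent dims
    subject_id: list[str]

    def __post_init__(self):
        if not np.isfinite(self.z).all():
            raise ValueError("latent matrix contains non-finite values")


@dataclass
class PairedVolumeCohort:
    """Two volumetric modalities per subject, identical shapes throughout."""

    subject_id: list[str]
    vol_a: np.ndarray            # (n_subjects, *shape)
    vol_b: np.ndarray
    shape: tuple[int, int, int]

    def __post_init__(self):
        if self.vol_a.shape != self.vol_b.shape:
            raise ValueError("modalities must have identical array shapes")
        if tuple(self.vol_a.shape[1:]) != tuple(self.shape):
            raise ValueError("volume shape does not match declared shape")
        if self.vol_a.shape[0] != len(self.subject_id):
            raise ValueError("subject count mismatch")


@dataclass
class TraitTable:
    """Stand-in conventional imaging traits plus covariates, one row/subject."""

    subject_id: list[str]
    idps: pd.DataFrame           # indexed by IID
    covariates: pd.DataFrame     # indexed by IID (age, sex, ...)

    def __post_init__(self):
        if self.idps.index.duplicated().any():
            raise ValueError("duplicated subject_id in trait table")


def _ids(n: int) -> list[str]:
    return [f"S{i:06d}" for i in range(n)]


def gen_genotypes(
    n_subjects: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    n_chrom: int = 2,
    seed: int = 0,
    spacing_bp: int = 10_000,
) -> GenotypePanel:
    """Draw a Hardy-Weinberg genotype panel of unrelated subjects."""
    lo, hi = maf_range
    if n_subjects <= 0 or n_snps <= 0:
        raise ValueError("n_subjects and n_snps must be positive")
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
    if n_chrom <= 0 or n_chrom > n_snps:
        raise ValueError("need 1 <= n_chrom <= n_snps")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_snps)
    dosages = rng.binomial(2, p, size=(n_subjects, n_snps)).astype(np.int8)
    per = np.full(n_chrom, n_snps // n_chrom)
    per[: n_snps % n_chrom] += 1
    chrom = np.concatenate(
        [np.full(k, str(c + 1)) for c, k in enumerate(per)]
    )
    pos = np.concatenate(
        [spacing_bp * (np.arange(k, dtype=np.int64) + 1) for k in per]
    )
    freq = dosages.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    snp_id = np.array([f"rs{c}_{p_}" for c, p_ in zip(chrom, pos)])
    return GenotypePanel(dosages, chrom, pos, maf, snp_id, _ids(n_subjects))


def standardize_dosages(dosages: np.ndarray) -> np.ndarray:
    """Column-standardize dosages; zero-variance columns map to zero."""
    g = dosages.astype(np.float64)
    mu = g.mean(axis=0)
    sd = g.std(axis=0)
    sd[sd == 0] = 1.0
    return (g - mu) / sd


def gen_latent(
    panel: GenotypePanel,
    causal_idx,
    beta,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> LatentCohort:
    """Build the shared subject latent from planted causal SNPs."""
    causal_idx = np.asarray(causal_idx, dtype=np.int64)
    beta = np.atleast_2d(np.asarray(beta, dtype=np.float64))
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if causal_idx.size and (
        causal_idx.min() < 0 or causal_idx.max() >= panel.n_snps
    ):
        raise ValueError("causal_idx out of SNP index range")
    if beta.shape[0] != causal_idx.size:
        raise ValueError(
            f"beta has {beta.shape[0]} rows but {causal_idx.size} causal SNPs"
        )
    rng = np.random.default_rng(seed)
    d = beta.shape[1]
    gz = standardize_dosages(panel.dosages[:, causal_idx]) if causal_idx.size else 0.0
    z = (gz @ beta if causal_idx.size else np.zeros((panel.n_subjects, d)))
    z = z + rng.normal(0.0, noise_sd, size=(panel.n_subjects, d))
    return LatentCohort(z, causal_idx, beta, list(panel.subject_id))


def render_paired_volumes(
    latent: LatentCohort,
    shape: tuple[int, int, int] = (32, 32, 32),
    smooth_sigma: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    private_dims_a=(),
    private_dims_b=(),
    null_voxel_frac: float = 0.0,
) -> PairedVolumeCohort:
    """Render two modality volumes per subject from the shared latent.

    Each modality has its own fixed seed-derived latent-to-voxel map, so the
    modalities are distinct deterministic renderings of the same ``z``.
    ``private_dims_a``/``private_dims_b`` list latent columns visible only to
    that modality (their loadings are zeroed in the other map), which creates
    modality-unique downstream genetic signal. ``null_voxel_frac`` forces
    that fraction of voxels to carry no latent signal in either modality
    (pure-noise control voxels).
    """
    n, d = latent.z.shape
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 2:
        raise ValueError("shape must be three dims of at least 2 voxels")
    nvox = int(np.prod(shape))
    rng_map = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    rng_noise = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    scale = 1.0 / np.sqrt(d)
    W_a = rng_map.normal(0.0, scale, size=(d, nvox))
    W_b = rng_map.normal(0.0, scale, size=(d, nvox))
    for dim in private_dims_a:
        W_b[int(dim), :] = 0.0
    for dim in private_dims_b:
        W_a[int(dim), :] = 0.0
    if null_voxel_frac > 0:
        n_null = int(round(null_voxel_frac * nvox))
        null_vox = rng_map.choice(nvox, size=n_null, replace=False)
        W_a[:, null_vox] = 0.0
        W_b[:, null_vox] = 0.0

    def render(W, z):
        vols = (z @ W).reshape(n, *shape)
        if smooth_sigma > 0:
            for i in range(n):
                vols[i] = gaussian_filter(vols[i], smooth_sigma)
        return vols

    vol_a = render(W_a, latent.z)
    vol_b = render(W_b, latent.z)
    if noise_sd > 0:
        vol_a = vol_a + rng_noise.normal(0.0, noise_sd, size=vol_a.shape)
        vol_b = vol_b + rng_noise.normal(0.0, noise_sd, size=vol_b.shape)
    cohort = PairedVolumeCohort(
        list(latent.subject_id),
        vol_a.astype(np.float32),
        vol_b.astype(np.float32),
        shape,
    )
    # expose the maps for construction-level tests
    cohort.W_a, cohort.W_b = W_a, W_b  # type: ignore[attr-defined]
    return cohort


def gen_trait_table(
    latent: LatentCohort,
    q_idps: int = 32,
    loading_sd: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> TraitTable:
    """Derive stand-in conventional traits as linear functions of the latent."""
    if q_idps <= 0:
        raise ValueError("q_idps must be positive")
    rng = np.random.default_rng(seed)
    n, d = latent.z.shape
    L = rng.normal(0.0, loading_sd, size=(d, q_idps))
    idps = latent.z @ L + rng.normal(0.0, noise_sd, size=(n, q_idps))
    ids = list(latent.subject_id)
    idp_df = pd.DataFrame(
        idps, index=pd.Index(ids, name="IID"),
        columns=[f"IDP_{j}" for j in range(q_idps)],
    )
    age = rng.uniform(45.0, 80.0, size=n)
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    cov = pd.DataFrame({"age": age, "sex": sex}, index=pd.Index(ids, name="IID"))
    cov = (cov - cov.mean()) / cov.std(ddof=0)
    return TraitTable(ids, idp_df, cov)


def simulate_cohort(
    n_subjects: int = 200,
    n_snps: int = 2000,
    d: int = 8,
    n_causal: int = 8,
    beta_scale: float = 1.0,
    latent_noise_sd: float = 0.25,
    shape: tuple[int, int, int] = (32, 32, 32),
    smooth_sigma: float = 1.0,
    volume_noise_sd: float = 0.5,
    q_idps: int = 32,
    trait_noise_sd: float = 0.5,
    maf_range: tuple[float, float] = (0.05, 0.5),
    n_chrom: int = 2,
    private_fraction: float = 0.0,
    seed: int = 0,
):
    """Generate a full synthetic cohort from one master seed.

    Causal SNPs are spread evenly across the panel, one per latent dimension
    (cycling if ``n_causal > d``). With ``private_fraction > 0`` the first
    ``ceil(private_fraction*d)`` latent dims are split between the two
    modalities as private dims, so the causal SNPs loading on them produce
    modality-unique loci.

    Returns ``(panel, latent, volumes, traits)``.
    """
    ss = np.random.SeedSequence(int(seed))
    s_geno, s_latent, s_render, s_traits = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    ]
    panel = gen_genotypes(n_subjects, n_snps, maf_range, n_chrom, s_geno)
    causal_idx = np.linspace(0, n_snps - 1, n_causal, dtype=np.int64)
    beta = np.zeros((n_causal, d))
    for j in range(n_causal):
        beta[j, j % d] = beta_scale
    latent = gen_latent(panel, causal_idx, beta, latent_noise_sd, s_latent)
    n_private = int(np.ceil(private_fraction * d))
    priv_a = tuple(range(0, n_private, 2))
    priv_b = tuple(range(1, n_private, 2))
    volumes = render_paired_volumes(
        latent, shape, smooth_sigma, volume_noise_sd, s_render,
        private_dims_a=priv_a, private_dims_b=priv_b,
    )
    traits = gen_trait_table(latent, q_idps, 1.0, trait_noise_sd, s_traits)
    return panel, latent, volumes, traits


# -- plain-text exports ---------------------------------------------------


def write_genotypes(panel: GenotypePanel, prefix) -> None:
    """Write a tab-separated dosage matrix plus a .bim-like SNP map."""
    dose = pd.DataFrame(
        panel.dosages, index=pd.Index(panel.subject_id, name="IID"),
        columns=panel.snp_id,
    )
    dose.to_csv(f"{prefix}.dosage.tsv", sep="\t")
    bim = pd.DataFrame(
        {
            "CHR": panel.chrom,
            "SNP": panel.snp_id,
            "POS": panel.pos,
            "A1": "A",
            "A2": "G",
        }
    )
    bim.to_csv(f"{prefix}.bim.tsv", sep="\t", index=False)


def write_traits(traits: TraitTable, idp_path, cov_path) -> None:
    traits.idps.to_csv(idp_path)
    traits.covariates.to_csv(cov_path)


def write_vcf(panel: GenotypePanel, path) -> None:
    """Minimal VCF 4.2 export with hard GT calls from dosages."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(set(panel.chrom.tolist())):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.subject_id) + "\n"
        )
        for j in range(panel.n_snps):
            calls = "\t".join(gt[int(d)] for d in panel.dosages[:, j])
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j]}\t{panel.snp_id[j]}"
                f"\tG\tA\t.\tPASS\t.\tGT\t{calls}\n"
            )
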