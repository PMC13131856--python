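"""Pipeline driver: simulate -> train -> embed -> reduce/QC -> align ->
association scan / clump -> overlap -> trait annotation.

``RunConfig`` gathers every stage's parameters. The ``paper`` profile records
the full-scale published hyperparameters (temperature 0.07, momentum 0.999,
queue 65,536, 128 components, 5-SD QC, alpha 5e-8/128, r^2 0.1, 250 kb merge,
125 kb pad, 12x6x384 encoder); the ``desk`` profile swaps in sizes that run
on a workstation (32^3 volumes, depth-2 width-64 encoder, queue 1,024,
20 epochs) while keeping every statistical convention identical.

Every run writes a manifest (package version, seeds, per-artifact SHA-256
hashes) sufficient for an exact re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .align import alignment_report
from .contrast import (
    ContrastiveConfig,
    EncoderConfig,
    PatchSpec,
    load_checkpoint,
    save_checkpoint,
    train_contrastive,
)
from .embed import extract_embeddings, outlier_mask, pca_reduce, write_udip_csv
from .genetics import (
    DEFAULT_ALPHA,
    clump_loci,
    gwas_scan,
    overlap_loci,
    write_loci_bed,
    write_sumstats,
)
from .phenoassoc import incremental_r2, phewas_scan
from .simdata import simulate_cohort, write_genotypes, write_traits

log = logging.getLogger("voxalign")

__all__ = ["RunConfig", "run_pipeline", "desk_config", "paper_config"]


@dataclass
class RunConfig:
    # stage toggles
    do_train: bool = True
    do_gwas: bool = True
    do_phewas: bool = True
    checkpoint: str | None = None  # consumed when do_train is False

    # cohort
    n_subjects: int = 200
    n_snps: int = 2000
    n_chrom: int = 2
    d_latent: int = 8
    n_causal: int = 8
    beta_scale: float = 1.0
    latent_noise_sd: float = 0.25
    volume_shape: tuple[int, int, int] = (32, 32, 32)
    smooth_sigma: float = 1.0
    volume_noise_sd: float = 0.5
    q_idps: int = 32
    trait_noise_sd: float = 0.5
    private_fraction: float = 0.0

    # model
    patch_size: tuple[int, int, int] = (8, 8, 8)
    encoder: EncoderConfig = field(
        default_factory=lambda: EncoderConfig(depth=2, heads=4, width=64,
                                              proj_dim=64)
    )
    temperature: float = 0.07
    momentum: float = 0.999
    queue_size: int = 1024
    lr: float = 1e-4
    schedule: tuple[int, int, float] = (10, 2, 1e-6)
    epochs: int = 20
    batch_size: int = 32

    # reduction / QC
    pca_k: int = 32
    joint_fit: bool = True
    qc_z: float = 5.0

    # genetics
    maf_min: float = 0.01
    alpha: float = DEFAULT_ALPHA
    r2_max: float = 0.1
    merge_kb: float = 250.0
    pad_kb: float = 125.0

    # alignment
    n_boot: int = 100

    seed: int = 0

    def contrastive(self) -> ContrastiveConfig:
        return ContrastiveConfig(
            temperature=self.temperature, momentum=self.momentum,
            queue_size=self.queue_size, lr=self.lr, schedule=self.schedule,
            epochs=self.epochs, batch_size=self.batch_size, seed=self.seed,
        )

    def patch_spec(self) -> PatchSpec:
        pad_to = tuple(
            int(np.ceil(s / p) * p)
            for s, p in zip(self.volume_shape, self.patch_size)
        )
        return PatchSpec(self.patch_size, pad_to)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "encoder" in raw:
            raw["encoder"] = EncoderConfig(**raw["encoder"])
        for key in ("volume_shape", "patch_size", "schedule"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def desk_config(seed: int = 0, **overrides) -> RunConfig:
    """Workstation-scale profile (the defaults)."""
    return dataclasses.replace(RunConfig(seed=seed), **overrides)


def paper_config(seed: int = 0) -> RunConfig:
    """Full-scale published hyperparameters; not desk-executable."""
    return RunConfig(
        n_subjects=22_985, n_snps=8_469_833, n_chrom=22,
        volume_shape=(182, 218, 182), patch_size=(14, 16, 14),
        encoder=EncoderConfig(depth=12, heads=6, width=384, proj_dim=256),
        queue_size=65_536, epochs=300, pca_k=128, q_idps=179, seed=seed,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(manifest, name):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.time()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.time() - self.t0
            if exc is None:
                manifest["stages"][name] = {"seconds": round(dt, 2)}
                log.info("stage %s: done in %.1fs", name, dt)
            else:
                manifest["stages"][name] = {"seconds": round(dt, 2),
                                            "error": str(exc)}
                log.error("stage %s: FAILED after %.1fs: %s", name, dt, exc)
            return False

    return _Ctx()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full pipeline; returns a results dict, writes artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": json.loads(json.dumps(config.to_dict(), default=str)),
        "seed": config.seed,
        "stages": {},
        "artifacts": {},
    }
    results: dict = {}

    with _stage(manifest, "simulate"):
        panel, latent, volumes, traits = simulate_cohort(
            n_subjects=config.n_subjects, n_snps=config.n_snps,
            d=config.d_latent, n_causal=config.n_causal,
            beta_scale=config.beta_scale,
            latent_noise_sd=config.latent_noise_sd,
            shape=config.volume_shape, smooth_sigma=config.smooth_sigma,
            volume_noise_sd=config.volume_noise_sd, q_idps=config.q_idps,
            trait_noise_sd=config.trait_noise_sd, n_chrom=config.n_chrom,
            private_fraction=config.private_fraction, seed=config.seed,
        )
        write_genotypes(panel, out / "genotypes")
        write_traits(traits, out / "idps.csv", out / "covariates.csv")

    spec = config.patch_spec()
    enc_cfg = config.encoder
    con_cfg = config.contrastive()

    with _stage(manifest, "train"):
        if config.do_train:
            state, trace = train_contrastive(volumes, enc_cfg, con_cfg, spec)
            save_checkpoint(out / "checkpoint.npz", state, spec, enc_cfg, con_cfg)
        else:
            if not config.checkpoint:
                raise ValueError("do_train=False requires a checkpoint path")
            state, spec, enc_cfg, con_cfg = load_checkpoint(config.checkpoint)
            trace = [float(x) for x in state.loss_trace]
        results["loss_trace"] = trace

    with _stage(manifest, "embed"):
        emb_a = extract_embeddings(state.query_params, volumes, "a", spec, enc_cfg)
        emb_b = extract_embeddings(state.query_params, volumes, "b", spec, enc_cfg)

    with _stage(manifest, "reduce_qc"):
        k = min(config.pca_k, 2 * config.n_subjects - 1)
        udip_a, udip_b = pca_reduce(emb_a, emb_b, k=k, joint_fit=config.joint_fit)
        udip_a = outlier_mask(udip_a, config.qc_z)
        udip_b = outlier_mask(udip_b, config.qc_z)
        write_udip_csv(udip_a, out / "udip_a.csv", out / "udip_a.json")
        write_udip_csv(udip_b, out / "udip_b.csv", out / "udip_b.json")
        results["explained_variance"] = float(
            np.sum(udip_a.explained_variance_ratio)
        )

    with _stage(manifest, "align"):
        report = alignment_report(udip_a, udip_b, n_boot=config.n_boot,
                                  seed=config.seed)
        results["alignment"] = report.to_dict()
        with open(out / "alignment.json", "w") as fh:
            json.dump(results["alignment"], fh, indent=1)

    if config.do_gwas:
        with _stage(manifest, "gwas"):
            cov = traits.covariates.to_numpy()
            summ_a = gwas_scan(panel, udip_a, cov, config.maf_min)
            summ_b = gwas_scan(panel, udip_b, cov, config.maf_min)
            write_sumstats(summ_a, out / "gwas_a")
            write_sumstats(summ_b, out / "gwas_b")

        with _stage(manifest, "clump_overlap"):
            loci_a = clump_loci(summ_a, panel, config.alpha, config.r2_max,
                                config.merge_kb)
            loci_b = clump_loci(summ_b, panel, config.alpha, config.r2_max,
                                config.merge_kb)
            write_loci_bed(loci_a, out / "loci_a.bed", out / "loci_a.json")
            write_loci_bed(loci_b, out / "loci_b.bed", out / "loci_b.json")
            ov, annot = overlap_loci(loci_a, loci_b, config.pad_kb)
            results["loci"] = {
                "n_a": len(loci_a), "n_b": len(loci_b),
                "shared": ov.shared, "unique_a": ov.unique_a,
                "unique_b": ov.unique_b, "total": ov.total,
                "percent_shared": ov.percent_shared,
            }
            with open(out / "overlap.json", "w") as fh:
                json.dump({"summary": results["loci"], "clusters": annot},
                          fh, indent=1)

    if config.do_phewas:
        with _stage(manifest, "phewas"):
            cov = traits.covariates.to_numpy()
            ph = phewas_scan(udip_a, traits.idps.to_numpy(), cov)
            results["phewas"] = {
                "n_significant": ph.n_significant,
                "bonferroni_alpha": ph.bonferroni_alpha,
            }
            inc = [
                incremental_r2(traits.idps.to_numpy()[:, j], udip_a, cov).delta_r2
                for j in range(min(8, traits.idps.shape[1]))
            ]
            results["phewas"]["mean_incremental_r2"] = float(np.mean(inc))
            with open(out / "phewas.json", "w") as fh:
                json.dump(results["phewas"], fh, indent=1)

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["artifacts"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return results
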