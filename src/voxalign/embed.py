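"""Frozen-encoder embedding extraction and latent imaging phenotypes (UDIPs).

After contrastive training the projection head is discarded and the frozen
query encoder produces per-patch embeddings for every subject and modality.
Each subject's (patches x width) embedding matrix is flattened (patch-major,
row-major) to one feature vector, and a single PCA basis — fitted jointly on
the stacked rows of both modalities by default — reduces it to K latent
imaging phenotypes per modality. A per-entry quality-control mask flags
values more than ``z_thresh`` standard deviations from the column mean.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .contrast import EncoderConfig, PatchSpec, encode_patches, tokenize_volume, zscore_volume

__all__ = [
    "EmbeddingTensor",
    "UdipMatrix",
    "extract_embeddings",
    "pca_reduce",
    "outlier_mask",
    "write_udip_csv",
    "read_udip_csv",
]


@dataclass
class EmbeddingTensor:
    subject_id: list[str]
    values: np.ndarray  # (n_subjects, n_patches, width)
    modality: str

    def __post_init__(self):
        if not np.isfinite(self.values).all():
            raise ValueError("embedding tensor contains non-finite values")
        if self.values.shape[0] != len(self.subject_id):
            raise ValueError("subject count mismatch")


@dataclass
class UdipMatrix:
    subject_id: list[str]
    udip: np.ndarray  # (n_subjects, K)
    explained_variance_ratio: np.ndarray
    qc_mask: np.ndarray  # (n_subjects, K) bool; False => excluded downstream
    modality: str
    qc_stats: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.udip.shape[1]

    def masked(self) -> np.ndarray:
        """UDIP values with QC-failing entries replaced by NaN."""
        out = self.udip.astype(float).copy()
        out[~self.qc_mask] = np.nan
        return out


def extract_embeddings(
    query_params: dict[str, np.ndarray],
    cohort,
    modality: str,
    spec: PatchSpec,
    enc_cfg: EncoderConfig,
    normalize: bool = True,
    batch_size: int = 32,
) -> EmbeddingTensor:
    """Apply the frozen encoder (no projection head) to one modality."""
    if modality == "a":
        vols = cohort.vol_a
    elif modality == "b":
        vols = cohort.vol_b
    else:
        raise ValueError("modality must be 'a' or 'b'")
    out = []
    for s in range(0, len(vols), batch_size):
        chunk = vols[s : s + batch_size]
        if normalize:
            chunk = np.stack([zscore_volume(v) for v in chunk])
        tokens = np.stack([tokenize_volume(v, spec)[0] for v in chunk])
        out.append(encode_patches(query_params, tokens, enc_cfg).data)
    values = np.concatenate(out, axis=0)
    return EmbeddingTensor(list(cohort.subject_id), values, modality)


def _flatten(emb: EmbeddingTensor) -> np.ndarray:
    n = emb.values.shape[0]
    return emb.values.reshape(n, -1)  # patch-major then width (row-major)


def pca_reduce(
    emb_a: EmbeddingTensor,
    emb_b: EmbeddingTensor,
    k: int = 128,
    joint_fit: bool = True,
    random_state: int = 0,
) -> tuple[UdipMatrix, UdipMatrix]:
    """Reduce flattened embeddings of both modalities to K components.

    With ``joint_fit`` (default) one PCA basis is fitted on the stacked rows
    of both modalities, placing them in a single coordinate system; with
    ``joint_fit=False`` each modality gets its own basis.
    """
    xa, xb = _flatten(emb_a), _flatten(emb_b)
    if xa.shape[1] != xb.shape[1]:
        raise ValueError("modalities have different feature dimensions")
    n_rows = xa.shape[0] + xb.shape[0]
    if k > min(n_rows - 1, xa.shape[1]):
        raise ValueError(
            f"k={k} exceeds min(total rows - 1, feature count) = "
            f"{min(n_rows - 1, xa.shape[1])}"
        )
    if joint_fit:
        stack = np.vstack([xa, xb])
        pca = PCA(n_components=k, svd_solver="auto", random_state=random_state)
        pca.fit(stack)
        sa = pca.transform(xa)
        sb = pca.transform(xb)
        evr_a = evr_b = pca.explained_variance_ratio_.copy()
    else:
        pa = PCA(n_components=min(k, xa.shape[0] - 1), random_state=random_state)
        pb = PCA(n_components=min(k, xb.shape[0] - 1), random_state=random_state)
        sa = pa.fit_transform(xa)
        sb = pb.fit_transform(xb)
        evr_a, evr_b = pa.explained_variance_ratio_, pb.explained_variance_ratio_

    def mk(emb, scores, evr):
        mask = np.ones(scores.shape, dtype=bool)
        return UdipMatrix(list(emb.subject_id), scores, evr, mask, emb.modality)

    return mk(emb_a, sa, evr_a), mk(emb_b, sb, evr_b)


def outlier_mask(udips: UdipMatrix, z_thresh: float = 5.0) -> UdipMatrix:
    """Flag entries beyond ``z_thresh`` SDs of their column (strict >).

    Column statistics are computed once on the unmasked data and cached on
    the result, so re-applying the same threshold is idempotent.
    """
    if z_thresh <= 0:
        raise ValueError("z_thresh must be positive")
    if udips.qc_stats:
        mu = udips.qc_stats["mean"]
        sd = udips.qc_stats["sd"]
    else:
        mu = udips.udip.mean(axis=0)
        sd = udips.udip.std(axis=0)
    mask = np.ones(udips.udip.shape, dtype=bool)
    zero_sd = sd == 0
    if zero_sd.any():
        warnings.warn(
            f"{int(zero_sd.sum())} zero-variance UDIP column(s); not masked"
        )
    ok = ~zero_sd
    dev = np.abs(udips.udip[:, ok] - mu[ok])
    mask[:, ok] = dev <= z_thresh * sd[ok]
    return UdipMatrix(
        udips.subject_id, udips.udip, udips.explained_variance_ratio,
        mask, udips.modality, qc_stats={"mean": mu, "sd": sd},
    )


# -- plain-text I/O ---------------------------------------------------------


def write_udip_csv(udips: UdipMatrix, path, sidecar_path=None) -> None:
    """CSV with header IID,UDIP_0,... ; masked entries written empty."""
    df = pd.DataFrame(
        udips.masked(),
        index=pd.Index(udips.subject_id, name="IID"),
        columns=[f"UDIP_{j}" for j in range(udips.k)],
    )
    df.to_csv(path)
    if sidecar_path is not None:
        meta = {
            "modality": udips.modality,
            "k": udips.k,
            "explained_variance_ratio":
                np.asarray(udips.explained_variance_ratio, dtype=float).tolist(),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=1)


def read_udip_csv(path, modality: str = "") -> UdipMatrix:
    df = pd.read_csv(path, index_col="IID")
    values = df.to_numpy(dtype=float)
    mask = np.isfinite(values)
    values = np.where(mask, values, 0.0)
    evr = np.full(values.shape[1], np.nan)
    return UdipMatrix(
        [str(i) for i in df.index], values, evr, mask, modality
    )
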