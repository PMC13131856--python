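"""Volumetric vision-transformer encoder with a contrastive projection head.

The encoder maps a matrix of flattened non-overlapping patches to per-patch
embeddings: linear patch projection, learned positional encoding, a stack of
pre-norm transformer blocks (multi-head self-attention + GELU MLP), and a
final layer norm. The projection head (mean pool -> 2-layer MLP -> L2
normalization) produces the unit-norm vector used in the contrastive loss;
it is dropped at embedding-extraction time.

Parameters live in a flat ``dict[str, Tensor]`` so the momentum update and
the optimizer can treat them uniformly.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, gelu, layer_norm, relu, softmax

__all__ = [
    "init_encoder_params",
    "encode_patches",
    "pool_project",
    "params_copy",
    "params_astensors",
]


def init_encoder_params(
    patch_voxels: int,
    n_patches: int,
    width: int,
    depth: int,
    heads: int,
    proj_dim: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Glorot-style initialization of every parameter tensor."""
    if width % heads != 0:
        raise ValueError(f"width {width} not divisible by heads {heads}")

    def lin(fan_in, fan_out):
        s = np.sqrt(2.0 / (fan_in + fan_out))
        return rng.normal(0.0, s, size=(fan_in, fan_out)).astype(np.float32)

    p: dict[str, np.ndarray] = {
        "patch_W": lin(patch_voxels, width),
        "patch_b": np.zeros(width, dtype=np.float32),
        "pos": (0.02 * rng.standard_normal((n_patches, width))).astype(np.float32),
    }
    for i in range(depth):
        p[f"blk{i}.ln1_g"] = np.ones(width, dtype=np.float32)
        p[f"blk{i}.ln1_b"] = np.zeros(width, dtype=np.float32)
        p[f"blk{i}.qkv_W"] = lin(width, 3 * width)
        p[f"blk{i}.qkv_b"] = np.zeros(3 * width, dtype=np.float32)
        p[f"blk{i}.proj_W"] = lin(width, width)
        p[f"blk{i}.proj_b"] = np.zeros(width, dtype=np.float32)
        p[f"blk{i}.ln2_g"] = np.ones(width, dtype=np.float32)
        p[f"blk{i}.ln2_b"] = np.zeros(width, dtype=np.float32)
        p[f"blk{i}.mlp1_W"] = lin(width, 4 * width)
        p[f"blk{i}.mlp1_b"] = np.zeros(4 * width, dtype=np.float32)
        p[f"blk{i}.mlp2_W"] = lin(4 * width, width)
        p[f"blk{i}.mlp2_b"] = np.zeros(width, dtype=np.float32)
    p["lnf_g"] = np.ones(width, dtype=np.float32)
    p["lnf_b"] = np.zeros(width, dtype=np.float32)
    p["head1_W"] = lin(width, width)
    p["head1_b"] = np.zeros(width, dtype=np.float32)
    p["head2_W"] = lin(width, proj_dim)
    p["head2_b"] = np.zeros(proj_dim, dtype=np.float32)
    return p


def params_copy(params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: v.copy() for k, v in params.items()}


def params_astensors(
    params: dict[str, np.ndarray], requires_grad: bool
) -> dict[str, Tensor]:
    return {k: Tensor(v, requires_grad=requires_grad) for k, v in params.items()}


def _infer_depth(params) -> int:
    d = 0
    while f"blk{d}.ln1_g" in params:
        d += 1
    return d


def _attention(x: Tensor, P: dict[str, Tensor], i: int, heads: int) -> Tensor:
    B, n, width = x.shape
    dh = width // heads
    qkv = x @ P[f"blk{i}.qkv_W"] + P[f"blk{i}.qkv_b"]  # (B, n, 3*width)
    qkv = qkv.reshape(B, n, 3, heads, dh).swapaxes(1, 3)  # (B, heads, 3, n, dh)
    q, k, v = qkv[:, :, 0], qkv[:, :, 1], qkv[:, :, 2]
    att = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))  # (B, heads, n, n)
    att = softmax(att, axis=-1)
    out = att @ v  # (B, heads, n, dh)
    out = out.swapaxes(1, 2).reshape(B, n, width)
    return out @ P[f"blk{i}.proj_W"] + P[f"blk{i}.proj_b"]


def encode_patches(
    params: dict[str, Tensor] | dict[str, np.ndarray],
    tokens,
    heads: int,
    use_positional: bool = True,
) -> Tensor:
    """Run the encoder on flattened patch tokens.

    ``tokens`` is (n_patches, patch_voxels) for one volume or
    (batch, n_patches, patch_voxels) for a batch; the result carries the same
    leading shape with the last axis replaced by ``width``.
    """
    P = {
        k: (v if isinstance(v, Tensor) else Tensor(v)) for k, v in params.items()
    }
    t = tokens if isinstance(tokens, Tensor) else Tensor(tokens)
    single = t.ndim == 2
    if single:
        t = t.reshape(1, *t.shape)
    if t.shape[-1] != P["patch_W"].shape[0]:
        raise ValueError(
            f"token width {t.shape[-1]} does not match patch projection "
            f"input {P['patch_W'].shape[0]}"
        )
    if t.shape[1] != P["pos"].shape[0]:
        raise ValueError(
            f"{t.shape[1]} patches but positional encoding has {P['pos'].shape[0]}"
        )
    x = t @ P["patch_W"] + P["patch_b"]
    if use_positional:
        x = x + P["pos"]
    for i in range(_infer_depth(P)):
        h = layer_norm(x, P[f"blk{i}.ln1_g"], P[f"blk{i}.ln1_b"])
        x = x + _attention(h, P, i, heads)
        h = layer_norm(x, P[f"blk{i}.ln2_g"], P[f"blk{i}.ln2_b"])
        h = gelu(h @ P[f"blk{i}.mlp1_W"] + P[f"blk{i}.mlp1_b"])
        x = x + (h @ P[f"blk{i}.mlp2_W"] + P[f"blk{i}.mlp2_b"])
    x = layer_norm(x, P["lnf_g"], P["lnf_b"])
    return x.reshape(*x.shape[1:]) if single else x


def pool_project(
    params: dict[str, Tensor] | dict[str, np.ndarray], patch_embs
) -> Tensor:
    """Mean-pool patch embeddings and project to the unit hypersphere."""
    P = {
        k: (v if isinstance(v, Tensor) else Tensor(v)) for k, v in params.items()
    }
    x = patch_embs if isinstance(patch_embs, Tensor) else Tensor(patch_embs)
    single = x.ndim == 2
    if single:
        x = x.reshape(1, *x.shape)
    pooled = x.mean(axis=1)  # (B, width)
    h = relu(pooled @ P["head1_W"] + P["head1_b"])
    z = h @ P["head2_W"] + P["head2_b"]
    sq = (z * z).sum(axis=-1, keepdims=True)
    if np.any(sq.data < 1e-12):
        raise FloatingPointError(
            "projection produced a (near-)zero vector; cannot L2-normalize"
        )
    out = z * sq.pow(-0.5)
    return out.reshape(*out.shape[1:]) if single else out
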