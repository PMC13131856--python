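"""Symmetric multimodal momentum-contrast training.

Two volumetric transformer encoders (query and key) are initialized with
identical weights. Each training step forms cross-modal positive pairs: the
query encoder embeds one modality, the key encoder embeds the paired
modality of the same subject, and all entries of a FIFO queue of past key
embeddings serve as negatives in an InfoNCE loss. The objective is
symmetric — both modalities take the query role and the two directional
losses are averaged — so neither modality is privileged. After each step
the key encoder is updated as an exponential moving average of the query
encoder, and the fresh key embeddings are enqueued.

Negatives are drawn from the queue matching the key's modality (one queue
per modality), so the loss cannot be solved by trivial modality
discrimination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .nn.autograd import Tensor, concat, logsumexp
from .nn.optim import AdamW, cosine_warm_restarts
from .nn.vit import (
    encode_patches as _encode,
    init_encoder_params,
    params_astensors,
    params_copy,
    pool_project as _pool_project,
)

__all__ = [
    "PatchSpec",
    "EncoderConfig",
    "ContrastiveConfig",
    "ContrastiveState",
    "tokenize_volume",
    "detokenize_volume",
    "encode_patches",
    "pool_project",
    "info_nce",
    "momentum_update",
    "symmetric_step",
    "train_contrastive",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class PatchSpec:
    """Non-overlapping patch tiling of a zero-padded volume."""

    patch_size: tuple[int, int, int]
    pad_to: tuple[int, int, int]

    def __post_init__(self):
        for t, p in zip(self.pad_to, self.patch_size):
            if p <= 0 or t <= 0:
                raise ValueError("patch_size and pad_to must be positive")
            if t % p != 0:
                raise ValueError(
                    f"pad_to {self.pad_to} not divisible by patch {self.patch_size}"
                )

    @property
    def grid(self) -> tuple[int, int, int]:
        return tuple(t // p for t, p in zip(self.pad_to, self.patch_size))

    @property
    def n_patches(self) -> int:
        return int(np.prod(self.grid))

    @property
    def patch_voxels(self) -> int:
        return int(np.prod(self.patch_size))


@dataclass(frozen=True)
class EncoderConfig:
    depth: int = 12
    heads: int = 6
    width: int = 384
    proj_dim: int = 256

    def __post_init__(self):
        if min(self.depth, self.heads, self.width, self.proj_dim) <= 0:
            raise ValueError("all encoder dimensions must be positive")
        if self.width % self.heads != 0:
            raise ValueError("width must be divisible by heads")


@dataclass(frozen=True)
class ContrastiveConfig:
    temperature: float = 0.07
    momentum: float = 0.999
    queue_size: int = 65_536
    lr: float = 1e-4
    schedule: tuple[int, int, float] = (10, 2, 1e-6)
    epochs: int = 300
    batch_size: int = 32
    weight_decay: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not (0.0 <= self.momentum <= 1.0):
            raise ValueError("momentum must lie in [0, 1]")
        if self.queue_size < self.batch_size:
            raise ValueError("queue_size must be at least batch_size")


@dataclass
class ContrastiveState:
    query_params: dict[str, np.ndarray]
    key_params: dict[str, np.ndarray]
    queue_a: np.ndarray  # (K, proj_dim), unit-norm rows
    queue_b: np.ndarray
    ptr_a: int = 0
    ptr_b: int = 0
    step: int = 0
    loss_trace: list = field(default_factory=list)


# -- tokenization ----------------------------------------------------------


def tokenize_volume(volume: np.ndarray, spec: PatchSpec):
    """Zero-pad a volume to ``spec.pad_to`` and tile it into patch tokens.

    Padding is symmetric with the extra voxel on the high side when the
    remainder is odd. Patches are enumerated with the first (x) grid axis
    varying fastest; each token is the C-order flattening of one patch.
    Returns ``(tokens, grid)`` with tokens of shape (n_patches, patch_voxels).
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("expected a 3D volume")
    for v, t in zip(volume.shape, spec.pad_to):
        if v > t:
            raise ValueError(f"volume shape {volume.shape} exceeds pad_to {spec.pad_to}")
    pads = []
    for v, t in zip(volume.shape, spec.pad_to):
        extra = t - v
        pads.append((extra // 2, extra - extra // 2))
    vol = np.pad(volume, pads) if any(sum(p) for p in pads) else volume
    gx, gy, gz = spec.grid
    px, py, pz = spec.patch_size
    # (gx,px,gy,py,gz,pz) -> patch grid in (z,y,x) C-order => x fastest
    tok = (
        vol.reshape(gx, px, gy, py, gz, pz)
        .transpose(4, 2, 0, 1, 3, 5)
        .reshape(spec.n_patches, spec.patch_voxels)
    )
    return np.ascontiguousarray(tok), spec.grid


def detokenize_volume(tokens: np.ndarray, spec: PatchSpec) -> np.ndarray:
    """Inverse of :func:`tokenize_volume` (returns the padded volume)."""
    gx, gy, gz = spec.grid
    px, py, pz = spec.patch_size
    vol = (
        np.asarray(tokens)
        .reshape(gz, gy, gx, px, py, pz)
        .transpose(2, 3, 1, 4, 0, 5)
        .reshape(gx * px, gy * py, gz * pz)
    )
    return vol


def zscore_volume(volume: np.ndarray) -> np.ndarray:
    """Per-scan intensity standardization (zero mean, unit variance)."""
    v = np.asarray(volume, dtype=np.float32)
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


# -- encoder wrappers ------------------------------------------------------


def encode_patches(params, tokens, cfg: EncoderConfig):
    """Per-patch embeddings (n_patches x width); deterministic in inference."""
    return _encode(params, tokens, heads=cfg.heads)


def pool_project(params, patch_embs):
    """Mean-pool over patches, project, L2-normalize."""
    return _pool_project(params, patch_embs)


# -- the contrastive objective ---------------------------------------------


def _check_unit(x: np.ndarray, what: str, tol: float = 1e-3) -> None:
    norms = np.linalg.norm(x, axis=-1)
    if np.any(np.abs(norms - 1.0) > tol):
        raise ValueError(f"{what} must be unit-norm (max deviation "
                         f"{np.abs(norms - 1.0).max():.2e})")


def info_nce(q, k_pos, negatives, temperature: float = 0.07):
    """InfoNCE loss with one positive and a bank of negatives.

    ``q`` may be a Tensor (gradients flow through it) or an array;
    ``k_pos`` and ``negatives`` are treated as constants. Accepts a single
    vector or a batch; returns the scalar mean loss (Tensor if q is one).
    loss = -log[ exp(q.k+/t) / (exp(q.k+/t) + sum_j exp(q.k-_j/t)) ],
    computed with log-sum-exp stabilization.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    qt = q if isinstance(q, Tensor) else Tensor(np.asarray(q))
    # keys are constants; double precision keeps the log-sum-exp exact
    k_pos = np.asarray(k_pos, dtype=np.float64)
    negatives = np.asarray(negatives, dtype=np.float64)
    single = qt.ndim == 1
    if single:
        qt = qt.reshape(1, -1)
        k_pos = k_pos.reshape(1, -1)
    _check_unit(qt.data, "query")
    _check_unit(k_pos, "positive key")
    _check_unit(negatives, "negatives")
    inv_t = 1.0 / float(temperature)
    l_pos = (qt * Tensor(k_pos)).sum(axis=-1, keepdims=True) * inv_t  # (B,1)
    l_neg = (qt @ Tensor(negatives.T)) * inv_t  # (B,K)
    logits = concat([l_pos, l_neg], axis=-1)
    losses = logsumexp(logits, axis=-1) - logits[:, 0]
    return losses.mean()


def momentum_update(
    key_params: dict[str, np.ndarray],
    query_params: dict[str, np.ndarray],
    m: float,
) -> dict[str, np.ndarray]:
    """Exponential moving average: theta_k <- m*theta_k + (1-m)*theta_q."""
    if set(key_params) != set(query_params):
        raise ValueError("parameter sets are not congruent")
    out = {}
    for k, kv in key_params.items():
        qv = query_params[k]
        if kv.shape != qv.shape:
            raise ValueError(f"shape mismatch for parameter {k!r}")
        out[k] = (m * kv + (1.0 - m) * qv).astype(np.float32)
    return out


def _enqueue(queue: np.ndarray, ptr: int, rows: np.ndarray) -> int:
    """FIFO ring-buffer insert; returns the new write pointer."""
    K = queue.shape[0]
    B = rows.shape[0]
    if B > K:
        raise ValueError(f"batch of {B} larger than queue of {K}")
    end = ptr + B
    if end <= K:
        queue[ptr:end] = rows
    else:
        first = K - ptr
        queue[ptr:] = rows[:first]
        queue[: end - K] = rows[first:]
    return end % K


def _as_tokens(batch: np.ndarray, spec: PatchSpec) -> np.ndarray:
    batch = np.asarray(batch, dtype=np.float32)
    if batch.ndim == 4:  # (B, x, y, z) volumes
        return np.stack([tokenize_volume(v, spec)[0] for v in batch])
    if batch.ndim == 3:  # already tokenized (B, P, V)
        return batch
    raise ValueError("batch must be (B,x,y,z) volumes or (B,P,V) tokens")


def symmetric_step(
    batch_a,
    batch_b,
    state: ContrastiveState,
    enc_cfg: EncoderConfig,
    con_cfg: ContrastiveConfig,
    spec: PatchSpec,
    optimizer: AdamW | None = None,
    modality_a: str = "a",
    modality_b: str = "b",
):
    """One symmetric training step; returns (loss, state) with state mutated.

    ``batch_a[i]`` and ``batch_b[i]`` are the two modality views of subject
    i; ``modality_a``/``modality_b`` tag which per-modality queue each batch
    belongs to, so the objective is invariant to argument order. Gradients
    flow only through the query-encoder path; key embeddings are computed
    without gradient and enqueued afterwards.
    """
    if {modality_a, modality_b} != {"a", "b"}:
        raise ValueError("modality tags must be 'a' and 'b' in some order")
    tok_a = _as_tokens(batch_a, spec)
    tok_b = _as_tokens(batch_b, spec)
    if tok_a.shape[0] != tok_b.shape[0]:
        raise ValueError("modality batches must pair the same subjects")
    if tok_a.shape[0] > state.queue_a.shape[0]:
        raise ValueError("batch larger than queue")
    queues = {"a": state.queue_a, "b": state.queue_b}
    ptrs = {"a": state.ptr_a, "b": state.ptr_b}

    qp = params_astensors(state.query_params, requires_grad=True)
    # key path: no gradient
    k_first = pool_project(
        state.key_params, encode_patches(state.key_params, tok_b, enc_cfg)
    ).data
    k_second = pool_project(
        state.key_params, encode_patches(state.key_params, tok_a, enc_cfg)
    ).data

    q_first = pool_project(qp, encode_patches(qp, tok_a, enc_cfg))
    q_second = pool_project(qp, encode_patches(qp, tok_b, enc_cfg))

    loss_ab = info_nce(q_first, k_first, queues[modality_b], con_cfg.temperature)
    loss_ba = info_nce(q_second, k_second, queues[modality_a], con_cfg.temperature)
    loss = (loss_ab + loss_ba) * 0.5
    loss_val = float(loss.data)

    loss.backward()
    grads = {k: t.grad for k, t in qp.items() if t.grad is not None}
    if optimizer is not None:
        optimizer.step(grads)
    state.key_params = momentum_update(
        state.key_params, state.query_params, con_cfg.momentum
    )
    ptrs[modality_b] = _enqueue(queues[modality_b], ptrs[modality_b], k_first)
    ptrs[modality_a] = _enqueue(queues[modality_a], ptrs[modality_a], k_second)
    state.ptr_a, state.ptr_b = ptrs["a"], ptrs["b"]
    state.step += 1
    state.loss_trace.append(loss_val)
    return loss_val, state


def init_state(
    spec: PatchSpec, enc_cfg: EncoderConfig, con_cfg: ContrastiveConfig
) -> ContrastiveState:
    """Fresh query/key parameters (identical) and random unit-vector queues."""
    rng = np.random.default_rng(con_cfg.seed)
    qp = init_encoder_params(
        spec.patch_voxels, spec.n_patches, enc_cfg.width, enc_cfg.depth,
        enc_cfg.heads, enc_cfg.proj_dim, rng,
    )

    def rand_queue():
        q = rng.standard_normal((con_cfg.queue_size, enc_cfg.proj_dim))
        return (q / np.linalg.norm(q, axis=1, keepdims=True)).astype(np.float32)

    return ContrastiveState(
        query_params=qp,
        key_params=params_copy(qp),
        queue_a=rand_queue(),
        queue_b=rand_queue(),
    )


def train_contrastive(
    cohort,
    enc_cfg: EncoderConfig,
    con_cfg: ContrastiveConfig,
    spec: PatchSpec | None = None,
    normalize: bool = True,
):
    """Train the symmetric contrastive model on a paired-volume cohort.

    Returns ``(state, epoch_loss_trace)``; ``state.query_params`` holds the
    trained encoder. Fully reproducible given ``con_cfg.seed``.
    """
    n = len(cohort.subject_id)
    if n == 0:
        raise ValueError("empty cohort")
    if n < 2:
        raise ValueError("need at least 2 subjects for contrastive training")
    if spec is None:
        pad_to = tuple(
            int(np.ceil(s / 8) * 8) for s in cohort.shape
        )
        spec = PatchSpec(patch_size=(8, 8, 8), pad_to=pad_to)
    vols_a = cohort.vol_a
    vols_b = cohort.vol_b
    if normalize:
        vols_a = np.stack([zscore_volume(v) for v in vols_a])
        vols_b = np.stack([zscore_volume(v) for v in vols_b])
    tok_a = np.stack([tokenize_volume(v, spec)[0] for v in vols_a])
    tok_b = np.stack([tokenize_volume(v, spec)[0] for v in vols_b])

    state = init_state(spec, enc_cfg, con_cfg)
    if con_cfg.epochs == 0:
        return state, []
    opt = AdamW(state.query_params, lr=con_cfg.lr,
                weight_decay=con_cfg.weight_decay)
    t0, t_mult, eta_min = con_cfg.schedule
    rng = np.random.default_rng(np.random.SeedSequence([con_cfg.seed, 7]))
    B = con_cfg.batch_size
    trace = []
    steps_per_epoch = max(1, int(np.ceil(n / B)))
    for epoch in range(con_cfg.epochs):
        perm = rng.permutation(n)
        losses = []
        for s in range(steps_per_epoch):
            idx = perm[s * B : (s + 1) * B]
            if idx.size == 0:
                continue
            opt.lr = cosine_warm_restarts(
                epoch + s / steps_per_epoch, con_cfg.lr, t0, t_mult, eta_min
            )
            lv, state = symmetric_step(
                tok_a[idx], tok_b[idx], state, enc_cfg, con_cfg, spec,
                optimizer=opt,
            )
            losses.append(lv)
        trace.append(float(np.mean(losses)))
    return state, trace


# -- checkpointing ---------------------------------------------------------


def save_checkpoint(path, state: ContrastiveState, spec: PatchSpec,
                    enc_cfg: EncoderConfig, con_cfg: ContrastiveConfig) -> None:
    meta = {
        "version": CHECKPOINT_VERSION,
        "patch_size": list(spec.patch_size),
        "pad_to": list(spec.pad_to),
        "encoder": enc_cfg.__dict__,
        "contrastive": {**con_cfg.__dict__, "schedule": list(con_cfg.schedule)},
        "step": state.step,
        "ptr_a": state.ptr_a,
        "ptr_b": state.ptr_b,
    }
    arrays = {f"query.{k}": v for k, v in state.query_params.items()}
    arrays.update({f"key.{k}": v for k, v in state.key_params.items()})
    arrays["queue_a"] = state.queue_a
    arrays["queue_b"] = state.queue_b
    arrays["loss_trace"] = np.asarray(state.loss_trace, dtype=np.float64)
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path):
    """Returns (state, spec, enc_cfg, con_cfg)."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        qp = {k[6:]: z[k] for k in z.files if k.startswith("query.")}
        kp = {k[4:]: z[k] for k in z.files if k.startswith("key.")}
        state = ContrastiveState(
            query_params=qp, key_params=kp,
            queue_a=z["queue_a"], queue_b=z["queue_b"],
            ptr_a=int(meta["ptr_a"]), ptr_b=int(meta["ptr_b"]),
            step=int(meta["step"]),
            loss_trace=list(z["loss_trace"]),
        )
    spec = PatchSpec(tuple(meta["patch_size"]), tuple(meta["pad_to"]))
    enc_cfg = EncoderConfig(**meta["encoder"])
    cc = dict(meta["contrastive"])
    cc["schedule"] = tuple(cc["schedule"])
    con_cfg = ContrastiveConfig(**cc)
    return state, spec, enc_cfg, con_cfg
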