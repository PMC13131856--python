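"""Cross-modal representation alignment: linear CKA and CCA.

Linear centered kernel alignment (CKA) is the cosine similarity between the
centered Gram matrices of two representations, computed here in the
equivalent feature-space form ||Yc'Xc||_F^2 / (||Xc'Xc||_F ||Yc'Yc||_F).
It is invariant to orthogonal rotation, translation, and isotropic scaling
of either representation and lies in [0, 1].

Bootstrap resampling of matched subjects gives a positive-pair (same
subject, different modality) distribution; derangement-style permutations of
the subject assignment give the negative-pair (different subject) null.

Canonical correlation analysis (CCA) finds paired linear projections of the
two feature sets maximizing successive correlations; both sides are
standardized first and the canonical correlations are summarized by mean,
max, and threshold counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AlignmentReport",
    "linear_cka",
    "cka_bootstrap",
    "cca_fit",
    "cca_summary",
    "alignment_report",
]


@dataclass
class AlignmentReport:
    cka_pos_mean: float
    cka_pos_sd: float
    cka_pos_samples: np.ndarray
    cka_neg_mean: float
    cka_neg_sd: float
    cka_neg_samples: np.ndarray
    cca_rho: np.ndarray
    cca_summary: dict
    n_subjects_used: int

    def to_dict(self) -> dict:
        return {
            "cka_pos": {"mean": self.cka_pos_mean, "sd": self.cka_pos_sd},
            "cka_neg": {"mean": self.cka_neg_mean, "sd": self.cka_neg_sd},
            "cca_rho": np.asarray(self.cca_rho, dtype=float).tolist(),
            "cca_summary": self.cca_summary,
            "n_subjects_used": self.n_subjects_used,
        }


def _complete_rows(X: np.ndarray, Y: np.ndarray):
    keep = np.isfinite(X).all(axis=1) & np.isfinite(Y).all(axis=1)
    return X[keep], Y[keep]


def linear_cka(X: np.ndarray, Y: np.ndarray) -> float:
    """Linear CKA between paired representations (rows = subjects)."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2D with the same number of rows")
    X, Y = _complete_rows(X, Y)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 complete paired rows")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    nx = np.linalg.norm(Xc.T @ Xc)
    ny = np.linalg.norm(Yc.T @ Yc)
    if nx == 0 or ny == 0:
        raise ValueError("zero-variance input: all rows identical")
    return float(np.linalg.norm(Yc.T @ Xc) ** 2 / (nx * ny))


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish permutation with no fixed points (redraw on self-match)."""
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def cka_bootstrap(
    udip_a, udip_b, n_boot: int = 100, seed: int = 0
) -> tuple[dict, dict]:
    """Positive (bootstrap) and negative (permutation) CKA distributions.

    Accepts UdipMatrix objects (masked entries excluded row-wise) or plain
    arrays with rows paired by subject.
    """
    A = udip_a.masked() if hasattr(udip_a, "masked") else np.asarray(udip_a, float)
    B = udip_b.masked() if hasattr(udip_b, "masked") else np.asarray(udip_b, float)
    if hasattr(udip_a, "subject_id") and hasattr(udip_b, "subject_id"):
        if list(udip_a.subject_id) != list(udip_b.subject_id):
            raise ValueError("subject IDs do not match between modalities")
    A, B = _complete_rows(A, B)
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 complete subjects")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    pos = np.empty(n_boot)
    neg = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        pos[i] = linear_cka(A[idx], B[idx])
    for i in range(n_boot):
        perm = _derangement(n, rng)
        neg[i] = linear_cka(A, B[perm])
    mk = lambda s: {"mean": float(s.mean()), "sd": float(s.std(ddof=1)),
                    "samples": s}
    return mk(pos), mk(neg)


def cca_fit(X: np.ndarray, Y: np.ndarray):
    """Canonical correlations and per-subject canonical scores.

    Columns of both sides are standardized; the number of components is
    min(n - 1, min(p, q)), reduced with a warning under rank deficiency.
    Returns ``(rho, scores_x, scores_y)`` with rho sorted non-increasing.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    X, Y = _complete_rows(X, Y)
    n, p = X.shape
    q = Y.shape[1]
    if n < 3:
        raise ValueError("need at least 3 complete rows")
    if n < 5 * max(p, q):
        warnings.warn(
            "n < 5*max(p, q): unregularized in-sample canonical correlations "
            "are inflated", stacklevel=2,
        )

    def std(M):
        mu = M.mean(axis=0)
        sd = M.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return (M - mu) / sd

    Xs, Ys = std(X), std(Y)
    n_comp = min(n - 1, min(p, q))

    def whiten(M):
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        tol = s.max() * max(M.shape) * np.finfo(float).eps if s.size else 0.0
        r = int((s > tol).sum())
        return U[:, :r], r

    Ux, rx = whiten(Xs)
    Uy, ry = whiten(Ys)
    eff = min(n_comp, rx, ry)
    if eff < n_comp:
        warnings.warn(
            f"rank deficiency: reducing components from {n_comp} to {eff}",
            stacklevel=2,
        )
    Uc, s, Vct = np.linalg.svd(Ux.T @ Uy, full_matrices=False)
    rho = np.clip(s[:eff], 0.0, 1.0)
    scores_x = Ux @ Uc[:, :eff] * np.sqrt(n - 1)
    scores_y = Uy @ Vct.T[:, :eff] * np.sqrt(n - 1)
    return rho, scores_x, scores_y


def cca_summary(rho) -> dict:
    """Mean, max, strict threshold counts, and the bar-profile mean (AUC)."""
    rho = np.asarray(rho, dtype=float)
    if rho.size == 0:
        raise ValueError("rho vector is empty")
    return {
        "mean": float(rho.mean()),
        "max": float(rho.max()),
        "n_gt_0.3": int((rho > 0.3).sum()),
        "n_gt_0.5": int((rho > 0.5).sum()),
        "auc": float(rho.mean()),
        "n_components": int(rho.size),
    }


def alignment_report(
    udip_a, udip_b, n_boot: int = 100, seed: int = 0
) -> AlignmentReport:
    """Full feature-level alignment report for two UDIP matrices."""
    pos, neg = cka_bootstrap(udip_a, udip_b, n_boot=n_boot, seed=seed)
    A = udip_a.masked() if hasattr(udip_a, "masked") else np.asarray(udip_a, float)
    B = udip_b.masked() if hasattr(udip_b, "masked") else np.asarray(udip_b, float)
    A, B = _complete_rows(A, B)
    rho, _, _ = cca_fit(A, B)
    return AlignmentReport(
        cka_pos_mean=pos["mean"], cka_pos_sd=pos["sd"],
        cka_pos_samples=pos["samples"],
        cka_neg_mean=neg["mean"], cka_neg_sd=neg["sd"],
        cka_neg_samples=neg["samples"],
        cca_rho=rho, cca_summary=cca_summary(rho),
        n_subjects_used=A.shape[0],
    )
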