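"""Phenotype annotation of latent imaging phenotypes.

Three analyses interpret UDIPs against conventional traits:

* ``phewas_scan`` — one linear regression per (UDIP, trait) pair with the
  trait as dependent variable and covariates entered directly, Bonferroni
  threshold computed from the tested matrix dimensions;
* ``incremental_r2`` — variance in a trait explained by the full UDIP block
  beyond covariates alone, with a partial (omnibus) F-test;
* ``cca_component_assoc`` — per canonical component, the strong-association
  tail (a percentile of -log10 p over traits) of trait regressions on the
  component score.

Masked UDIP entries are handled pairwise-complete; each pair's effective n
is reported. P-values are floored at 1e-300 to keep -log10 finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PhewasResult",
    "IncrementalFit",
    "phewas_scan",
    "incremental_r2",
    "cca_component_assoc",
]

P_FLOOR = 1e-300


@dataclass
class PhewasResult:
    p: np.ndarray        # (n_udips, n_traits)
    beta: np.ndarray
    se: np.ndarray
    n: np.ndarray        # effective sample size per pair
    bonferroni_alpha: float

    @property
    def n_significant(self) -> int:
        return int((self.p < self.bonferroni_alpha).sum())


@dataclass
class IncrementalFit:
    r2_cov: float
    r2_full: float
    delta_r2: float
    f_stat: float
    df1: int
    df2: int
    p: float


def _as_matrix(x) -> np.ndarray:
    m = np.asarray(x.to_numpy() if hasattr(x, "to_numpy") else x, dtype=np.float64)
    return m[:, None] if m.ndim == 1 else m


def _drop_collinear(C: np.ndarray) -> np.ndarray:
    """Drop covariate columns that add nothing to the column space."""
    keep = []
    for j in range(C.shape[1]):
        trial = C[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear covariate column {j}")
    return C[:, keep]


def _ols_scan(x: np.ndarray, Y: np.ndarray, C: np.ndarray):
    """Regress each column of Y on [1, x, C]; stats for the x coefficient."""
    n = x.shape[0]
    X = np.column_stack([np.ones(n), x, C])
    pdim = X.shape[1]
    if n <= pdim:
        raise ValueError("more parameters than observations")
    XtX = X.T @ X
    XtXi = np.linalg.pinv(XtX)
    B = XtXi @ (X.T @ Y)
    resid = Y - X @ B
    dof = n - pdim
    sigma2 = (resid ** 2).sum(axis=0) / dof
    var_b = sigma2 * XtXi[1, 1]
    se = np.sqrt(var_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = B[1] / se
    p = np.clip(2.0 * stats.t.sf(np.abs(t), dof), P_FLOOR, 1.0)
    return B[1], se, p


def phewas_scan(udips, traits, covariates=None) -> PhewasResult:
    """Trait ~ UDIP + covariates for every (UDIP, trait) pair."""
    U = udips.masked() if hasattr(udips, "masked") else _as_matrix(udips)
    T = _as_matrix(traits)
    if U.shape[0] != T.shape[0]:
        raise ValueError("UDIPs and traits must share subjects (row-aligned)")
    n, K = U.shape
    q = T.shape[1]
    C = _as_matrix(covariates) if covariates is not None else np.empty((n, 0))
    if C.shape[1]:
        C = _drop_collinear(C)
    beta = np.full((K, q), np.nan)
    se = np.full((K, q), np.nan)
    p = np.ones((K, q))
    n_eff = np.zeros((K, q), dtype=int)
    trait_ok = np.isfinite(T)
    for k in range(K):
        rows_u = np.isfinite(U[:, k])
        # group traits by their missingness pattern restricted to rows_u
        patterns: dict[bytes, list[int]] = {}
        for j in range(q):
            patterns.setdefault((rows_u & trait_ok[:, j]).tobytes(), []).append(j)
        for pat, cols in patterns.items():
            rows = np.frombuffer(pat, dtype=bool)
            if rows.sum() < C.shape[1] + 3:
                continue
            b, s, pv = _ols_scan(U[rows, k], T[np.ix_(rows, cols)], C[rows])
            beta[k, cols] = b
            se[k, cols] = s
            p[k, cols] = pv
            n_eff[k, cols] = int(rows.sum())
    alpha = 0.05 / K / q
    return PhewasResult(p=p, beta=beta, se=se, n=n_eff, bonferroni_alpha=alpha)


def incremental_r2(trait, udips, covariates=None) -> IncrementalFit:
    """Variance explained by the UDIP block beyond covariates, with partial F."""
    y = np.asarray(
        trait.to_numpy() if hasattr(trait, "to_numpy") else trait, dtype=np.float64
    ).ravel()
    U = udips.masked() if hasattr(udips, "masked") else _as_matrix(udips)
    if U.shape[1] == 0:
        raise ValueError("no UDIP columns: incremental R^2 is undefined")
    n = y.shape[0]
    C = _as_matrix(covariates) if covariates is not None else np.empty((n, 0))
    rows = np.isfinite(y) & np.isfinite(U).all(axis=1)
    if C.shape[1]:
        rows &= np.isfinite(C).all(axis=1)
    y, U, C = y[rows], U[rows], C[rows]
    n = y.shape[0]
    K = U.shape[1]
    c = C.shape[1]
    if n <= c + K + 1:
        raise ValueError("need n > c + K + 1 observations")
    X_red = np.column_stack([np.ones(n), C])
    X_full = np.column_stack([X_red, U])
    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        # identify offending columns by greedy rank growth
        bad = []
        kept = np.empty((n, 0))
        names = ["intercept"] + [f"cov_{j}" for j in range(c)] + [
            f"udip_{j}" for j in range(K)
        ]
        for j in range(X_full.shape[1]):
            trial = np.column_stack([kept, X_full[:, j]])
            if np.linalg.matrix_rank(trial) > kept.shape[1]:
                kept = trial
            else:
                bad.append(names[j])
        raise ValueError(f"singular full design; offending columns: {bad}")

    def rss(X):
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ b
        return float(r @ r)

    tss = float(((y - y.mean()) ** 2).sum())
    rss_red, rss_full = rss(X_red), rss(X_full)
    r2_cov = 1.0 - rss_red / tss
    r2_full = 1.0 - rss_full / tss
    df1 = K
    df2 = n - c - K - 1
    f = ((rss_red - rss_full) / df1) / (rss_full / df2)
    f = max(f, 0.0)
    p = float(np.clip(stats.f.sf(f, df1, df2), P_FLOOR, 1.0))
    return IncrementalFit(
        r2_cov=r2_cov, r2_full=r2_full, delta_r2=r2_full - r2_cov,
        f_stat=f, df1=df1, df2=df2, p=p,
    )


def cca_component_assoc(
    cca_scores, traits, covariates=None, percentile: float = 95.0
):
    """Strong-association tail per canonical component.

    For each component, every trait is regressed on the component score plus
    covariates; the requested percentile of the -log10 p distribution over
    traits is reported (percentile 100 = the maximum).
    """
    S = _as_matrix(cca_scores)
    T = _as_matrix(traits)
    if T.shape[1] < 20:
        warnings.warn("fewer than 20 traits: the percentile summary is unstable")
    n = S.shape[0]
    C = _as_matrix(covariates) if covariates is not None else np.empty((n, 0))
    out = np.empty(S.shape[1])
    for comp in range(S.shape[1]):
        _, _, pv = _ols_scan(S[:, comp], T, C)
        out[comp] = np.percentile(-np.log10(pv), percentile)
    return out
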