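"""Miniature imaging-genetics pipeline over latent imaging phenotypes.

Per-SNP associations are tested for every UDIP with an ordinary-least-squares
model (phenotype and dosage residualized on covariates plus intercept; the
Frisch-Waugh theorem makes this equivalent to the full multiple regression).
OLS is a deliberate simplification appropriate for unrelated synthetic
subjects, standing in for a linear mixed model with a genetic relationship
random effect. Per-SNP results are aggregated by minP (the most significant
p-value across UDIPs), thresholded with Bonferroni correction, greedily
clumped into non-overlapping loci by LD (r^2) and physical proximity, and
compared across analyses by interval intersection after extending each locus
by a fixed pad (default 125 kb) per side.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "GwasSummary",
    "Locus",
    "LocusSet",
    "OverlapResult",
    "gwas_scan",
    "minp_aggregate",
    "ld_r2",
    "clump_loci",
    "overlap_loci",
    "novel_loci",
    "DEFAULT_ALPHA",
    "write_sumstats",
    "write_loci_bed",
]

DEFAULT_ALPHA = 5e-8 / 128  # genome-wide threshold / number of phenotypes


@dataclass
class GwasSummary:
    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    maf: np.ndarray
    beta: np.ndarray     # (n_snps, n_udips)
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray        # two-sided, in (0, 1]
    n_used: np.ndarray   # (n_udips,) effective sample size per phenotype
    minp: np.ndarray | None = None
    best_udip: np.ndarray | None = None
    snp_index: np.ndarray | None = None  # indices into the source panel

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    @property
    def n_udips(self) -> int:
        return self.p.shape[1]


@dataclass
class Locus:
    chrom: str
    start: int           # 1-based inclusive
    end: int
    lead_snp: str
    top_p: float
    members: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"locus start {self.start} > end {self.end}")
        if self.lead_snp not in self.members:
            raise ValueError("lead SNP must be a member of its locus")


@dataclass
class LocusSet:
    loci: list[Locus]
    alpha: float

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)


@dataclass
class OverlapResult:
    shared: int
    unique_a: int
    unique_b: int

    @property
    def total(self) -> int:
        return self.shared + self.unique_a + self.unique_b

    @property
    def percent_shared(self) -> float:
        if self.total == 0:
            return 0.0
        return 100.0 * self.shared / self.total


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of each column of M on [1, C] via least squares."""
    Q, _ = np.linalg.qr(C)
    return M - Q @ (Q.T @ M)


def _covariate_matrix(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(
        covariates.to_numpy() if hasattr(covariates, "to_numpy") else covariates,
        dtype=np.float64,
    )
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([np.ones(n), C])


def gwas_scan(
    panel,
    udips,
    covariates=None,
    maf_min: float = 0.01,
) -> GwasSummary:
    """Association scan of every retained SNP against every UDIP.

    Subjects must already be aligned by IID across panel, UDIPs, and
    covariates. SNPs with MAF below ``maf_min`` are dropped; QC-masked UDIP
    entries are excluded per phenotype; two-sided p-values come from the t
    distribution with n - c - 2 degrees of freedom (c = covariate count).
    """
    keep = panel.maf >= maf_min
    G = panel.dosages[:, keep].astype(np.float64)
    snp_idx = np.flatnonzero(keep)
    n, m = G.shape
    Y = udips.udip.astype(np.float64)
    mask = udips.qc_mask
    K = Y.shape[1]
    if Y.shape[0] != n:
        raise ValueError("panel and UDIPs have different subject counts")
    C = _covariate_matrix(covariates, n)
    c = C.shape[1] - 1  # covariates excluding the intercept

    const = G.std(axis=0) == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant dosage column(s) after MAF filter; "
            "their tests are skipped"
        )

    beta = np.full((m, K), np.nan)
    se = np.full((m, K), np.nan)
    tstat = np.full((m, K), np.nan)
    pval = np.ones((m, K))
    n_used = np.zeros(K, dtype=int)

    # group phenotypes by identical QC-mask pattern to share residualization
    patterns: dict[bytes, list[int]] = {}
    for j in range(K):
        patterns.setdefault(mask[:, j].tobytes(), []).append(j)

    for pat, cols in patterns.items():
        rows = np.frombuffer(pat, dtype=bool)
        ns = int(rows.sum())
        df = ns - c - 2
        if df <= 0:
            raise ValueError("too few subjects for the covariate-adjusted test")
        Cm = C[rows]
        Gm = _residualize(G[rows], Cm)
        gss = (Gm ** 2).sum(axis=0)
        ok = ~const & (gss > 0)
        Ym = _residualize(Y[np.ix_(rows, cols)], Cm)
        gy = Gm.T @ Ym                       # (m, len(cols))
        b = np.where(ok[:, None], gy / np.where(gss == 0, 1, gss)[:, None], np.nan)
        yss = (Ym ** 2).sum(axis=0)          # (len(cols),)
        rss = yss[None, :] - b ** 2 * gss[:, None]
        rss = np.clip(rss, 0.0, None)
        s2 = rss / df
        with np.errstate(divide="ignore", invalid="ignore"):
            se_pat = np.sqrt(s2 / gss[:, None])
            t_pat = b / se_pat
        p_pat = 2.0 * stats.t.sf(np.abs(t_pat), df)
        p_pat = np.clip(p_pat, np.finfo(float).tiny, 1.0)
        for jj, col in enumerate(cols):
            beta[:, col] = b[:, jj]
            se[:, col] = se_pat[:, jj]
            tstat[:, col] = t_pat[:, jj]
            pval[ok, col] = p_pat[ok, jj]
            n_used[col] = ns

    summ = GwasSummary(
        snp_id=panel.snp_id[keep],
        chrom=panel.chrom[keep],
        pos=panel.pos[keep],
        maf=panel.maf[keep],
        beta=beta, se=se, t=tstat, p=pval, n_used=n_used,
        snp_index=snp_idx,
    )
    return minp_aggregate(summ)


def minp_aggregate(summary: GwasSummary) -> GwasSummary:
    """Per-SNP minimum p over the UDIP axis; ties break to the lowest index."""
    summary.minp = summary.p.min(axis=1)
    summary.best_udip = summary.p.argmin(axis=1)
    return summary


def ld_r2(panel, snp_i: int, snp_j: int) -> float:
    """Squared Pearson correlation between two dosage columns."""
    gi = panel.dosages[:, snp_i].astype(np.float64)
    gj = panel.dosages[:, snp_j].astype(np.float64)
    if gi.std() == 0 or gj.std() == 0:
        raise ValueError("monomorphic SNP has undefined LD")
    r = np.corrcoef(gi, gj)[0, 1]
    return float(r * r)


def clump_loci(
    summary: GwasSummary,
    panel,
    alpha: float = DEFAULT_ALPHA,
    r2_max: float = 0.1,
    merge_kb: float = 250.0,
) -> LocusSet:
    """Greedy LD/distance clumping of significant SNPs into loci.

    Significant SNPs (minP < alpha) are processed in ascending minP order:
    the best remaining SNP becomes a lead, and every remaining significant
    SNP on the same chromosome with r^2 > ``r2_max`` to the lead joins its
    locus. The locus interval spans its members' positions. Finally,
    same-chromosome loci whose gap is below ``merge_kb`` kb are merged, the
    merged lead being the member with the smallest minP.
    """
    if summary.minp is None:
        raise ValueError("run minp_aggregate first")
    sig = np.flatnonzero(summary.minp < alpha)
    if sig.size == 0:
        return LocusSet([], alpha)
    order = sig[np.lexsort((summary.snp_id[sig], summary.pos[sig],
                            summary.minp[sig]))]
    # dosage columns for the retained SNPs, standardized once
    idx_panel = summary.snp_index
    if idx_panel is None:
        idx_panel = np.arange(summary.n_snps)
    G = panel.dosages[:, idx_panel].astype(np.float64)
    Gc = G - G.mean(axis=0)
    norms = np.sqrt((Gc ** 2).sum(axis=0))
    norms[norms == 0] = 1.0
    Gc /= norms

    remaining = list(order)
    loci: list[Locus] = []
    while remaining:
        lead = remaining.pop(0)
        members = [lead]
        still = []
        for s in remaining:
            if summary.chrom[s] == summary.chrom[lead]:
                r2 = float(Gc[:, s] @ Gc[:, lead]) ** 2
                if r2 > r2_max:
                    members.append(s)
                    continue
            still.append(s)
        remaining = still
        pos = summary.pos[members]
        loci.append(
            Locus(
                chrom=str(summary.chrom[lead]),
                start=int(pos.min()),
                end=int(pos.max()),
                lead_snp=str(summary.snp_id[lead]),
                top_p=float(summary.minp[members].min()),
                members=[str(summary.snp_id[s]) for s in members],
            )
        )

    # merge same-chromosome loci closer than merge_kb
    merge_bp = merge_kb * 1000.0
    merged: list[Locus] = []
    for chrom in sorted({l.chrom for l in loci}):
        chrom_loci = sorted(
            (l for l in loci if l.chrom == chrom), key=lambda l: l.start
        )
        cur = chrom_loci[0]
        for nxt in chrom_loci[1:]:
            if nxt.start - cur.end < merge_bp:
                lead, top = (
                    (cur.lead_snp, cur.top_p)
                    if cur.top_p <= nxt.top_p
                    else (nxt.lead_snp, nxt.top_p)
                )
                cur = Locus(
                    chrom=chrom,
                    start=min(cur.start, nxt.start),
                    end=max(cur.end, nxt.end),
                    lead_snp=lead,
                    top_p=top,
                    members=cur.members + nxt.members,
                )
            else:
                merged.append(cur)
                cur = nxt
        merged.append(cur)
    merged.sort(key=lambda l: (l.chrom, l.start))
    return LocusSet(merged, alpha)


def _extended(locus: Locus, pad_bp: int) -> tuple[int, int]:
    return max(1, locus.start - pad_bp), locus.end + pad_bp


def overlap_loci(
    set_a: LocusSet, set_b: LocusSet, pad_kb: float = 125.0
) -> tuple[OverlapResult, list[dict]]:
    """Cluster extended loci from both sets by transitive interval overlap.

    Each locus is extended by ``pad_kb`` kb per side (floored at position 1);
    per-chromosome interval trees index one set and clusters are formed by
    union-find over all pairwise intersections. A cluster containing members
    of both sets counts as shared.
    """
    items = [("a", i, l) for i, l in enumerate(set_a)] + [
        ("b", i, l) for i, l in enumerate(set_b)
    ]
    for _, _, l in items:
        if l.start > l.end:
            raise ValueError("locus with start > end")
    pad_bp = int(round(pad_kb * 1000))
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    trees: dict[str, IntervalTree] = {}
    for idx, (_, _, l) in enumerate(items):
        s, e = _extended(l, pad_bp)
        trees.setdefault(l.chrom, IntervalTree()).addi(s, e + 1, idx)
    for idx, (_, _, l) in enumerate(items):
        s, e = _extended(l, pad_bp)
        for hit in trees[l.chrom].overlap(s, e + 1):
            union(idx, hit.data)

    clusters: dict[int, list[int]] = {}
    for idx in range(len(items)):
        clusters.setdefault(find(idx), []).append(idx)

    shared = unique_a = unique_b = 0
    annotations = []
    for memb in clusters.values():
        sets_here = {items[i][0] for i in memb}
        kind = "shared" if sets_here == {"a", "b"} else f"unique_{sets_here.pop()}"
        if kind == "shared":
            shared += 1
        elif kind == "unique_a":
            unique_a += 1
        else:
            unique_b += 1
        annotations.append(
            {
                "kind": kind,
                "loci": [
                    {"set": items[i][0], "lead_snp": items[i][2].lead_snp,
                     "chrom": items[i][2].chrom,
                     "start": items[i][2].start, "end": items[i][2].end}
                    for i in memb
                ],
            }
        )
    return OverlapResult(shared, unique_a, unique_b), annotations


def novel_loci(
    set_target: LocusSet, reference_sets: list[LocusSet], pad_kb: float = 125.0
) -> list[Locus]:
    """Target loci whose extended interval misses every extended reference."""
    pad_bp = int(round(pad_kb * 1000))
    trees: dict[str, IntervalTree] = {}
    for ref in reference_sets:
        for l in ref:
            s, e = _extended(l, pad_bp)
            trees.setdefault(l.chrom, IntervalTree()).addi(s, e + 1)
    out = []
    for l in set_target:
        s, e = _extended(l, pad_bp)
        tree = trees.get(l.chrom)
        if tree is None or not tree.overlaps(s, e + 1):
            out.append(l)
    return out


# -- plain-text exports ------------------------------------------------------


def write_sumstats(summary: GwasSummary, prefix) -> None:
    """Per-UDIP association TSVs plus a per-SNP minP TSV."""
    base = pd.DataFrame(
        {
            "CHR": summary.chrom,
            "SNP": summary.snp_id,
            "POS": summary.pos,
            "A1": "A",
            "A2": "G",
        }
    )
    for j in range(summary.n_udips):
        df = base.copy()
        df["N"] = summary.n_used[j]
        df["BETA"] = summary.beta[:, j]
        df["SE"] = summary.se[:, j]
        df["P"] = summary.p[:, j]
        df.to_csv(f"{prefix}.UDIP_{j}.tsv", sep="\t", index=False)
    minp = base[["CHR", "SNP", "POS"]].copy()
    minp["MINP"] = summary.minp
    minp["BEST_UDIP"] = summary.best_udip
    minp.to_csv(f"{prefix}.minp.tsv", sep="\t", index=False)


def write_loci_bed(locus_set: LocusSet, bed_path, json_path=None) -> None:
    """BED export (0-based half-open) with a JSON sidecar of locus detail."""
    with open(bed_path, "w") as fh:
        for l in locus_set:
            fh.write(f"{l.chrom}\t{l.start - 1}\t{l.end}\t{l.lead_snp}\n")
    if json_path is not None:
        payload = [
            {
                "chrom": l.chrom, "start": l.start, "end": l.end,
                "lead_snp": l.lead_snp, "top_p": l.top_p, "members": l.members,
            }
            for l in locus_set
        ]
        with open(json_path, "w") as fh:
            json.dump({"alpha": locus_set.alpha, "loci": payload}, fh, indent=1)
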