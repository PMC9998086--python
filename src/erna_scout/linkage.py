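"""Linking eRNA regions to candidate target genes.

Two complementary assignments: the nearest-gene model (signed distance from
region centre to the strand-aware TSS) and windowed best correlation
(Spearman rho between eRNA and gene expression across shared samples, over
genes whose TSS lies within a half-window, default +/-100 kb, of the region
centre).  Gene-level consequences are summarised by the net enhancer change
(#cohort-gained minus #cohort-lost eRNAs within +/-200 kb of the TSS,
clamped to nine bins -4..+4) compared against the gene's expression shift
with a Kruskal-Wallis test, and by hypergeometric / Fisher gene-set overlap
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import LABEL_A, LABEL_B
from .intervals import GenomeAnnotation, RegionSet

__all__ = [
    "nearest_gene",
    "windowed_best_correlation",
    "net_enhancer_change",
    "bin_expression_shift",
    "overlap_test",
    "stratify_by_gene",
    "OverlapTestResult",
]

NET_CHANGE_CLAMP = 4


def _region_ids(regions: RegionSet) -> list[str]:
    return [iv.name or f"{iv.chrom}:{iv.start}-{iv.end}" for iv in regions]


def nearest_gene(regions: RegionSet, ann: GenomeAnnotation) -> pd.DataFrame:
    """Nearest-gene assignment by |TSS - region centre|.

    Distance is signed (TSS minus centre); ties go to the lexicographically
    smaller gene_id; regions on chromosomes without genes get NA.
    """
    tss = ann.tss_table().sort_values(["chrom", "tss", "gene_id"])
    by_chrom = {c: g for c, g in tss.groupby("chrom")}
    rows = []
    for iv, rid in zip(regions, _region_ids(regions)):
        sub = by_chrom.get(iv.chrom)
        if sub is None or sub.empty:
            rows.append((rid, None, np.nan))
            continue
        d = sub["tss"].to_numpy() - iv.centre
        best = np.min(np.abs(d))
        cand = sub.iloc[np.flatnonzero(np.abs(d) == best)]
        pick = cand.sort_values("gene_id").iloc[0]
        rows.append((rid, pick["gene_id"], int(pick["tss"] - iv.centre)))
    return pd.DataFrame(rows, columns=["region_id", "nearest_gene_id", "distance"])


def _spearman_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman rho between each row of x and each row of y (shared columns).

    Average ranks for ties, then Pearson on the rank vectors.
    """
    rx = stats.rankdata(x, axis=1)
    ry = stats.rankdata(y, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    nx = np.sqrt((rx**2).sum(axis=1))
    ny = np.sqrt((ry**2).sum(axis=1))
    denom = np.outer(nx, ny)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rx @ ry.T) / denom
    return np.where(denom > 0, rho, np.nan)


def windowed_best_correlation(
    erna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    ann: GenomeAnnotation,
    regions: RegionSet,
    half_window: int = 100_000,
    use_abs: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Best-correlated gene with TSS within ``half_window`` of each region.

    ``erna_expr``: regions x samples; ``gene_expr``: genes x samples.  The
    best gene maximises signed Spearman rho (|rho| with ``use_abs``).
    Returns (linkage table, eRNA x in-window-gene rho long table).
    """
    shared = [s for s in erna_expr.columns if s in set(gene_expr.columns)]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples for correlation linkage")
    ee = erna_expr[shared]
    ge = gene_expr[shared]
    tss = ann.tss_table().set_index("gene_id")
    tss = tss.loc[[g for g in ge.index if g in tss.index]]

    rid_list = _region_ids(regions)
    region_by_id = {rid: iv for rid, iv in zip(rid_list, regions)}
    rows = []
    rho_rows = []
    for rid in ee.index:
        iv = region_by_id.get(rid)
        if iv is None:
            raise KeyError(f"eRNA expression row {rid!r} not in region set")
        in_win = tss[
            (tss["chrom"] == iv.chrom) & (np.abs(tss["tss"] - iv.centre) <= half_window)
        ]
        if in_win.empty:
            rows.append((rid, None, np.nan, half_window))
            continue
        rho = _spearman_matrix(
            ee.loc[[rid]].to_numpy(float), ge.loc[in_win.index].to_numpy(float)
        )[0]
        for g, r in zip(in_win.index, rho):
            rho_rows.append((rid, g, r))
        score = np.abs(rho) if use_abs else rho
        if np.all(np.isnan(score)):
            rows.append((rid, None, np.nan, half_window))
            continue
        k = int(np.nanargmax(score))
        rows.append((rid, in_win.index[k], float(rho[k]), half_window))
    link = pd.DataFrame(
        rows, columns=["region_id", "best_corr_gene_id", "rho", "best_corr_window"]
    )
    rho_long = pd.DataFrame(rho_rows, columns=["region_id", "gene_id", "rho"])
    return link, rho_long


def net_enhancer_change(
    ann: GenomeAnnotation,
    regions: RegionSet,
    labels: pd.Series | dict,
    half_window: int = 200_000,
) -> pd.DataFrame:
    """Per gene: (#B-specific - #A-specific) eRNAs with centre within
    ``half_window`` of the TSS; bin = clamp(net, -4, +4) (nine groups)."""
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    centres = []
    for iv, rid in zip(regions, _region_ids(regions)):
        lab = labels.get(rid, None)
        if lab in (LABEL_A, LABEL_B):
            centres.append((iv.chrom, iv.centre, lab))
    rows = []
    for g in ann.genes:
        gained = lost = 0
        for chrom, c, lab in centres:
            if chrom == g.chrom and abs(g.tss - c) <= half_window:
                if lab == LABEL_B:
                    gained += 1
                else:
                    lost += 1
        net = gained - lost
        rows.append(
            (g.gene_id, gained, lost, net, int(np.clip(net, -NET_CHANGE_CLAMP, NET_CHANGE_CLAMP)))
        )
    return pd.DataFrame(rows, columns=["gene_id", "gained", "lost", "net_change", "bin"])


def bin_expression_shift(nct: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """Per-bin summary of gene log2FC plus a Kruskal-Wallis test over bins.

    ``nct`` needs columns ``bin`` and ``log2FC``; genes with undefined
    log2FC are dropped.  Returns (summary, H, p).
    """
    df = nct.dropna(subset=["log2FC"])
    groups = [g["log2FC"].to_numpy(float) for _, g in df.groupby("bin") if len(g)]
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty bins")
    summary = (
        df.groupby("bin")["log2FC"]
        .agg(n="size", median="median", q25=lambda s: s.quantile(0.25), q75=lambda s: s.quantile(0.75))
        .reset_index()
    )
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return summary, 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return summary, float(h), float(p)


@dataclass(frozen=True)
class OverlapTestResult:
    universe: int
    n_a: int
    n_b: int
    overlap: int
    p_hypergeom: float
    p_fisher: float


def overlap_test(set_a, set_b, universe) -> OverlapTestResult:
    """Enrichment of the overlap of two gene sets within a universe.

    Upper-tail hypergeometric P[X >= k] and two-sided Fisher's exact p on
    the 2x2 membership table.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("both sets must be subsets of the universe")
    n, na, nb = len(u), len(a), len(b)
    k = len(a & b)
    p_hyp = float(stats.hypergeom.sf(k - 1, n, na, nb))
    table = [[k, na - k], [nb - k, n - na - nb + k]]
    p_fis = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return OverlapTestResult(n, na, nb, k, p_hyp, p_fis)


def stratify_by_gene(expr: pd.Series, n_sd: float = 2.0) -> pd.Series:
    """Amplification-style stratification of samples on one gene.

    A sample is "high" iff its expression exceeds the cohort median plus
    ``n_sd`` population standard deviations (the ERBB2^AMP rule).
    """
    x = expr.astype(float)
    thresh = x.median() + n_sd * x.std(ddof=0)
    return (x > thresh).rename(f"{expr.name}_high" if expr.name else "high")
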