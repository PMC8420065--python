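"""Link differentially methylated enhancer regions (DMERs) to target genes.

Genes whose expression already tracks their own promoter methylation are
identified first and excluded; remaining genes are paired with DMERs on the
same chromosome within 1 Mbp of the region center, and pairs are retained
only when region methylation and gene expression are negatively correlated
across tumor samples (two-sided p from the t transform of Pearson's r, then
the r < 0 sign gate selects the negative tail).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .methylome import EnhancerRegion, MethylationMatrix

PAIR_COLUMNS = [
    "region_id", "gene_id", "gene_type", "distance",
    "pcc", "p", "methylation_direction",
]


def pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of Pearson's r via t = r*sqrt((n-2)/(1-r^2))."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def _row_standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale rows; returns (standardized rows, zero-variance mask)."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    zero = sd[:, 0] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = (X - mu) / sd
    Z[zero] = 0.0
    return Z, zero


def correlation_matrix(A: pd.DataFrame, B: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between rows of A and rows of B over shared columns."""
    shared = A.columns.intersection(B.columns)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")
    Za, _ = _row_standardize(A[shared].to_numpy(dtype=float))
    Zb, _ = _row_standardize(B[shared].to_numpy(dtype=float))
    R = (Za @ Zb.T) / len(shared)
    return pd.DataFrame(np.clip(R, -1.0, 1.0), index=A.index, columns=B.index)


def identify_promoter_regulated_genes(
    promoter_meth: MethylationMatrix,
    expression: pd.DataFrame,
    dpmgs: pd.DataFrame,
    p_cut: float = 0.05,
) -> set[str]:
    """Genes whose promoter methylation anticorrelates with their expression.

    For every differentially promoter-methylated gene (direction != 'ns'),
    Pearson's r between promoter beta and expression across shared samples is
    computed; the gene enters the exclusion set iff r < 0 and p <= p_cut.
    """
    called = dpmgs.index[dpmgs["direction"] != "ns"]
    genes = [g for g in called if g in promoter_meth.values.index and g in expression.index]
    shared = promoter_meth.values.columns.intersection(expression.columns)
    if len(shared) < 3:
        warnings.warn("fewer than 3 shared samples; no promoter-regulated genes called")
        return set()
    n = len(shared)
    regulated: set[str] = set()
    for g in genes:
        x = promoter_meth.values.loc[g, shared].to_numpy(dtype=float)
        y = expression.loc[g, shared].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            warnings.warn(f"gene {g!r}: zero-variance vector, skipped")
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r < 0 and pearson_p(r, n) <= p_cut:
            regulated.add(g)
    return regulated


def candidate_pairs_by_distance(
    dmers: list[EnhancerRegion],
    directions: pd.Series,
    genes: pd.DataFrame,
    excluded_genes: set[str] | None = None,
    max_distance: int = 1_000_000,
) -> pd.DataFrame:
    """All (region, gene) pairs on the same chromosome within max_distance.

    ``directions`` maps region_id -> 'hyper'/'hypo'; only regions present in
    it are paired. The distance is |region center - TSS| with the center at
    floor((start+end)/2). Genes in ``excluded_genes`` are dropped.
    """
    excluded = excluded_genes or set()
    rows = []
    by_chrom = {c: g for c, g in genes.groupby("chrom", sort=False)}
    for region in dmers:
        if region.region_id not in directions.index:
            continue
        gsub = by_chrom.get(region.chrom)
        if gsub is None:
            continue
        dist = np.abs(gsub["tss"].to_numpy() - region.center)
        ok = dist <= max_distance
        for gid, gtype, d in zip(gsub["gene_id"][ok], gsub["gene_type"][ok], dist[ok]):
            if gid in excluded:
                continue
            rows.append(
                (region.region_id, gid, gtype, int(d), np.nan, np.nan,
                 directions[region.region_id])
            )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def screen_pairs_by_correlation(
    candidates: pd.DataFrame,
    region_meth: MethylationMatrix,
    expression: pd.DataFrame,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Keep candidate pairs with r < 0 and p <= p_cut over tumor samples."""
    if candidates.empty:
        return candidates.copy()
    tumor = [s for s in region_meth.tumor_samples() if s in expression.columns]
    if len(tumor) < 3:
        warnings.warn("fewer than 3 shared tumor samples; all pairs skipped")
        return candidates.iloc[0:0].copy()
    n = len(tumor)
    M = region_meth.values[tumor]
    E = expression[tumor]
    usable = candidates["region_id"].isin(M.index) & candidates["gene_id"].isin(E.index)
    cand = candidates.loc[usable].copy()
    R = correlation_matrix(M.loc[cand["region_id"].unique()], E.loc[cand["gene_id"].unique()])
    zero_m = M.loc[cand["region_id"].unique()].std(axis=1) == 0
    zero_e = E.loc[cand["gene_id"].unique()].std(axis=1) == 0
    r = R.to_numpy()[
        R.index.get_indexer(cand["region_id"]), R.columns.get_indexer(cand["gene_id"])
    ]
    degenerate = (
        zero_m.reindex(cand["region_id"]).to_numpy()
        | zero_e.reindex(cand["gene_id"]).to_numpy()
    )
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} pairs with zero variance skipped")
    cand["pcc"] = r
    cand["p"] = pearson_p(r, n)
    keep = (~degenerate) & (cand["pcc"] < 0) & (cand["p"] <= p_cut)
    return cand.loc[keep].reset_index(drop=True)


def split_pairs_by_gene_type(pairs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition screened pairs into (DMER-lncRNA, DMER-mRNA) tables."""
    lnc = pairs.loc[pairs["gene_type"] == "lncRNA"].reset_index(drop=True)
    mrna = pairs.loc[pairs["gene_type"] == "mRNA"].reset_index(drop=True)
    return lnc, mrna
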