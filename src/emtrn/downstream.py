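"""Biomarker evaluation, gene-set over-representation and drug mapping.

The diagnostic value of a module on an independent tumor/normal expression
matrix is summarized by the ROC AUC, computed as the Mann-Whitney
probability that a tumor sample outscores a normal one (ties count 1/2).
The module-level score is the mean of per-gene z-scores on the validation
matrix; per-gene AUCs are reported alongside. Over-representation uses the
same upper-tail hypergeometric as the ceRNA screen, against a user-supplied
GMT collection.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError


def compute_auc(scores: pd.Series, labels: pd.Series) -> float:
    """AUC = P(tumor score > normal score) + P(equal)/2."""
    labels = labels.reindex(scores.index)
    y = (labels == "tumor").to_numpy()
    if y.all() or (~y).all():
        raise ParameterError("both classes must be present")
    return float(roc_auc_score(y, scores.to_numpy(dtype=float)))


def module_scores(expression: pd.DataFrame, genes: list[str]) -> pd.Series:
    """Mean of per-gene z-scores (standardized on the given matrix)."""
    present = [g for g in genes if g in expression.index]
    if not present:
        raise ParameterError("no module gene present in the expression matrix")
    X = expression.loc[present].to_numpy(dtype=float)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=1, keepdims=True)) / sd
    return pd.Series(Z.mean(axis=0), index=expression.columns, name="module_score")


def module_auc_report(
    expression: pd.DataFrame, labels: pd.Series, genes: list[str]
) -> tuple[float, pd.DataFrame]:
    """Module-level AUC plus per-gene AUCs on a validation matrix."""
    score = module_scores(expression, genes)
    overall = compute_auc(score, labels)
    rows = []
    for g in genes:
        if g not in expression.index:
            rows.append((g, np.nan, True))
            continue
        rows.append((g, compute_auc(expression.loc[g], labels), False))
    per_gene = pd.DataFrame(rows, columns=["gene_id", "auc", "missing"])
    return overall, per_gene


def expression_group_stats(
    expression: pd.DataFrame, labels: pd.Series, genes: list[str]
) -> pd.DataFrame:
    """Per-gene tumor/normal medians, rank-sum p and BH FDR over the query set."""
    labels = labels.reindex(expression.columns)
    tumor = expression.columns[labels == "tumor"]
    normal = expression.columns[labels == "normal"]
    if len(tumor) < 2 or len(normal) < 2:
        raise ParameterError("need >= 2 samples per group")
    rows = []
    for g in genes:
        if g not in expression.index:
            rows.append((g, np.nan, np.nan, np.nan, "missing"))
            continue
        t = expression.loc[g, tumor].to_numpy(dtype=float)
        n = expression.loc[g, normal].to_numpy(dtype=float)
        if np.ptp(np.concatenate([t, n])) == 0:
            rows.append((g, float(np.median(t)), float(np.median(n)), 1.0, "tied"))
            continue
        p = float(stats.mannwhitneyu(t, n, alternative="two-sided").pvalue)
        med_t, med_n = float(np.median(t)), float(np.median(n))
        if med_t > med_n:
            direction = "up_in_tumor"
        elif med_t < med_n:
            direction = "down_in_tumor"
        else:
            direction = "ns"
        rows.append((g, med_t, med_n, p, direction))
    out = pd.DataFrame(rows, columns=["gene_id", "median_tumor", "median_normal",
                                      "p", "direction"])
    mask = out["p"].notna()
    out["fdr"] = np.nan
    if mask.any():
        out.loc[mask, "fdr"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out


def gene_set_ora(
    query: set[str],
    collection: dict[str, set[str]],
    universe: set[str],
    p_cut: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric over-representation of the query in each gene set.

    Population = universe, successes = |set & universe|, draws = |query|,
    p = P(X >= overlap). BH across sets; 'significant' flags p <= p_cut.
    """
    if not query:
        raise ParameterError("empty query gene set")
    query = set(query) & universe
    if not query:
        raise ParameterError("query disjoint from the universe")
    N = len(universe)
    rows = []
    for name in sorted(collection):
        members = collection[name] & universe
        overlap = len(query & members)
        p = float(stats.hypergeom.sf(overlap - 1, N, len(members), len(query)))
        rows.append((name, len(members), overlap, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p"])
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else np.nan
    out["significant"] = out["p"] <= p_cut
    return out


def build_drug_network(
    drugs: pd.DataFrame, hypo_network: nx.Graph
) -> tuple[pd.DataFrame, nx.Graph]:
    """Bipartite drug--lncRNA network of down-regulating associations.

    Keeps rows with direction == 'down' whose lncRNA is a lncRNA node of the
    hypomethylation subnetwork, de-duplicated. Returns the edge table and a
    networkx graph with node types.
    """
    lncs = {
        n for n, d in hypo_network.nodes(data=True) if d.get("node_type") == "lncRNA"
    }
    keep = (drugs["direction"] == "down") & drugs["lncrna"].isin(lncs)
    edges = drugs.loc[keep, ["drug", "lncrna", "direction"]].drop_duplicates(
        subset=["drug", "lncrna"]
    ).reset_index(drop=True)
    if edges.empty:
        warnings.warn("no down-regulating drug association targets the hypo network")
    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_node(row["drug"], node_type="drug")
        g.add_node(row["lncrna"], node_type="lncRNA")
        g.add_edge(row["drug"], row["lncrna"], direction="down")
    return edges, g
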