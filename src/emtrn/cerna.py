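"""Competing-endogenous-RNA network assembly.

lncRNA--mRNA pairs sharing at least two miRNA partners are scored with a
hypergeometric test (population = the miRNA universe, successes = the
lncRNA's partners, draws = the mRNA's partners, upper tail inclusive of the
observed overlap), BH-corrected, intersected with the DMER-linked gene sets,
screened for co-expression (PCC > 0.5, p <= 0.05 over tumor samples), and
assembled into the full / hypermethylation / hypomethylation networks with
per-node degree and hub annotation.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .linking import correlation_matrix, pearson_p

CERNA_COLUMNS = [
    "lncrna", "mrna", "n_lnc_mirnas", "n_mrna_mirnas", "shared", "p", "fdr",
]


def shared_mirna_significance(
    lnc_mirna: pd.DataFrame,
    mirna_mrna: pd.DataFrame,
    min_shared: int = 2,
    fdr_cut: float = 0.05,
    universe: str = "union",
) -> pd.DataFrame:
    """Hypergeometric screen of shared-miRNA lncRNA--mRNA pairs.

    ``lnc_mirna`` has columns (lncrna, mirna); ``mirna_mrna`` has columns
    (mirna, mrna). Pairs sharing k >= min_shared miRNAs are tested with
    p = P(X >= k), X ~ Hypergeom(N, K, n); BH over all tested pairs; pairs
    with FDR <= fdr_cut are retained.
    """
    if lnc_mirna.empty or mirna_mrna.empty:
        warnings.warn("empty interaction table; no ceRNA pairs")
        return pd.DataFrame(columns=CERNA_COLUMNS)
    lnc_sets = lnc_mirna.groupby("lncrna")["mirna"].agg(set)
    mrna_sets = mirna_mrna.groupby("mrna")["mirna"].agg(set)
    mir_l = set(lnc_mirna["mirna"])
    mir_m = set(mirna_mrna["mirna"])
    if universe == "union":
        N = len(mir_l | mir_m)
    elif universe == "intersection":
        N = len(mir_l & mir_m)
    else:
        raise ValueError(f"unknown universe {universe!r}")

    # sparse incidence product gives shared counts for all pairs at once
    mirnas = sorted(mir_l | mir_m)
    mir_index = {m: i for i, m in enumerate(mirnas)}
    lncs = list(lnc_sets.index)
    mrnas = list(mrna_sets.index)
    A = np.zeros((len(lncs), len(mirnas)), dtype=np.int32)
    for i, l in enumerate(lncs):
        for m in lnc_sets[l]:
            A[i, mir_index[m]] = 1
    B = np.zeros((len(mrnas), len(mirnas)), dtype=np.int32)
    for i, g in enumerate(mrnas):
        for m in mrna_sets[g]:
            B[i, mir_index[m]] = 1
    shared = A @ B.T

    li, mi = np.nonzero(shared >= min_shared)
    if li.size == 0:
        return pd.DataFrame(columns=CERNA_COLUMNS)
    K = A.sum(axis=1)[li]
    n = B.sum(axis=1)[mi]
    k = shared[li, mi]
    p = stats.hypergeom.sf(k - 1, N, K, n)
    p = np.clip(p, 0.0, 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "lncrna": [lncs[i] for i in li],
            "mrna": [mrnas[i] for i in mi],
            "n_lnc_mirnas": K,
            "n_mrna_mirnas": n,
            "shared": k,
            "p": p,
            "fdr": fdr,
        }
    )
    return out.loc[out["fdr"] <= fdr_cut].reset_index(drop=True)


def intersect_with_dmer_targets(
    pairs: pd.DataFrame, dmer_lnc_pairs: pd.DataFrame, dmer_mrna_pairs: pd.DataFrame
) -> pd.DataFrame:
    """Keep ceRNA pairs whose lncRNA and mRNA are both DMER-linked."""
    if pairs.empty:
        return pairs.copy()
    lncs = set(dmer_lnc_pairs["gene_id"])
    mrnas = set(dmer_mrna_pairs["gene_id"])
    keep = pairs["lncrna"].isin(lncs) & pairs["mrna"].isin(mrnas)
    return pairs.loc[keep].reset_index(drop=True)


def coexpression_screen(
    pairs: pd.DataFrame,
    lnc_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    pcc_cut: float = 0.5,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Keep pairs with Pearson r > pcc_cut (strict) and p <= p_cut."""
    if pairs.empty:
        return pairs.assign(pcc=pd.Series(dtype=float), pcc_p=pd.Series(dtype=float))
    shared = lnc_expr.columns.intersection(mrna_expr.columns)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")
    usable = pairs["lncrna"].isin(lnc_expr.index) & pairs["mrna"].isin(mrna_expr.index)
    out = pairs.loc[usable].copy()
    if out.empty:
        return out.assign(pcc=pd.Series(dtype=float), pcc_p=pd.Series(dtype=float))
    L = lnc_expr.loc[out["lncrna"].unique(), shared]
    M = mrna_expr.loc[out["mrna"].unique(), shared]
    zero_l = L.std(axis=1) == 0
    zero_m = M.std(axis=1) == 0
    R = correlation_matrix(L, M)
    r = R.to_numpy()[R.index.get_indexer(out["lncrna"]), R.columns.get_indexer(out["mrna"])]
    degenerate = (
        zero_l.reindex(out["lncrna"]).to_numpy() | zero_m.reindex(out["mrna"]).to_numpy()
    )
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} pairs with zero variance skipped")
    out["pcc"] = r
    out["pcc_p"] = pearson_p(r, len(shared))
    keep = (~degenerate) & (out["pcc"] > pcc_cut) & (out["pcc_p"] <= p_cut)
    return out.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

def node_directions(
    dmer_lnc_pairs: pd.DataFrame, dmer_mrna_pairs: pd.DataFrame
) -> pd.Series:
    """Per-gene methylation direction inherited from its associated DMERs.

    A gene linked only to hypomethylated regions is 'hypo', only to
    hypermethylated regions 'hyper', otherwise 'mixed'.
    """
    all_pairs = pd.concat([dmer_lnc_pairs, dmer_mrna_pairs], ignore_index=True)
    dirsets = all_pairs.groupby("gene_id")["methylation_direction"].agg(set)
    return dirsets.map(lambda s: next(iter(s)) if len(s) == 1 else "mixed")


def _build_graph(edges: pd.DataFrame, types: dict[str, str],
                 directions: pd.Series, hub_fraction: float) -> nx.Graph:
    g = nx.Graph()
    for _, row in edges.iterrows():
        for node in (row["lncrna"], row["mrna"]):
            if node not in g:
                g.add_node(
                    node,
                    node_type=types[node],
                    direction=str(directions.get(node, "ns")),
                )
        g.add_edge(row["lncrna"], row["mrna"], pcc=float(row["pcc"]),
                   pcc_p=float(row["pcc_p"]))
    annotate_hubs(g, hub_fraction)
    return g


def annotate_hubs(g: nx.Graph, hub_fraction: float = 0.15) -> None:
    """Flag nodes in the top ``hub_fraction`` of the degree distribution.

    A node is a hub iff its degree strictly exceeds the (1 - fraction)
    degree quantile; on a degree-regular graph nothing is flagged. The flag
    is reported, never used as a filter.
    """
    degrees = dict(g.degree())
    nx.set_node_attributes(g, degrees, "degree")
    if not degrees:
        return
    cut = float(np.quantile(list(degrees.values()), 1.0 - hub_fraction, method="lower"))
    nx.set_node_attributes(g, {n: bool(d > cut) for n, d in degrees.items()}, "hub")


def assemble_emtrn(
    edges: pd.DataFrame,
    dmer_lnc_pairs: pd.DataFrame,
    dmer_mrna_pairs: pd.DataFrame,
    hub_fraction: float = 0.15,
) -> dict[str, nx.Graph]:
    """Assemble the full network and its hyper-/hypo-methylation subnetworks.

    Each node inherits a direction from its DMERs; an edge joins a
    subnetwork iff both endpoints carry that subnetwork's direction. Edges
    with discordant endpoints stay in the full network flagged 'mixed'.
    """
    directions = node_directions(dmer_lnc_pairs, dmer_mrna_pairs)
    types = {n: "lncRNA" for n in edges["lncrna"]}
    types.update({n: "mRNA" for n in edges["mrna"]})
    full = _build_graph(edges, types, directions, hub_fraction)
    for u, v, data in full.edges(data=True):
        du, dv = full.nodes[u]["direction"], full.nodes[v]["direction"]
        data["direction"] = du if du == dv and du in ("hyper", "hypo") else "mixed"

    nets = {"full": full}
    for key in ("hyper", "hypo"):
        sub_edges = edges.loc[
            [full.edges[r["lncrna"], r["mrna"]]["direction"] == key for _, r in edges.iterrows()]
        ]
        nets[key] = _build_graph(sub_edges, types, directions, hub_fraction)
    return nets


def network_node_table(g: nx.Graph) -> pd.DataFrame:
    rows = [
        (n, d["node_type"], d["direction"], d["degree"], d["hub"])
        for n, d in g.nodes(data=True)
    ]
    return pd.DataFrame(rows, columns=["node", "node_type", "direction", "degree", "hub"])


def network_edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = []
    for u, v, d in g.edges(data=True):
        if g.nodes[u]["node_type"] != "lncRNA":
            u, v = v, u
        rows.append((u, v, d.get("pcc"), d.get("pcc_p"), d.get("direction", "")))
    rows.sort(key=lambda t: (t[0], t[1]))
    return pd.DataFrame(rows, columns=["lncrna", "mrna", "pcc", "pcc_p", "direction"])
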