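"""Maximal biclique enumeration on the bipartite lncRNA--mRNA network.

Maximal bicliques of a bipartite graph are exactly the formal concepts of
its adjacency relation. They are enumerated with the Close-by-One scheme:
closed left-sets are grown element by element, computing the closure
(A'', A') at each step and pruning non-canonical branches so every concept
is produced exactly once. Modules are then filtered to a minimum size per
side (default 2 lncRNAs x 2 mRNAs, i.e. the "at least two nodes per side"
rule) and reported in a deterministic lexicographic order.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ParameterError


@dataclass(frozen=True)
class BicliqueModule:
    """A maximal complete-bipartite lncRNA-set x mRNA-set module."""

    module_id: str
    lncrnas: frozenset[str]
    mrnas: frozenset[str]

    @property
    def n_lncrnas(self) -> int:
        return len(self.lncrnas)

    @property
    def n_mrnas(self) -> int:
        return len(self.mrnas)


def _validate_bipartite(edges: pd.DataFrame, left_nodes: set[str], right_nodes: set[str]):
    overlap = left_nodes & right_nodes
    if overlap:
        raise ParameterError(
            f"edge endpoints appear on both sides (not bipartite): {sorted(overlap)[:3]}"
        )


def enumerate_maximal_bicliques(
    edges: pd.DataFrame,
    min_left: int = 2,
    min_right: int = 2,
    left_col: str = "lncrna",
    right_col: str = "mrna",
    node_types: dict[str, str] | None = None,
) -> list[BicliqueModule]:
    """All maximal bicliques with >= min_left x min_right vertices.

    ``edges`` is a two-column bipartite edge table. When ``node_types`` maps
    node id -> {'lncRNA', 'mRNA'}, every edge is checked to join a lncRNA to
    an mRNA. The result is ordered lexicographically by (sorted left
    members, sorted right members).
    """
    if edges.empty:
        return []
    left_nodes = set(edges[left_col])
    right_nodes = set(edges[right_col])
    _validate_bipartite(edges, left_nodes, right_nodes)
    if node_types is not None:
        for l, r in zip(edges[left_col], edges[right_col]):
            if node_types.get(l) == node_types.get(r):
                raise ParameterError(f"non-bipartite edge {l!r}--{r!r}")

    lefts = sorted(left_nodes)
    adj = {l: frozenset() for l in lefts}
    grouped = edges.groupby(left_col)[right_col].agg(frozenset)
    adj.update(grouped.to_dict())
    n = len(lefts)
    all_right = frozenset(right_nodes)

    found: list[tuple[frozenset, frozenset]] = []

    def closure_left(B: frozenset) -> frozenset:
        return frozenset(l for l in lefts if B <= adj[l])

    def cbo(A: frozenset, B: frozenset, start: int) -> None:
        found.append((A, B))
        for j in range(start, n):
            lj = lefts[j]
            if lj in A:
                continue
            B2 = B & adj[lj]
            A2 = closure_left(B2)
            # canonicity: the closure may add only elements >= lj outside A
            if any(l in A2 and l not in A for l in lefts[:j]):
                continue
            cbo(A2, B2, j + 1)

    B0 = all_right
    A0 = closure_left(B0)
    cbo(A0, B0, 0)

    modules = [
        BicliqueModule("", frozenset(A), frozenset(B))
        for A, B in found
        if len(A) >= min_left and len(B) >= min_right
    ]
    modules.sort(key=lambda m: (sorted(m.lncrnas), sorted(m.mrnas)))
    return [
        BicliqueModule(f"M{i:04d}", m.lncrnas, m.mrnas)
        for i, m in enumerate(modules, start=1)
    ]


def is_complete_biclique(edges: pd.DataFrame, left: set[str], right: set[str],
                         left_col: str = "lncrna", right_col: str = "mrna") -> bool:
    """Every cross pair present in the edge table?"""
    present = set(zip(edges[left_col], edges[right_col]))
    return all((l, r) in present for l in left for r in right)


def is_maximal_biclique(edges: pd.DataFrame, left: set[str], right: set[str],
                        left_col: str = "lncrna", right_col: str = "mrna") -> bool:
    """Complete and not extendable by any vertex on either side."""
    if not is_complete_biclique(edges, left, right, left_col, right_col):
        return False
    present = set(zip(edges[left_col], edges[right_col]))
    for l in set(edges[left_col]) - left:
        if all((l, r) in present for r in right):
            return False
    for r in set(edges[right_col]) - right:
        if all((l, r) in present for l in left):
            return False
    return True


def modules_table(modules: list[BicliqueModule]) -> pd.DataFrame:
    rows = [
        (m.module_id, ",".join(sorted(m.lncrnas)), ",".join(sorted(m.mrnas)),
         m.n_lncrnas, m.n_mrnas)
        for m in modules
    ]
    return pd.DataFrame(rows, columns=["module_id", "lncrnas", "mrnas",
                                       "n_lncrnas", "n_mrnas"])
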