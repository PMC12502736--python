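"""Drug co-occurrence network over case reports.

Nodes are (normalized) drugs with case-report counts; an undirected edge
weights the number of case reports listing both drugs, whatever their role
codes (suspects are routinely co-reported with corticosteroid and other
co-medication, so the default includes all roles).  Within a report each
drug counts once, so there are no self-loops and an edge weight can never
exceed the report count of either endpoint.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import pandas as pd

from .cohort import CaseSet, DrugNormalizer

__all__ = ["build_graph", "edge_table", "write_graphml"]


def build_graph(cases: CaseSet, roles=("PS", "SS", "C", "I"),
                min_weight: int = 3,
                normalizer: DrugNormalizer | None = None) -> nx.Graph:
    """Co-occurrence graph of drugs on case reports.

    Edges with weight below ``min_weight`` are pruned; isolated nodes are
    kept with their report counts so node prevalence stays interpretable.
    """
    normalizer = normalizer or DrugNormalizer()
    drug = cases.store.table("drug")
    rows = drug[drug["role_cod"].isin(set(roles))]
    g = nx.Graph()
    if rows.empty:
        return g
    norm = normalizer.normalize_series(rows["drugname"])["drug"]
    pairs = pd.DataFrame({"primaryid": rows["primaryid"].astype(int),
                          "drug": norm}).drop_duplicates()

    node_counts = pairs.groupby("drug")["primaryid"].nunique()
    for d, c in node_counts.items():
        g.add_node(d, reports=int(c))

    weights: dict[tuple[str, str], int] = {}
    for _, sub in pairs.groupby("primaryid"):
        for u, v in combinations(sorted(sub["drug"].unique()), 2):
            weights[(u, v)] = weights.get((u, v), 0) + 1
    for (u, v), w in weights.items():
        if w >= min_weight:
            g.add_edge(u, v, weight=w)
    g.graph["min_weight"] = min_weight
    return g


def edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = [(u, v, d["weight"]) for u, v, d in g.edges(data=True)]
    return (pd.DataFrame(rows, columns=["drug_u", "drug_v", "weight"])
            .sort_values("weight", ascending=False, ignore_index=True))


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)
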