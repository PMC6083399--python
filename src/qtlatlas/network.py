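"""Candidate-gene interaction graph and degree-layout (DL) analysis.

The graph is undirected and built from a user-supplied scored edge table
(e.g. a STRING export for the candidates' A. thaliana orthologs), restricted
to a node whitelist.  "Degree layout" is the raw incident-edge count per
node; genes at or above a degree threshold (DL >= 20 by convention) are the
influential hubs.  Functional clusters are taken as an input gene→category
mapping; genes without a mapping fall into the "unknown" category.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import InputError

#: STRING "medium confidence" convention
DEFAULT_SCORE_MIN = 0.4
DEFAULT_DL_MIN = 20

EDGE_COLUMNS = ("gene_a", "gene_b", "score")


def build_graph(
    edges: pd.DataFrame,
    whitelist: Iterable[str],
    score_min: float = DEFAULT_SCORE_MIN,
) -> nx.Graph:
    """Undirected graph over ``whitelist`` from a scored edge table.

    Rules: edges below ``score_min`` are dropped; duplicate unordered pairs
    collapse to the maximum score; self-loops are discarded; an edge naming
    a gene outside the whitelist is dropped with a warning (never an error);
    isolated whitelist genes are retained with degree 0.
    """
    missing = set(EDGE_COLUMNS) - set(edges.columns)
    if missing:
        raise InputError(f"edge table lacks column(s) {sorted(missing)}")
    allowed = set(whitelist)
    G = nx.Graph()
    G.add_nodes_from(sorted(allowed))
    dropped_foreign = 0
    for row in edges.itertuples(index=False):
        a, b, score = str(row.gene_a), str(row.gene_b), float(row.score)
        if a == b:
            continue
        if a not in allowed or b not in allowed:
            dropped_foreign += 1
            continue
        if score < score_min:
            continue
        if G.has_edge(a, b):
            G[a][b]["score"] = max(G[a][b]["score"], score)
        else:
            G.add_edge(a, b, score=score)
    if dropped_foreign:
        warnings.warn(
            f"dropped {dropped_foreign} edge(s) referencing genes outside "
            "the whitelist",
            stacklevel=2,
        )
    return G


def degree_layout(G: nx.Graph) -> dict[str, int]:
    """DL per node: the number of incident edges."""
    return {n: int(d) for n, d in G.degree()}


def influential_from_degrees(
    degrees: Mapping[str, int], dl_min: int = DEFAULT_DL_MIN
) -> list[tuple[str, int]]:
    """Nodes with DL >= dl_min, sorted by DL descending then name."""
    picked = [(g, int(d)) for g, d in degrees.items() if d >= dl_min]
    picked.sort(key=lambda t: (-t[1], t[0]))
    return picked


def influential_genes(
    G: nx.Graph, dl_min: int = DEFAULT_DL_MIN
) -> list[tuple[str, int]]:
    """Hub genes of the graph at the DL threshold (see
    :func:`influential_from_degrees` for ordering)."""
    return influential_from_degrees(degree_layout(G), dl_min)


UNKNOWN_CATEGORY = "unknown"


@dataclass
class ClusterSummary:
    """Functional-category composition of the graph."""

    node_counts: pd.Series          # category -> n nodes
    within_edges: pd.Series         # category -> edges inside the category
    between_edges: int              # edges joining two different categories
    between_pairs: pd.Series        # "catA|catB" -> n edges

    @property
    def n_nodes(self) -> int:
        return int(self.node_counts.sum())


def cluster_summary(
    G: nx.Graph, categories: Mapping[str, str]
) -> ClusterSummary:
    """Tally nodes and edges by functional category.

    Categories partition the nodes (unknown absorbs unmapped genes), so the
    per-category node counts always sum to the node count.
    """
    cat = {n: categories.get(n, UNKNOWN_CATEGORY) for n in G.nodes}
    node_counts = Counter(cat.values())
    within: Counter = Counter()
    between_pairs: Counter = Counter()
    between = 0
    for a, b in G.edges:
        ca, cb = cat[a], cat[b]
        if ca == cb:
            within[ca] += 1
        else:
            between += 1
            between_pairs["|".join(sorted((ca, cb)))] += 1
    return ClusterSummary(
        node_counts=pd.Series(dict(sorted(node_counts.items())), dtype=int),
        within_edges=pd.Series(dict(sorted(within.items())), dtype=int),
        between_edges=between,
        between_pairs=pd.Series(dict(sorted(between_pairs.items())), dtype=int),
    )


def graph_tables(
    G: nx.Graph, categories: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(node table, edge table) ready for TSV export / graph viewers."""
    degrees = degree_layout(G)
    nodes = pd.DataFrame(
        [
            {
                "gene": n,
                "degree": degrees[n],
                "category": (categories or {}).get(n, UNKNOWN_CATEGORY),
            }
            for n in sorted(G.nodes)
        ],
        columns=["gene", "degree", "category"],
    )
    edges = pd.DataFrame(
        [
            {"gene_a": a, "gene_b": b, "score": d["score"]}
            for a, b, d in sorted(G.edges(data=True))
        ],
        columns=["gene_a", "gene_b", "score"],
    )
    return nodes, edges
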