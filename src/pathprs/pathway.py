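"""Pathway-gene ranking by relative betweenness centrality.

Genes are nodes of an undirected interaction graph (information flow can
go both ways); a gene's relative betweenness is the fraction of all-pairs
shortest paths passing through it, normalized by (n-1)(n-2)/2 so values
lie in [0, 1].  Pairs with no connecting path contribute 0, so
disconnected graphs are allowed.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd


def load_edge_list(path) -> nx.Graph:
    """Two-column whitespace/tab-separated gene-pair file -> undirected graph.

    Self-loops are dropped and parallel edges collapse; lines starting
    with ``#`` are comments.  Isolated nodes can be declared by a line
    with a single gene symbol.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 1:
                g.add_node(parts[0])
            elif len(parts) == 2:
                if parts[0] != parts[1]:
                    g.add_edge(parts[0], parts[1])
                else:
                    g.add_node(parts[0])
            else:
                raise ValueError(f"{path}:{lineno}: expected 1 or 2 columns")
    if g.number_of_nodes() == 0:
        raise ValueError(f"{path}: empty graph")
    return g


def load_kgml(path) -> nx.Graph:
    """Best-effort KGML (KEGG XML) reader producing a gene graph.

    Gene entries are labelled by the first token of their ``name``
    attribute (typically ``org:geneid``); relations between gene entries
    become undirected edges.  Group/compound semantics are not resolved —
    the canonical input for this package is the plain edge list.
    """
    import xml.etree.ElementTree as ET

    tree = ET.parse(path)
    root = tree.getroot()
    entry_label = {}
    for entry in root.findall("entry"):
        if entry.get("type") == "gene":
            name = (entry.get("name") or "").split()
            if name:
                entry_label[entry.get("id")] = name[0]
    g = nx.Graph()
    g.add_nodes_from(entry_label.values())
    for rel in root.findall("relation"):
        a = entry_label.get(rel.get("entry1"))
        b = entry_label.get(rel.get("entry2"))
        if a and b and a != b:
            g.add_edge(a, b)
    if g.number_of_nodes() == 0:
        raise ValueError(f"{path}: no gene entries found")
    return g


def relative_betweenness(graph: nx.Graph) -> pd.Series:
    """Relative betweenness centrality of every node, values in [0, 1].

    Uses Brandes shortest-path-counting accumulation.  Graphs with fewer
    than 3 nodes have a degenerate (n-1)(n-2)/2 normalizer; every
    centrality is then 0 by convention.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if graph.number_of_nodes() < 3:
        vals = {v: 0.0 for v in graph.nodes}
    else:
        vals = nx.betweenness_centrality(graph, normalized=True)
    s = pd.Series(vals, name="relative_betweenness")
    order = sorted(range(len(s)), key=lambda i: str(s.index[i]))
    return s.iloc[order]  # stable order even for mixed-type node labels


def rank_genes(centrality: pd.Series, k: int) -> list[str]:
    """Top-``k`` genes by descending centrality, ties broken lexicographically."""
    if k > len(centrality):
        raise ValueError(f"k={k} exceeds the {len(centrality)} graph nodes")
    order = sorted(centrality.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in order[:k]]


def ranking_table(graph: nx.Graph) -> pd.DataFrame:
    """Full ranking with tie groups (equal-centrality runs share a group id)."""
    cent = relative_betweenness(graph)
    ordered = rank_genes(cent, len(cent))
    vals = cent[ordered].to_numpy()
    tie_group = [0]
    for i in range(1, len(vals)):
        tie_group.append(tie_group[-1] + (vals[i] != vals[i - 1]))
    return pd.DataFrame(
        {
            "gene": ordered,
            "relative_betweenness": vals,
            "rank": range(1, len(vals) + 1),
            "tie_group": tie_group,
        }
    )
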