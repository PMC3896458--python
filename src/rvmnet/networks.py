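"""Term interaction networks (GO-map / Path-Net) and the Signal-Net gene
network with its centrality statistics.

The Signal-Net is the directed, relation-typed interaction graph induced on
the differentially expressed genes. Core genes are ranked by relative
betweenness centrality

    C'B(v) = 2/(n^2 - 3n + 2) * sum_{s != v != t} sigma_st(v) / sigma_st,

with sigma_st the number of shortest (unit-length) paths from s to t and
pairs with no path contributing 0. The normalization 2/((n-1)(n-2)) is the
undirected two-per-pair convention; applied to the directed graph (the
default mode, consistent with sink/source nodes having betweenness exactly
zero) it bounds values by 2 rather than 1.

"Degree" Ki is the distinct-neighbor count of the undirected projection —
not indegree + outdegree, which double-counts reciprocal partners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .diffexpr import DEGeneList
from .errors import InvalidInputError

logger = logging.getLogger(__name__)

RELATION_CODES = ("a", "ex", "b", "c", "ind", "inh", "u", "s")
# a activation, ex expression, b binding, c compound, ind indirect effect,
# inh inhibition, u ubiquitination, s state change
UNDIRECTED_RELATIONS = frozenset({"b"})

CENTRALITY_COLUMNS = [
    "gene_id", "betweenness", "degree", "indegree", "outdegree", "clustering", "style",
]


@dataclass
class InteractionEdgeList:
    """Directed gene-gene interactions with KEGG-style relation codes.

    Edges are (source, target, relation, directed) tuples; self-loops are
    rejected and duplicate (source, target, relation) triples dropped.
    """

    edges: list[tuple[str, str, str, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen, deduped = set(), []
        for src, tgt, rel, directed in self.edges:
            if src == tgt:
                raise InvalidInputError(f"self-loop on {src!r}")
            if rel not in RELATION_CODES:
                raise InvalidInputError(f"unknown relation code {rel!r} on edge {src}->{tgt}")
            key = (src, tgt, rel)
            if key in seen:
                continue
            seen.add(key)
            deduped.append((src, tgt, rel, bool(directed)))
        self.edges = deduped

    def __len__(self) -> int:
        return len(self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.edges, columns=["source", "target", "relation", "directed"]
        ).assign(direction=lambda d: d["directed"].map({True: "directed", False: "undirected"}))


@dataclass
class SignalNetwork:
    """Directed gene graph with up/down node styles.

    ``graph`` is a simple DiGraph; an undirected interaction contributes both
    orientations. Edge attribute ``relations`` keeps the set of relation
    codes supporting the edge.
    """

    graph: nx.DiGraph
    styles: dict[str, str]

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    def undirected(self) -> nx.Graph:
        return self.graph.to_undirected(as_view=False)


@dataclass
class TermGraph:
    """Undirected network of significant terms, node class in {up, down, both}."""

    graph: nx.Graph

    def node_class(self, term: str) -> str:
        return self.graph.nodes[term]["node_class"]


def build_term_network(records: pd.DataFrame, relations) -> TermGraph:
    """GO-map / Path-Net: significant terms as nodes, given term-term
    relations (pairs) as edges restricted to those nodes.

    A term significant in both the up and down batches gets class ``both``.
    Relations naming a term absent from *records* are skipped with a warning.
    """
    known = set(records["term_id"]) if len(records) else set()
    sig = records[records["significant"]] if len(records) else records
    classes: dict[str, set[str]] = {}
    for _, row in sig.iterrows():
        classes.setdefault(row["term_id"], set()).add(row["direction_class"])
    g = nx.Graph()
    for term, dirs in classes.items():
        g.add_node(term, node_class="both" if len(dirs) > 1 else next(iter(dirs)))
    for ta, tb in relations:
        if ta not in known or tb not in known:
            logger.warning("term relation (%s, %s) references unknown term; skipped", ta, tb)
            continue
        if ta in g and tb in g and ta != tb:
            g.add_edge(ta, tb)
    return TermGraph(graph=g)


def build_signal_net(edges: InteractionEdgeList, de: DEGeneList) -> SignalNetwork:
    """Induce the interaction graph on the DE genes.

    Keeps edges whose endpoints are both differentially expressed; node style
    comes from the DE direction. Isolated DE genes are not included. An empty
    intersection yields an empty network with a warning.
    """
    styles_all = dict(zip(de.selected["gene_id"], de.selected["direction"]))
    g = nx.DiGraph()
    for src, tgt, rel, directed in edges.edges:
        if src not in styles_all or tgt not in styles_all:
            continue
        pairs = [(src, tgt)] if directed else [(src, tgt), (tgt, src)]
        for u, v in pairs:
            if g.has_edge(u, v):
                g[u][v]["relations"].add(rel)
            else:
                g.add_edge(u, v, relations={rel})
    if g.number_of_nodes() == 0:
        logger.warning("no interaction edge connects two DE genes; Signal-Net is empty")
    styles = {node: styles_all[node] for node in g.nodes}
    return SignalNetwork(graph=g, styles=styles)


def degrees(net: SignalNetwork) -> pd.DataFrame:
    """Per-node distinct-neighbor degree Ki, indegree and outdegree.

    Indegree counts distinct source genes, outdegree distinct target genes;
    Ki counts distinct neighbors in the undirected projection, so a
    reciprocal partner is one neighbor.
    """
    und = net.undirected()
    rows = [
        {
            "gene_id": v,
            "degree": und.degree(v),
            "indegree": net.graph.in_degree(v),
            "outdegree": net.graph.out_degree(v),
        }
        for v in net.graph.nodes
    ]
    return pd.DataFrame(rows, columns=["gene_id", "degree", "indegree", "outdegree"])


def betweenness(net: SignalNetwork, mode: str = "directed") -> dict[str, float]:
    """Relative betweenness centrality C'B(v) with the 2/((n-1)(n-2)) scale.

    ``mode`` selects shortest paths on the directed graph (default) or on the
    undirected projection (each unordered pair counted once). Networks with
    fewer than 3 nodes get all-zero centralities with a warning.
    """
    if mode not in ("directed", "undirected"):
        raise InvalidInputError(f"mode must be 'directed' or 'undirected', got {mode!r}")
    nodes = list(net.graph.nodes)
    n = len(nodes)
    if n < 3:
        if n:
            logger.warning("betweenness normalization undefined for n=%d < 3; returning zeros", n)
        return {v: 0.0 for v in nodes}
    g = net.graph if mode == "directed" else net.undirected()
    raw = nx.betweenness_centrality(g, normalized=False)
    scale = 2.0 / ((n - 1) * (n - 2))
    return {v: raw[v] * scale for v in nodes}


def clustering_coefficient(net: SignalNetwork) -> dict[str, float]:
    """Watts-Strogatz local clustering on the undirected projection
    (2 * edges among neighbors / (Ki * (Ki - 1)); 0 when Ki < 2)."""
    return {v: float(c) for v, c in nx.clustering(net.undirected()).items()}


def rank_core_genes(net: SignalNetwork, mode: str = "directed") -> pd.DataFrame:
    """Full centrality table sorted by betweenness (descending).

    Ties break by degree descending, then gene id; one row per network node.
    """
    deg = degrees(net).set_index("gene_id")
    btw = betweenness(net, mode=mode)
    clust = clustering_coefficient(net)
    df = pd.DataFrame({
        "gene_id": list(net.graph.nodes),
        "betweenness": [btw[v] for v in net.graph.nodes],
        "degree": deg["degree"].reindex(net.graph.nodes).to_numpy(),
        "indegree": deg["indegree"].reindex(net.graph.nodes).to_numpy(),
        "outdegree": deg["outdegree"].reindex(net.graph.nodes).to_numpy(),
        "clustering": [clust[v] for v in net.graph.nodes],
        "style": [net.styles[v] for v in net.graph.nodes],
    })
    return df.sort_values(
        ["betweenness", "degree", "gene_id"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)[CENTRALITY_COLUMNS]
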