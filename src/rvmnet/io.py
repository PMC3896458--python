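"""Readers and writers for every on-disk format the pipeline touches.

Formats: expression TSV (first column gene id, header = sample ids), design
TSV (sample, group), GMT gene sets, interaction edge TSV (source, target,
relation, direction), term-relation TSV (term_a, term_b), stage result TSVs,
truth/manifest JSON, and GraphML / DOT graph exports.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .enrichment import GeneSetCollection
from .errors import ParseError
from .expression import GROUPS, ExpressionMatrix
from .networks import RELATION_CODES, InteractionEdgeList, SignalNetwork, TermGraph
from .simulate import SimTruth

logger = logging.getLogger(__name__)


# -- expression ----------------------------------------------------------

def write_expression(matrix: ExpressionMatrix, expr_path, design_path) -> None:
    df = matrix.intensities.copy()
    df.index.name = "gene_id"
    df.to_csv(expr_path, sep="\t", float_format="%.17g")  # lossless float round trip
    design = matrix.design.rename("group").rename_axis("sample")
    design.to_csv(design_path, sep="\t")


def read_expression(path, design_path) -> ExpressionMatrix:
    """Read an expression TSV + design TSV into a validated matrix."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - delegated message
        raise ParseError(f"cannot read expression table {path}: {exc}") from exc
    try:
        design_df = pd.read_csv(design_path, sep="\t")
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"cannot read design table {design_path}: {exc}") from exc
    if design_df.shape[1] < 2:
        raise ParseError(f"design table {design_path} needs columns sample, group")
    design = pd.Series(design_df.iloc[:, 1].values, index=design_df.iloc[:, 0].astype(str))
    bad = set(design.unique()) - set(GROUPS)
    if bad:
        raise ParseError(f"design table has unknown groups {sorted(bad)}")
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(non_numeric):
        raise ParseError(f"non-numeric intensity column(s): {list(non_numeric)}")
    from .errors import InvalidInputError
    try:
        return ExpressionMatrix(intensities=df.astype(float), design=design)
    except InvalidInputError as exc:
        raise ParseError(str(exc)) from exc


# -- gene sets (GMT) -----------------------------------------------------

def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(collection.terms):
            name, category, members = collection.terms[tid]
            fields = [tid, f"{name}|{category}", *sorted(members)]
            fh.write("\t".join(fields) + "\n")


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Parse a GMT file (term, description, members...).

    The description field may carry ``name|category``; otherwise the category
    defaults to ``GO``. Duplicate members within a term are deduplicated with
    a warning. The universe defaults to the union of all members.
    """
    terms: dict[str, tuple[str, str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            tid, desc, members = fields[0], fields[1], fields[2:]
            if tid in terms:
                raise ParseError(f"{path}:{lineno}: duplicate term id {tid!r}")
            if len(set(members)) != len(members):
                logger.warning("%s:%d: duplicate members in term %s deduplicated",
                               path, lineno, tid)
            name, _, category = desc.partition("|")
            terms[tid] = (name or tid, category or "GO", frozenset(members))
    uni = frozenset(universe) if universe is not None else \
        frozenset().union(*(m for _, _, m in terms.values())) if terms else frozenset()
    return GeneSetCollection(terms=terms, universe=uni)


# -- interaction edges ---------------------------------------------------

def write_edges(edges: InteractionEdgeList, path) -> None:
    edges.to_frame()[["source", "target", "relation", "direction"]].to_csv(
        path, sep="\t", index=False
    )


def read_edges(path) -> InteractionEdgeList:
    """Edge TSV with columns source, target, relation, direction."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"source", "target", "relation", "direction"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: edge table needs columns {sorted(required)}")
    records = []
    for i, row in df.iterrows():
        if row["relation"] not in RELATION_CODES:
            raise ParseError(f"{path}: row {i + 2}: unknown relation code {row['relation']!r}")
        if row["direction"] not in ("directed", "undirected"):
            raise ParseError(f"{path}: row {i + 2}: direction must be directed|undirected")
        records.append((row["source"], row["target"], row["relation"],
                        row["direction"] == "directed"))
    return InteractionEdgeList(edges=records)


def write_term_relations(relations, path) -> None:
    pd.DataFrame(relations, columns=["term_a", "term_b"]).to_csv(path, sep="\t", index=False)


def read_term_relations(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"term_a", "term_b"} <= set(df.columns):
        raise ParseError(f"{path}: term relation table needs columns term_a, term_b")
    return [(a, b) for a, b in zip(df["term_a"], df["term_b"])]


# -- truth / tables ------------------------------------------------------

def write_truth(truth: SimTruth, path) -> None:
    payload = {
        "de_signs": dict(sorted(truth.de_signs.items())),
        "enriched_term_directions": dict(sorted(truth.enriched_term_directions.items())),
        "hub_genes": sorted(truth.hub_genes),
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_truth(path) -> SimTruth:
    payload = json.loads(Path(path).read_text())
    return SimTruth(
        de_signs={g: int(s) for g, s in payload["de_signs"].items()},
        enriched_term_directions=dict(payload["enriched_term_directions"]),
        hub_genes=set(payload["hub_genes"]),
    )


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# -- graph exports -------------------------------------------------------

def _attributed_graph(net: SignalNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    for v in net.graph.nodes:
        g.add_node(v, style=net.styles[v])
    for u, v, data in net.graph.edges(data=True):
        g.add_edge(u, v, relation=",".join(sorted(data["relations"])))
    return g


def export_graphml(graph: SignalNetwork | TermGraph, path) -> None:
    if isinstance(graph, SignalNetwork):
        nx.write_graphml(_attributed_graph(graph), path)
    else:
        nx.write_graphml(graph.graph, path)


def export_dot(graph: SignalNetwork | TermGraph, path) -> None:
    """Minimal DOT writer with node style / class and edge relation attrs."""
    lines = []
    if isinstance(graph, SignalNetwork):
        lines.append("digraph signalnet {")
        for v in sorted(graph.graph.nodes):
            lines.append(f'  "{v}" [style="{graph.styles[v]}"];')
        for u, v, data in sorted(graph.graph.edges(data=True)):
            rel = ",".join(sorted(data["relations"]))
            lines.append(f'  "{u}" -> "{v}" [relation="{rel}"];')
    else:
        lines.append("graph termnet {")
        for v in sorted(graph.graph.nodes):
            lines.append(f'  "{v}" [class="{graph.graph.nodes[v]["node_class"]}"];')
        for u, v in sorted(graph.graph.edges):
            lines.append(f'  "{u}" -- "{v}";')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
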