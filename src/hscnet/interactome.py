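"""Protein-interaction network model and HSC-expressed subnetwork projection.

A disease interactome (e.g. an ataxia or autism protein-interaction network)
is an undirected simple graph over gene symbols. The projection keeps every
interaction with at least one endpoint expressed in the cell type of interest
and classes each retained node:

* ``fingerprint`` — in the cell-type-specific fingerprint set (highest
  precedence),
* ``expressed`` — expressed but not fingerprint,
* ``partner`` — retained only because it interacts with an expressed node.

Node degree is computed within the projected subnetwork (its "connectedness").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .core_sets import GeneSet, _normalizer

log = logging.getLogger(__name__)

__all__ = [
    "Interactome", "Subnetwork",
    "read_edges", "project_subnetwork", "node_degrees",
    "write_graph", "read_graphml",
]

NODE_CLASSES = ("fingerprint", "expressed", "partner")


@dataclass(frozen=True)
class Interactome:
    """Undirected simple graph of protein-protein interactions."""

    graph: nx.Graph
    name: str = "interactome"

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}


@dataclass(frozen=True)
class Subnetwork:
    """Projection result; node attributes ``node_class`` and ``degree``."""

    graph: nx.Graph
    parent_name: str = "interactome"

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def classes(self) -> dict[str, str]:
        return dict(self.graph.nodes(data="node_class"))


def read_edges(path, format: str | None = None, policy: str = "upper",
               name: str | None = None) -> Interactome:
    """Read an interactome from SIF or two-column TSV.

    SIF lines are ``A relation B [C ...]`` (whitespace-delimited; the relation
    fans out to every trailing node). Reversed duplicates collapse to one
    undirected edge; self-loops are dropped with a warning. Symbols are
    normalized per ``policy``.
    """
    path = Path(path)
    if format is None:
        format = "SIF" if path.suffix.lower() == ".sif" else "TSV"
    format = format.upper()
    if format not in ("SIF", "TSV"):
        raise ValueError(f"unknown edge format {format!r}")
    norm = _normalizer(policy)
    g = nx.Graph()
    dropped_loops = 0
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if format == "SIF":
                fields = line.split()
                if len(fields) == 1:
                    g.add_node(norm(fields[0]))  # isolated node, legal SIF
                    continue
                if len(fields) < 3:
                    raise ValueError(f"line {lineno}: SIF needs 'A relation B "
                                     "[C ...]'")
                src, rel, targets = norm(fields[0]), fields[1], fields[2:]
            else:
                fields = line.split("\t")
                if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                    raise ValueError(f"line {lineno}: expected 2 tab-separated "
                                     "columns")
                src, rel, targets = norm(fields[0].strip()), "pp", [fields[1].strip()]
            for t in targets:
                tgt = norm(t)
                if tgt == src:
                    dropped_loops += 1
                    continue
                g.add_edge(src, tgt, relation=rel)
    if dropped_loops:
        log.warning("read_edges(%s): dropped %d self-loop(s)", path, dropped_loops)
    return Interactome(graph=g, name=name or path.stem)


def project_subnetwork(net: Interactome, expressed: GeneSet,
                       fingerprint: GeneSet | None = None) -> Subnetwork:
    """Induce the subnetwork of edges touching an expressed (or fingerprint) gene.

    Edge retention uses expressed | fingerprint (fingerprint genes are
    expressed by definition; a warning is emitted if the inputs disagree).
    Node classes follow the precedence fingerprint > expressed > partner, and
    degrees are recomputed within the subnetwork.
    """
    fp = frozenset() if fingerprint is None else fingerprint.symbols
    if fingerprint is not None and not fp <= expressed.symbols:
        log.warning("fingerprint set %s is not a subset of expressed set %s; "
                    "using their union for edge retention",
                    fingerprint.name, expressed.name)
    keep = expressed.symbols | fp
    if not keep:
        log.warning("empty expressed set: projection is empty")
    sub = nx.Graph()
    for u, v, data in net.graph.edges(data=True):
        if u in keep or v in keep:
            sub.add_edge(u, v, **data)
    for node in sub.nodes:
        if node in fp:
            cls = "fingerprint"
        elif node in expressed.symbols:
            cls = "expressed"
        else:
            cls = "partner"
        sub.nodes[node]["node_class"] = cls
    for node, deg in sub.degree():
        sub.nodes[node]["degree"] = int(deg)
    return Subnetwork(graph=sub, parent_name=net.name)


def node_degrees(sub: Subnetwork) -> dict[str, int]:
    """Degree of each node within the subnetwork (sums to 2x edge count)."""
    return {node: int(deg) for node, deg in sub.graph.degree()}


def write_graph(sub: Subnetwork, path, format: str | None = None) -> None:
    """Export a subnetwork.

    GraphML carries ``node_class`` and ``degree`` node attributes and
    round-trips exactly through :func:`read_graphml`. SIF/TSV write the edge
    list (relation ``pp`` for SIF) plus a ``<stem>.nodes.tsv`` sidecar with
    node attributes.
    """
    path = Path(path)
    if format is None:
        format = {".graphml": "GraphML", ".sif": "SIF"}.get(
            path.suffix.lower(), "TSV")
    fmt = format.upper()
    if fmt == "GRAPHML":
        nx.write_graphml(sub.graph, path)
        return
    if fmt not in ("SIF", "TSV"):
        raise ValueError(f"unknown graph format {format!r}")
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in sub.graph.edges):
            if fmt == "SIF":
                fh.write(f"{u} pp {v}\n")
            else:
                fh.write(f"{u}\t{v}\n")
    sidecar = path.with_suffix(path.suffix + ".nodes.tsv")
    write_node_table(sub, sidecar)


def write_node_table(sub: Subnetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node\tnode_class\tdegree\n")
        for node in sorted(sub.graph.nodes):
            data = sub.graph.nodes[node]
            fh.write(f"{node}\t{data['node_class']}\t{data['degree']}\n")


def read_graphml(path, parent_name: str = "interactome") -> Subnetwork:
    g = nx.read_graphml(path)
    g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    for node in g.nodes:
        if "degree" in g.nodes[node]:
            g.nodes[node]["degree"] = int(g.nodes[node]["degree"])
    return Subnetwork(graph=g, parent_name=parent_name)
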