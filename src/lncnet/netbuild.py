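"""Heterogeneous lncRNA/mRNA/TF network assembly and Cytoscape-readable export.

Three builders mirror the study's three views: the bipartite lncRNA-mRNA
coexpression network seeded on the top differential lncRNAs, the bipartite
TF->lncRNA regulation network from enrichment ranking, and the tripartite
lncRNA-target-TF network restricted to each lncRNA's lowest-p partners.
Coexpression edges carry the Pearson r they were selected by; TF edges
carry the enrichment p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from lncnet.coexpress import CorrelationEdge

logger = logging.getLogger(__name__)

NODE_TYPES = ("lncRNA", "mRNA", "TF")
EDGE_TYPES = ("coexpr_pos", "coexpr_neg", "tf_regulates_lnc", "lnc_targets_mrna")

# endpoint-type contract per edge type: (source type, target type)
_EDGE_ENDPOINTS = {
    "coexpr_pos": ("lncRNA", "mRNA"),
    "coexpr_neg": ("lncRNA", "mRNA"),
    "tf_regulates_lnc": ("TF", "lncRNA"),
    "lnc_targets_mrna": ("lncRNA", "mRNA"),
}

NodeKey = tuple[str, str]  # (id, node_type); identity is id + type
EdgeKey = tuple[NodeKey, NodeKey, str]


@dataclass
class TypedGraph:
    """Simple typed graph: no duplicate (source, target, edge_type) triples.

    Parallel edges of different types between the same endpoints are
    allowed; node identity is resolved by (id, node_type), so a TF sharing
    a name with an mRNA symbol stays a distinct node.
    """

    nodes: dict[NodeKey, None] = field(default_factory=dict)  # insertion-ordered set
    edges: dict[EdgeKey, float] = field(default_factory=dict)  # -> weight

    def add_node(self, node_id: str, node_type: str) -> NodeKey:
        if node_type not in NODE_TYPES:
            raise ValueError(f"node_type must be in {NODE_TYPES}, got {node_type!r}")
        key = (node_id, node_type)
        self.nodes.setdefault(key, None)
        return key

    def add_edge(self, source: NodeKey, target: NodeKey, edge_type: str, weight: float) -> None:
        if edge_type not in EDGE_TYPES:
            raise ValueError(f"edge_type must be in {EDGE_TYPES}, got {edge_type!r}")
        st, tt = _EDGE_ENDPOINTS[edge_type]
        if source[1] != st or target[1] != tt:
            raise ValueError(
                f"{edge_type} edges connect {st}->{tt}, got {source[1]}->{target[1]}"
            )
        if source not in self.nodes or target not in self.nodes:
            raise ValueError("edge endpoints must be added as nodes first")
        self.edges[(source, target, edge_type)] = float(weight)

    # -- summaries -------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_type_counts(self) -> dict[str, int]:
        out = {t: 0 for t in EDGE_TYPES}
        for (_, _, et) in self.edges:
            out[et] += 1
        return out

    def degree(self, node_id: str, node_type: str) -> int:
        key = (node_id, node_type)
        return sum(1 for (s, t, _) in self.edges if s == key or t == key)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TypedGraph):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and self.edges == other.edges

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for (nid, ntype) in self.nodes:
            g.add_node(f"{ntype}::{nid}", node_id=nid, node_type=ntype)
        for (s, t, et), w in self.edges.items():
            g.add_edge(f"{s[1]}::{s[0]}", f"{t[1]}::{t[0]}", key=et, edge_type=et, weight=w)
        return g


def build_lnc_mrna_network(
    top_lnc: Iterable[str], edges: Sequence[CorrelationEdge]
) -> TypedGraph:
    """Coexpression network restricted to edges incident to the seed lncRNAs.

    Seed lncRNAs appear as nodes even when none of their edges survived;
    mRNA nodes are added on first incident edge.  Positive/negative r maps
    to the solid/dotted edge classes of the study's figures.
    """
    g = TypedGraph()
    seeds = list(dict.fromkeys(top_lnc))
    for lnc in seeds:
        g.add_node(lnc, "lncRNA")
    seed_set = set(seeds)
    if not edges:
        logger.warning("empty coexpression edge set: network has no edges")
    for e in edges:
        if e.lnc_id not in seed_set:
            continue
        src = (e.lnc_id, "lncRNA")
        dst = g.add_node(e.mrna_id, "mRNA")
        et = "coexpr_pos" if e.sign == "positive" else "coexpr_neg"
        g.add_edge(src, dst, et, e.r)
    return g


def build_lnc_tf_network(pairs: Sequence[tuple[str, str, float]]) -> TypedGraph:
    """Bipartite TF -> lncRNA regulation network from (lnc, TF, p) pairs."""
    g = TypedGraph()
    for lnc, tf, p in pairs:
        src = g.add_node(tf, "TF")
        dst = g.add_node(lnc, "lncRNA")
        g.add_edge(src, dst, "tf_regulates_lnc", p)
    return g


def build_lnc_target_tf_network(
    top_lnc: Iterable[str],
    edges: Sequence[CorrelationEdge],
    pairs: Sequence[tuple[str, str, float]],
    k_mrna: int = 2,
    k_tf: int = 2,
) -> TypedGraph:
    """Tripartite network of each lncRNA's lowest-p mRNA and TF partners.

    Per lncRNA: its ``k_mrna`` lowest-p coexpression edges become
    lnc->mRNA target edges (weight r) and its ``k_tf`` lowest-p TF pairs
    become TF->lnc edges (weight p).  A lncRNA missing from either source
    is included with whatever edges it has.
    """
    if k_mrna < 0 or k_tf < 0:
        raise ValueError("k_mrna and k_tf must be non-negative")
    g = TypedGraph()
    by_lnc_edges: dict[str, list[CorrelationEdge]] = {}
    for e in edges:
        by_lnc_edges.setdefault(e.lnc_id, []).append(e)
    by_lnc_pairs: dict[str, list[tuple[str, str, float]]] = {}
    for lnc, tf, p in pairs:
        by_lnc_pairs.setdefault(lnc, []).append((lnc, tf, p))

    for lnc in dict.fromkeys(top_lnc):
        src = g.add_node(lnc, "lncRNA")
        best_m = sorted(
            by_lnc_edges.get(lnc, ()), key=lambda e: (e.p_value, -abs(e.r), e.mrna_id)
        )[:k_mrna]
        best_t = sorted(by_lnc_pairs.get(lnc, ()), key=lambda x: (x[2], x[1]))[:k_tf]
        if not best_m and not best_t:
            logger.warning("lncRNA %s has no partners in either source", lnc)
        for e in best_m:
            dst = g.add_node(e.mrna_id, "mRNA")
            g.add_edge(src, dst, "lnc_targets_mrna", e.r)
        for _, tf, p in best_t:
            tfn = g.add_node(tf, "TF")
            g.add_edge(tfn, src, "tf_regulates_lnc", p)
    return g


# -- export / import ----------------------------------------------------------

_FORMATS = ("sif", "graphml", "tsv")


def export_graph(g: TypedGraph, path, format: str) -> None:
    """Write SIF, GraphML, or edge-TSV.

    Edge-TSV and GraphML round-trip losslessly (node and edge attributes
    preserved; float weights written with shortest-round-trip repr).  SIF
    carries the edge type as the interaction label and lists isolated
    nodes on single-column lines.
    """
    fmt = format.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
    if fmt == "sif":
        _write_sif(g, path)
    elif fmt == "graphml":
        nx.write_graphml(g.to_networkx(), path, named_key_ids=True)
    else:
        _write_edge_tsv(g, path)


def import_graph(path, format: str) -> TypedGraph:
    fmt = format.lower()
    if fmt == "tsv":
        return _read_edge_tsv(path)
    if fmt == "graphml":
        return _from_networkx(nx.read_graphml(path, force_multigraph=True))
    raise ValueError(f"import supports tsv and graphml, not {format!r}")


def _isolated(g: TypedGraph) -> list[NodeKey]:
    touched = {n for (s, t, _) in g.edges for n in (s, t)}
    return [n for n in g.nodes if n not in touched]


def _write_sif(g: TypedGraph, path) -> None:
    with open(path, "w") as fh:
        for (s, t, et), _ in g.edges.items():
            fh.write(f"{s[0]}\t{et}\t{t[0]}\n")
        for (nid, _) in _isolated(g):
            fh.write(f"{nid}\n")


_TSV_HEADER = "source\tsource_type\tinteraction\ttarget\ttarget_type\tweight"


def _write_edge_tsv(g: TypedGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for (s, t, et), w in g.edges.items():
            fh.write(f"{s[0]}\t{s[1]}\t{et}\t{t[0]}\t{t[1]}\t{w!r}\n")
        for (nid, ntype) in _isolated(g):
            fh.write(f"{nid}\t{ntype}\t\t\t\t\n")


def _read_edge_tsv(path) -> TypedGraph:
    g = TypedGraph()
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _TSV_HEADER:
            raise ValueError(f"unexpected edge-TSV header: {header!r}")
        for line in fh:
            src, st, et, dst, tt, w = line.rstrip("\n").split("\t")
            if et == "":  # isolated-node row
                g.add_node(src, st)
                continue
            a = g.add_node(src, st)
            b = g.add_node(dst, tt)
            g.add_edge(a, b, et, float(w))
    return g


def _from_networkx(nxg: nx.MultiDiGraph) -> TypedGraph:
    g = TypedGraph()
    for _, data in nxg.nodes(data=True):
        g.add_node(data["node_id"], data["node_type"])
    for u, v, data in nxg.edges(data=True):
        s = (nxg.nodes[u]["node_id"], nxg.nodes[u]["node_type"])
        t = (nxg.nodes[v]["node_id"], nxg.nodes[v]["node_type"])
        g.add_edge(s, t, data["edge_type"], float(data["weight"]))
    return g
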