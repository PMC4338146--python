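"""Confidence-weighted interactomes and query-centric "zooming" subgraphs.

The interactome is an undirected gene graph with per-edge confidence scores
on a 0-1 scale (STRING-style combined scores; integer 0-1000 scores can be
rescaled on load).  Only high-confidence edges (strictly above a threshold,
0.7 by default) are retained.

Given a query gene list, three zooming levels extract nested neighborhoods:

* **L1** — the query genes plus every gene with at least one interaction
  with a query gene;
* **L2** — the query genes plus genes interacting with at least two
  distinct query genes;
* **L3** — the query genes only ("query network": direct interactions
  between query genes).

Edges at every level are those of the induced subgraph on the selected
nodes.  Connected components are reported largest-first.
"""
from __future__ import annotations

import dataclasses
import enum
import json
from collections.abc import Iterable
from pathlib import Path

import networkx as nx

from .annotation import canonical_gene
from .sieve import GeneList

#: Default STRING-style high-confidence threshold (strictly greater-than).
DEFAULT_THRESHOLD = 0.7


class EdgeFormatError(ValueError):
    """Malformed or invalid interaction edge data."""


class ZoomLevel(enum.Enum):
    L1 = 1
    L2 = 2
    L3 = 3

    @classmethod
    def coerce(cls, level) -> "ZoomLevel":
        if isinstance(level, cls):
            return level
        if isinstance(level, int):
            return cls(level)
        return cls[str(level).upper()]


class InteractionGraph:
    """Undirected gene graph with confidence-scored edges.

    Node ids are canonical gene ids; no self-loops; one edge per pair
    (duplicates collapse to the maximum confidence).
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    def add_edge(self, gene_a: str, gene_b: str, confidence: float) -> None:
        a, b = canonical_gene(gene_a), canonical_gene(gene_b)
        if a == b:
            return  # self-interactions carry no zooming information
        if not 0.0 <= confidence <= 1.0:
            raise EdgeFormatError(
                f"confidence {confidence} outside [0, 1] for ({gene_a}, {gene_b})"
            )
        if self.graph.has_edge(a, b):
            confidence = max(confidence, self.graph.edges[a, b]["confidence"])
        self.graph.add_edge(a, b, confidence=confidence)

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def confidence(self, gene_a: str, gene_b: str) -> float:
        return self.graph.edges[canonical_gene(gene_a), canonical_gene(gene_b)][
            "confidence"
        ]

    def neighbors(self, gene: str) -> set:
        g = canonical_gene(gene)
        return set(self.graph.neighbors(g)) if g in self.graph else set()

    def __contains__(self, gene: str) -> bool:
        return canonical_gene(gene) in self.graph

    def __repr__(self) -> str:
        return f"<InteractionGraph {self.graph.number_of_nodes()} nodes, {self.n_edges} edges>"


def load_edges(
    path: str | Path,
    threshold: float = DEFAULT_THRESHOLD,
    rescale_string_scores: bool = False,
) -> InteractionGraph:
    """Load a TSV edge list ``gene_a<TAB>gene_b<TAB>confidence``.

    Edges with confidence strictly greater than `threshold` are retained;
    ids are canonicalized; duplicate pairs collapse to the maximum
    confidence.  With `rescale_string_scores`, integer 0-1000 combined
    scores are divided by 1000 before thresholding.
    """
    if not 0.0 <= threshold <= 1.0:
        raise EdgeFormatError(f"threshold {threshold} outside [0, 1]")
    graph = InteractionGraph()
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise EdgeFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields"
                )
            a, b, raw = fields
            try:
                conf = float(raw)
            except ValueError:
                raise EdgeFormatError(
                    f"{path}:{lineno}: bad confidence {raw!r}"
                ) from None
            if rescale_string_scores:
                conf /= 1000.0
            if not 0.0 <= conf <= 1.0:
                raise EdgeFormatError(
                    f"{path}:{lineno}: confidence {conf} outside [0, 1]"
                )
            if conf > threshold:
                graph.add_edge(a, b, conf)
    return graph


@dataclasses.dataclass
class ZoomResult:
    """A zooming-level subgraph with its connected components."""

    level: ZoomLevel
    query_genes: frozenset
    subgraph: nx.Graph

    @property
    def node_set(self) -> set:
        return set(self.subgraph.nodes)

    @property
    def edge_set(self) -> set:
        return {frozenset(e) for e in self.subgraph.edges}

    @property
    def components(self) -> list[tuple[set, int]]:
        return components(self)

    def summary(self) -> dict:
        comps = components(self)
        return {
            "level": self.level.name,
            "n_query_genes": len(self.query_genes),
            "n_nodes": self.subgraph.number_of_nodes(),
            "n_edges": self.subgraph.number_of_edges(),
            "component_sizes": [size for _, size in comps],
            "components": [sorted(nodes) for nodes, _ in comps],
        }


def zoom(graph: InteractionGraph, query, level) -> ZoomResult:
    """Extract the zooming-level subgraph for a query gene set.

    `query` may be a :class:`GeneList` or any iterable of gene ids; the
    node set is the query genes present in the graph plus, at L1/L2,
    non-query genes with at least one / at least two distinct query
    neighbors.  Edges are those of the induced subgraph.
    """
    level = ZoomLevel.coerce(level)
    if isinstance(query, GeneList):
        qset = set(query.members)
    else:
        qset = {canonical_gene(g) for g in query}
    if not qset:
        raise ValueError("query gene set is empty")
    present = qset & graph.nodes
    selected = set(present)
    if level is not ZoomLevel.L3:
        needed = 1 if level is ZoomLevel.L1 else 2
        counts: dict[str, int] = {}
        for q in present:
            for nb in graph.graph.neighbors(q):
                if nb not in qset:
                    counts[nb] = counts.get(nb, 0) + 1
        selected |= {g for g, c in counts.items() if c >= needed}
    sub = graph.graph.subgraph(selected).copy()
    return ZoomResult(level=level, query_genes=frozenset(qset), subgraph=sub)


def seed_zoom(
    graph: InteractionGraph, genes: GeneList, seed_gene: str, level
) -> ZoomResult:
    """Per-gene zoom: query = the seed gene plus its direct partners within
    `genes` (its L3 neighborhood in the list), then zoom at `level`.

    This mirrors exploring the neighborhood network of a single gene of
    interest together with the list members it directly interacts with.
    """
    seed = canonical_gene(seed_gene)
    partners = graph.neighbors(seed) & set(genes.members)
    query = GeneList(
        name=f"{seed}+partners",
        members=frozenset({seed}) | frozenset(partners),
        provenance=f"seed-zoom({seed})",
    )
    return zoom(graph, query, level)


def components(result: ZoomResult) -> list[tuple[set, int]]:
    """Connected components, sorted by decreasing size then by smallest
    member id (lexicographic tie-break)."""
    comps = [set(c) for c in nx.connected_components(result.subgraph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return [(c, len(c)) for c in comps]


# -- exports ---------------------------------------------------------------

def write_sif(result: ZoomResult, path: str | Path, relation: str = "pp") -> None:
    """Simple interaction format: ``a<TAB>pp<TAB>b``; isolated nodes on
    their own line."""
    g = result.subgraph
    with Path(path).open("w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for node in sorted(g.nodes):
            if g.degree(node) == 0:
                fh.write(f"{node}\n")


def write_graphml(result: ZoomResult, path: str | Path) -> None:
    g = result.subgraph.copy()
    for node in g.nodes:
        g.nodes[node]["is_query"] = node in result.query_genes
    nx.write_graphml(g, str(path))


def write_component_summary(result: ZoomResult, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(result.summary(), indent=2) + "\n", encoding="utf-8"
    )
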