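"""Disease term DAG: the ancestry structure behind semantic similarity.

Diseases are terms in a directed acyclic graph (MeSH-descriptor style)
whose edges point from a child term to its parents.  Semantic similarity
between two diseases is driven by the overlap of their ancestor closures,
so the container exposes exactly that: per-term parents, children, and
the ancestor closure T(D) (which includes D itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx


class DAGCycleError(ValueError):
    """Raised when the supplied term hierarchy contains a directed cycle."""


@dataclass
class DiseaseDAG:
    """Term hierarchy with child->parent edges, validated acyclic."""

    terms: list[str]
    parent_edges: list[tuple[str, str]]  # (child, parent)
    _graph: nx.DiGraph = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.terms = list(self.terms)
        term_set = set(self.terms)
        if len(term_set) != len(self.terms):
            raise ValueError("duplicate term identifiers in DAG term list")
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parent in self.parent_edges:
            for t in (child, parent):
                if t not in term_set:
                    raise KeyError(f"edge references unknown term: {t!r}")
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
            raise DAGCycleError(f"term hierarchy contains a cycle: {path}")
        self._graph = g

    @property
    def roots(self) -> list[str]:
        """Terms with no parents, in term-list order."""
        return [t for t in self.terms if self._graph.out_degree(t) == 0]

    def parents(self, term: str) -> list[str]:
        self._check(term)
        return sorted(self._graph.successors(term))

    def children(self, term: str) -> list[str]:
        self._check(term)
        return sorted(self._graph.predecessors(term))

    def ancestor_closure(self, term: str) -> set[str]:
        """T(term): the term itself plus every ancestor reachable via parent edges."""
        self._check(term)
        return {term} | nx.descendants(self._graph, term)

    def _check(self, term: str) -> None:
        if term not in self._graph:
            raise KeyError(f"unknown term: {term!r}")

    def __contains__(self, term: str) -> bool:
        return term in self._graph
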