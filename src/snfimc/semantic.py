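"""Disease semantic similarity from a term DAG.

Each disease D contributes a decayed score DD(d) to every ancestor term
d in its closure T(D): the disease itself contributes 1, and each
ancestor contributes ``delta`` times the largest contribution among its
children that lie on a path back to D.  The semantic value
DV(D) = sum of DD over T(D) measures how specific the disease is, and
the similarity of two diseases is the contribution mass they share:

    DS(di, dj) = sum_{t in T(di) & T(dj)} (DD_di(t) + DD_dj(t))
                 -------------------------------------------------
                               DV(di) + DV(dj)

With the default decay delta = 0.5, shallower shared ancestors count
for less, so diseases meeting only at a generic root term are weakly
similar while siblings under a specific term are strongly similar.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .containers import SimilarityMatrix
from .dag import DiseaseDAG

#: default semantic contribution (decay) factor
DEFAULT_DELTA = 0.5


def _check_delta(delta: float) -> None:
    if not (0.0 < delta <= 1.0):
        raise ValueError(f"delta must lie in (0, 1], got {delta}")


def ancestor_closure(dag: DiseaseDAG, d: str) -> set[str]:
    """T(d): the term itself plus all ancestors reachable via parent edges."""
    return dag.ancestor_closure(d)


def contribution_scores(
    dag: DiseaseDAG, disease: str, delta: float = DEFAULT_DELTA
) -> dict[str, float]:
    """Contribution DD(d) of every ancestor term d in T(disease).

    DD(disease) = 1; every other ancestor gets delta times the maximum
    contribution among its children that lie inside the closure, so only
    paths leading back to the disease carry contribution.
    """
    _check_delta(delta)
    closure = dag.ancestor_closure(disease)
    # children before parents: order closure terms by longest path from the disease
    sub = dag._graph.subgraph(closure)
    order = list(nx.topological_sort(sub))  # edges child->parent, so disease first
    dd: dict[str, float] = {}
    for term in order:
        if term == disease:
            dd[term] = 1.0
        else:
            dd[term] = delta * max(dd[c] for c in sub.predecessors(term))
    return dd


def semantic_value(dag: DiseaseDAG, disease: str, delta: float = DEFAULT_DELTA) -> float:
    """DV(disease): total contribution over the ancestor closure (>= 1)."""
    return float(sum(contribution_scores(dag, disease, delta).values()))


def semantic_similarity_matrix(
    dag: DiseaseDAG, diseases: list[str], delta: float = DEFAULT_DELTA
) -> SimilarityMatrix:
    """Pairwise semantic similarity DS over an ordered disease list.

    The diagonal is exactly 1; diseases with disjoint ancestor closures
    get similarity 0.
    """
    _check_delta(delta)
    contribs = [contribution_scores(dag, d, delta) for d in diseases]
    dvs = [sum(c.values()) for c in contribs]
    n = len(diseases)
    values = np.eye(n)
    for i in range(n):
        ci = contribs[i]
        for j in range(i + 1, n):
            cj = contribs[j]
            shared = ci.keys() & cj.keys()
            if shared:
                num = sum(ci[t] + cj[t] for t in shared)
                values[i, j] = values[j, i] = num / (dvs[i] + dvs[j])
    return SimilarityMatrix(values, list(diseases), view_name="semantic")
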