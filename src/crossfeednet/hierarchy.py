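"""Hierarchy metrics for directed graphs: orderability, feedforwardness,
and treeness on the node-weighted condensation.

The three indices diagnose how far a directed network is from a clean
top-down "supply chain" and how much of it sits inside feedback loops:

orderability ``O``
    Fraction of nodes outside any directed feedback loop, i.e. nodes in
    acyclic singleton strongly connected components.  1 means no loops at
    all; 0 means every node sits on a cycle.
feedforwardness ``F``
    Mean, over all maximal-to-minimal paths of the condensation, of the
    path's node count divided by the summed SCC sizes along it.  1 on a
    DAG; small when large cycles sit on the paths.
treeness ``T``
    Entropy-based asymmetry between forward (top-down) and backward
    (bottom-up) path uncertainty, averaged over a leaf-removal sequence
    of the condensation.  +1 for a pyramid (out-star), -1 for an inverted
    pyramid, 0 for chains and other direction-symmetric graphs.

Forward entropy ``H_f`` is the mean over maximal (in-degree 0) nodes of
``h(v)``, where ``h(v) = 0`` for sinks and otherwise
``h(v) = log2 k_out(v) + mean over successors of h``; this equals the
Shannon entropy of the distribution over root-to-sink paths induced by
uniform branching.  ``H_b`` is the same on the edge-reversed DAG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import networkx as nx
import numpy as np

__all__ = [
    "Condensation",
    "HierarchyReport",
    "condense",
    "orderability",
    "path_entropies",
    "treeness",
    "feedforwardness",
    "hierarchy_report",
]

#: feedforwardness aborts (rather than silently sampling) beyond this
#: many maximal-to-minimal condensation paths
MAX_PATHS = 100_000


def _digraph(obj) -> nx.DiGraph:
    return obj.graph if hasattr(obj, "graph") and isinstance(getattr(obj, "graph"), nx.DiGraph) else obj


@dataclass
class Condensation:
    """Acyclic quotient of a digraph by its strongly connected components."""

    dag: nx.DiGraph  # nodes are SCC ids with attributes alpha (size), cyclic
    members: dict[int, frozenset]
    mapping: dict  # original node -> SCC id

    @property
    def alpha(self) -> dict[int, int]:
        return {v: self.dag.nodes[v]["alpha"] for v in self.dag.nodes}

    @property
    def maximal(self) -> list[int]:
        return [v for v in self.dag.nodes if self.dag.in_degree(v) == 0]

    @property
    def minimal(self) -> list[int]:
        return [v for v in self.dag.nodes if self.dag.out_degree(v) == 0]

    @property
    def n_original(self) -> int:
        return sum(self.dag.nodes[v]["alpha"] for v in self.dag.nodes)


def condense(graph) -> Condensation:
    """Condensation with SCC sizes and cyclicity flags.

    A singleton SCC counts as cyclic when its node carries a self-loop;
    self-loop edges are dropped from the induced DAG.
    """
    g = _digraph(graph)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot condense an empty graph")
    cond = nx.condensation(g)  # acyclic; nodes carry 'members'
    dag = nx.DiGraph()
    members: dict[int, frozenset] = {}
    mapping = dict(cond.graph["mapping"])
    for v in cond.nodes:
        mem = frozenset(cond.nodes[v]["members"])
        members[v] = mem
        cyclic = len(mem) >= 2 or any(g.has_edge(u, u) for u in mem)
        dag.add_node(v, alpha=len(mem), cyclic=cyclic)
    dag.add_edges_from(cond.edges)
    return Condensation(dag, members, mapping)


def orderability(graph) -> float:
    """Fraction of nodes in acyclic singleton SCCs."""
    cond = condense(graph)
    total = cond.n_original
    outside = sum(
        1 for v in cond.dag.nodes
        if cond.dag.nodes[v]["alpha"] == 1 and not cond.dag.nodes[v]["cyclic"]
    )
    return outside / total


def _node_entropies(dag: nx.DiGraph) -> dict:
    h: dict = {}
    for v in reversed(list(nx.topological_sort(dag))):
        succ = list(dag.successors(v))
        if not succ:
            h[v] = 0.0
        else:
            k = len(succ)
            h[v] = float(np.log2(k) + sum(h[u] for u in succ) / k)
    return h


def path_entropies(cond: Condensation) -> tuple[float, float]:
    """Forward and backward path entropies (bits) of a condensation DAG."""
    dag = cond.dag
    if dag.number_of_nodes() == 0:
        raise ValueError("empty condensation")
    h_fwd = _node_entropies(dag)
    maximal = [v for v in dag.nodes if dag.in_degree(v) == 0]
    h_f = float(np.mean([h_fwd[v] for v in maximal])) if maximal else 0.0
    rev = dag.reverse(copy=True)
    h_bwd = _node_entropies(rev)
    rev_maximal = [v for v in rev.nodes if rev.in_degree(v) == 0]
    h_b = float(np.mean([h_bwd[v] for v in rev_maximal])) if rev_maximal else 0.0
    return h_f, h_b


def _f_value(dag: nx.DiGraph) -> float:
    if dag.number_of_edges() == 0:
        return 0.0
    stub = Condensation(dag, {}, {})
    h_f, h_b = path_entropies(stub)
    top = h_f - h_b
    bottom = max(h_f, h_b)
    return 0.0 if bottom == 0 else top / bottom


def treeness(graph) -> float:
    """Mean direction-asymmetry ``f`` over a leaf-removal sequence.

    Starting from the condensation ``g_0``, each pruning step removes both
    the maximal (in-degree 0) and minimal (out-degree 0) nodes; the
    sequence stops when the graph is empty or edgeless.  Removing both
    extremes keeps the schedule symmetric under edge reversal, so
    ``T(G reversed) = -T(G)`` holds exactly.
    """
    return hierarchy_report(graph).T


def feedforwardness(cond: Condensation, max_paths: int = MAX_PATHS) -> float:
    """Mean over maximal-to-minimal condensation paths of |path| / sum(alpha).

    A node that is both maximal and minimal contributes the length-one
    path through itself (so a single-SCC condensation of an n-node cycle
    gives 1/n).  Raises if the number of paths exceeds ``max_paths``;
    sampling is left to the caller rather than done silently.
    """
    dag = cond.dag
    alpha = cond.alpha
    vals = []
    for source in cond.maximal:
        for target in cond.minimal:
            if source == target:
                paths = [[source]]
            else:
                paths = nx.all_simple_paths(dag, source, target)
            for path in paths:
                vals.append(len(path) / sum(alpha[v] for v in path))
                if len(vals) > max_paths:
                    raise RuntimeError(
                        f"more than {max_paths} maximal-to-minimal paths; "
                        "increase max_paths or sample paths explicitly"
                    )
    if not vals:  # acyclic condensations always have >= 1 maximal/minimal pair
        raise ValueError("condensation has no maximal-to-minimal paths")
    return float(np.mean(vals))


@dataclass
class HierarchyReport:
    """Treeness / feedforwardness / orderability with intermediates."""

    T: float
    F: float
    O: float
    H_f: float
    H_b: float
    D: int
    f_values: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "treeness": self.T,
            "feedforwardness": self.F,
            "orderability": self.O,
            "H_f": self.H_f,
            "H_b": self.H_b,
            "pruning_steps": self.D,
            "f_values": list(self.f_values),
        }


def hierarchy_report(graph, max_paths: int = MAX_PATHS) -> HierarchyReport:
    """All three hierarchy indices of a directed graph in one pass."""
    cond = condense(graph)
    h_f, h_b = path_entropies(cond)
    # leaf-removal sequence for treeness
    f_values = [_f_value(cond.dag)]
    current = cond.dag.copy()
    while True:
        extremes = {
            v for v in current.nodes
            if current.in_degree(v) == 0 or current.out_degree(v) == 0
        }
        current.remove_nodes_from(extremes)
        if current.number_of_nodes() == 0 or current.number_of_edges() == 0:
            break
        f_values.append(_f_value(current))
    report = HierarchyReport(
        T=float(np.mean(f_values)),
        F=feedforwardness(cond, max_paths=max_paths),
        O=orderability(graph),
        H_f=h_f,
        H_b=h_b,
        D=len(f_values) - 1,
        f_values=f_values,
    )
    return report
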