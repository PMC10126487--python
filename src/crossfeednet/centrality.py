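"""Keystone-species ranking on directed interaction networks.

Two complementary views of a species' network position:

influence centrality
    How much of the network a species can affect downstream: the fraction
    of other nodes reachable from it along directed edges (local reaching
    centrality).  High influence marks "upstream" taxa whose fluctuations
    can propagate widely — candidate keystones.  The measure is pluggable;
    reaching centrality is the default strategy.
PageRank centrality
    How strongly a species accumulates incoming flow from well-connected
    donors; high PageRank marks "sink" taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CentralityReport",
    "influence",
    "pagerank",
    "centrality_report",
    "keystone_ranking",
]


def _digraph(obj) -> nx.DiGraph:
    g = getattr(obj, "graph", None)
    return g if isinstance(g, nx.DiGraph) else obj


def influence(net) -> dict[str, float]:
    """Local reaching centrality: I(v) = |reachable from v| / (N - 1).

    Reachability ignores edge weights (a documented limitation: a chain of
    weak edges counts the same as one strong edge).
    """
    g = _digraph(net)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("influence centrality needs at least 2 nodes")
    return {v: len(nx.descendants(g, v)) / (n - 1) for v in g.nodes}


def pagerank(
    net,
    d: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
    weight: Optional[str] = None,
    x0: Optional[dict] = None,
) -> dict[str, float]:
    """PageRank by power iteration with uniform teleport.

    Dangling nodes (no out-edges) redistribute their mass uniformly.
    Convergence is declared when the L1 change drops below ``tol``; edge
    weights are used as transition probabilities only when ``weight``
    names an edge attribute (unweighted by default, mirroring the
    unweighted ranking question).
    """
    g = _digraph(net)
    nodes = list(g.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("pagerank needs at least 1 node")
    idx = {v: i for i, v in enumerate(nodes)}
    x = np.full(n, 1.0 / n) if x0 is None else np.array([x0[v] for v in nodes], float)
    x = x / x.sum()
    out_weight = np.zeros(n)
    edges = []
    for u, v, data in g.edges(data=True):
        w = float(data.get(weight, 1.0)) if weight else 1.0
        edges.append((idx[u], idx[v], w))
        out_weight[idx[u]] += w
    dangling = out_weight == 0
    for iteration in range(1, max_iter + 1):
        new = np.full(n, (1.0 - d) / n)
        dangling_mass = x[dangling].sum()
        new += d * dangling_mass / n
        for i, j, w in edges:
            new[j] += d * x[i] * w / out_weight[i]
        delta = float(np.abs(new - x).sum())
        x = new
        if delta < tol:
            return {v: float(x[idx[v]]) for v in nodes}
    raise RuntimeError(
        f"PageRank failed to converge in {max_iter} iterations "
        f"(last L1 change {delta:.3e}, tol {tol:.1e}, n={n})"
    )


@dataclass
class CentralityReport:
    """Per-node influence and PageRank for one network."""

    influence: dict[str, float]
    pagerank: dict[str, float]
    damping: float
    day: Optional[int] = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "day": self.day,
                "species": v,
                "influence": self.influence[v],
                "pagerank": self.pagerank[v],
            }
            for v in self.influence
        ]
        return pd.DataFrame(rows)

    def ranking(self, by: str = "influence") -> list[str]:
        scores = getattr(self, by)
        return sorted(scores, key=lambda v: (-scores[v], v))


def centrality_report(
    net,
    damping: float = 0.85,
    day: Optional[int] = None,
    influence_strategy: Callable[[nx.DiGraph], dict] = influence,
) -> CentralityReport:
    g = _digraph(net)
    return CentralityReport(
        influence=influence_strategy(g),
        pagerank=pagerank(g, d=damping),
        damping=damping,
        day=day,
    )


def keystone_ranking(records: pd.DataFrame, top_k: int = 5) -> dict[str, pd.DataFrame]:
    """Summarize per-run, per-day centralities into keystone tables.

    ``records`` has one row per (day, run, species) with columns
    ``influence`` and ``pagerank``.  Returns per-day mean/SD tables, an
    across-days summary per species, and top-k tables by each score.
    """
    if records.empty:
        raise ValueError("no centrality records")

    def _agg(group_cols):
        g = records.groupby(group_cols)[["influence", "pagerank"]]
        mean = g.mean()
        sd = g.std(ddof=1).fillna(0.0)
        out = mean.join(sd, lsuffix="_mean", rsuffix="_sd").reset_index()
        return out

    per_day = _agg(["day", "species"])
    overall = _agg(["species"])
    top_influence = overall.nlargest(top_k, "influence_mean").reset_index(drop=True)
    top_pagerank = overall.nlargest(top_k, "pagerank_mean").reset_index(drop=True)
    return {
        "per_day": per_day,
        "overall": overall,
        "top_influence": top_influence,
        "top_pagerank": top_pagerank,
    }
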