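"""Directed interaction networks from coupling-score runs.

Edges point donor -> recipient (the direction of metabolite flow); an
edge is kept when the mean coupling score across replicate runs exceeds a
threshold and both endpoints were detected at the time point.  Edges
whose endpoints share a strongly connected component of size >= 2 (or
that are self-loops) are flagged as feedback-loop edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exchange import CouplingResult
from .timeseries import AbundanceSeries

__all__ = [
    "DirectedInteractionNetwork",
    "build_network",
    "loop_edges",
    "detect_nodes",
    "read_network_tsv",
]


@dataclass
class DirectedInteractionNetwork:
    """Weighted directed species network at one time point.

    ``graph`` carries edge attributes ``weight_mean``, ``weight_sd`` and
    ``is_loop``; nodes are the detected species (isolated nodes are kept —
    they matter for orderability and centrality denominators).
    """

    graph: nx.DiGraph
    day: Optional[int] = None

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def loop_edges(self) -> set[tuple[str, str]]:
        return {
            (u, v) for u, v, flag in self.graph.edges(data="is_loop") if flag
        }

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            {
                "day": self.day,
                "donor": u,
                "recipient": v,
                "weight_mean": d["weight_mean"],
                "weight_sd": d["weight_sd"],
                "is_loop": bool(d["is_loop"]),
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            rows, columns=["day", "donor", "recipient", "weight_mean", "weight_sd", "is_loop"]
        )

    def to_tsv(self, path) -> None:
        # the node list rides along as a header comment so isolated nodes survive
        with open(path, "w") as fh:
            fh.write(f"# nodes: {','.join(self.nodes)}\n")
            self.to_edge_frame().to_csv(fh, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        if self.day is not None:
            g.graph["day"] = int(self.day)
        nx.write_graphml(g, path)


def read_network_tsv(path) -> DirectedInteractionNetwork:
    with open(path) as fh:
        first = fh.readline()
        nodes: list[str] = []
        if first.startswith("# nodes:"):
            raw = first.split(":", 1)[1].strip()
            nodes = [n for n in raw.split(",") if n]
            frame = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            frame = pd.read_csv(fh, sep="\t")
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    day = None
    for row in frame.itertuples(index=False):
        g.add_edge(
            str(row.donor),
            str(row.recipient),
            weight_mean=float(row.weight_mean),
            weight_sd=float(row.weight_sd),
            is_loop=bool(row.is_loop),
        )
        if not pd.isna(row.day):
            day = int(row.day)
    return DirectedInteractionNetwork(g, day)


def _flag_loops(g: nx.DiGraph) -> None:
    scc_of = {}
    for comp in nx.strongly_connected_components(g):
        for node in comp:
            scc_of[node] = (id(comp), len(comp))
    for u, v in g.edges:
        same_big_scc = u != v and scc_of[u] == scc_of[v] and scc_of[u][1] >= 2
        g.edges[u, v]["is_loop"] = bool(u == v or same_big_scc)


def build_network(
    runs: Sequence[CouplingResult],
    threshold: float = 0.0,
    detected: Optional[Iterable[str]] = None,
    day: Optional[int] = None,
) -> DirectedInteractionNetwork:
    """Aggregate coupling runs into one thresholded directed network.

    An edge donor -> recipient is kept iff the mean coupling score across
    runs is strictly greater than ``threshold`` and both endpoints are in
    the detected node set.  Mean and sample SD across runs are attached as
    edge weights; loop flags are computed on the resulting graph.
    """
    if not runs:
        raise ValueError("need at least one coupling run")
    ids = list(runs[0].scs.index)
    for r in runs[1:]:
        if list(r.scs.index) != ids or list(r.scs.columns) != ids:
            raise ValueError("runs have inconsistent species sets")
    stack = np.stack([r.scs.to_numpy() for r in runs])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros_like(mean)
    node_set = set(ids) if detected is None else set(detected)
    g = nx.DiGraph()
    g.add_nodes_from([s for s in ids if s in node_set])
    for i, donor in enumerate(ids):
        for j, recipient in enumerate(ids):
            if donor == recipient:
                continue
            if donor in node_set and recipient in node_set and mean[i, j] > threshold:
                g.add_edge(
                    donor, recipient,
                    weight_mean=float(mean[i, j]),
                    weight_sd=float(sd[i, j]),
                    is_loop=False,
                )
    _flag_loops(g)
    return DirectedInteractionNetwork(g, day)


def loop_edges(net) -> set[tuple[str, str]]:
    """Edges whose endpoints share an SCC of size >= 2, plus self-loops."""
    g = net.graph if isinstance(net, DirectedInteractionNetwork) else net
    g = g.copy()
    _flag_loops(g)
    return {(u, v) for u, v, flag in g.edges(data="is_loop") if flag}


def detect_nodes(series: AbundanceSeries, day: int, min_abundance: float = 0.0) -> set[str]:
    """Species detected at a day: abundance >= threshold and strictly positive."""
    col = series.column(day)
    return {
        sp
        for sp, val in zip(series.species_ids, col)
        if val > 0 and val >= min_abundance
    }
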