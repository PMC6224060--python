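"""Centrality index, principal/secondary selection, representative graph.

Each node gets a Centrality Index: its degree summed over the 14
group-level double-thresholded matrices, normalized by the largest such
sum.  Principal vertices V' are nodes whose index reaches a histogram-based
cutoff; principal edges E' are emerging links inside V'.  Secondary
vertices V'' attach to V' through a link present in at least ``min_freq``
of the 14 groups, and secondary edges E'' are those attaching links plus
any emerging link fully inside V''.  The representative graph is
G(V' u V'', E' u E'').
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .grouping import LinkTable, SecondThresholdReport


def centrality_index(
    thresholded: list[SecondThresholdReport | np.ndarray],
) -> pd.Series:
    """Normalized degree sum per node over the group matrices.

    Returns a Series indexed by 1-based node id, restricted to nodes with
    at least one nonzero incident entry; max value is 1.
    """
    if not thresholded:
        raise ValueError("need at least one group matrix")
    mats = [
        r.Wstar if isinstance(r, SecondThresholdReport) else np.asarray(r)
        for r in thresholded
    ]
    total = np.zeros(mats[0].shape[0], dtype=float)
    for M in mats:
        M = M.copy()
        np.fill_diagonal(M, 0.0)
        total += (M != 0).sum(axis=1)
    nodes = np.nonzero(total)[0]
    ci = pd.Series(total[nodes] / total.max(), index=nodes + 1, name="ci")
    return ci


def ci_cutoff(ci: pd.Series, n_bins: int = 10) -> float:
    """Midpoint of bin 5 of an ``n_bins``-bin histogram over [min, max] of CI.

    The histogram spans the observed range (not [0, 1]); with the published
    centrality values (min 0.02, max 1.00) this gives 0.461, i.e. 0.46 at
    the printed precision.
    """
    values = np.asarray(ci, dtype=float)
    if np.unique(values).size < 2:
        raise ValueError("centrality distribution is constant; cutoff undefined")
    lo, hi = float(values.min()), float(values.max())
    return lo + 4.5 * (hi - lo) / n_bins


def principal_vertices(ci: pd.Series, cutoff: float) -> set[int]:
    """Nodes with centrality index >= cutoff."""
    return {int(v) for v, c in ci.items() if c >= cutoff}


def _sorted_links(lt: LinkTable) -> list[tuple[tuple[int, int], int]]:
    return [
        ((int(r.node_i), int(r.node_j)), int(r.frequency))
        for r in lt.table.itertuples(index=False)
    ]


def principal_edges(lt: LinkTable, vp: set[int]) -> set[tuple[int, int]]:
    """Emerging links with both endpoints principal (any nonzero frequency)."""
    return {
        (i, j) for (i, j), f in _sorted_links(lt) if f >= 1 and i in vp and j in vp
    }


def secondary_vertices(
    lt: LinkTable, vp: set[int], min_freq: int = 7
) -> set[int]:
    """Non-principal nodes linked to a principal one in >= min_freq groups."""
    if min_freq < 1:
        raise ValueError("min_freq must be >= 1")
    vs: set[int] = set()
    for (i, j), f in _sorted_links(lt):
        if f >= min_freq:
            if i in vp and j not in vp:
                vs.add(j)
            elif j in vp and i not in vp:
                vs.add(i)
    return vs


def secondary_edges(
    lt: LinkTable, vp: set[int], vs: set[int], min_freq: int = 7
) -> set[tuple[int, int]]:
    """Attaching links (V''-V', freq >= min_freq) plus links inside V''.

    Links fully inside V'' qualify at any nonzero frequency; their presence
    strengthens the periphery of the representative graph.
    """
    out: set[tuple[int, int]] = set()
    for (i, j), f in _sorted_links(lt):
        endpoints = {i, j}
        if f >= min_freq and len(endpoints & vp) == 1 and len(endpoints & vs) == 1:
            out.add((i, j))
        elif endpoints <= vs and f >= 1:
            out.add((i, j))
    return out


@dataclass
class GraphSpec:
    """Representative graph with vertex/edge class annotations."""

    graph: nx.Graph
    vprime: set[int]
    vsecond: set[int]
    eprime: set[tuple[int, int]] = field(default_factory=set)
    esecond: set[tuple[int, int]] = field(default_factory=set)

    @property
    def vertices(self) -> set[int]:
        return self.vprime | self.vsecond


def build_graph(
    vp: set[int],
    vs: set[int],
    ep: set[tuple[int, int]],
    es: set[tuple[int, int]],
    lt: LinkTable | None = None,
) -> GraphSpec:
    """Assemble G(V' u V'', E' u E''); isolated vertices are retained.

    Edge attributes: ``cls`` ("principal"/"secondary"; principal wins on a
    duplicate) and ``frequency`` (from ``lt`` when given).  Dangling edge
    endpoints raise.
    """
    if vp & vs:
        raise ValueError(f"V' and V'' overlap: {sorted(vp & vs)}")
    nodes = vp | vs
    dangling = {v for e in ep | es for v in e} - nodes
    if dangling:
        raise ValueError(f"edge endpoints outside V: {sorted(dangling)}")
    G = nx.Graph()
    for v in sorted(nodes):
        G.add_node(v, cls="principal" if v in vp else "secondary")
    for edge_set, cls in ((es, "secondary"), (ep, "principal")):
        for i, j in sorted(edge_set):
            freq = lt.frequency((i, j)) if lt is not None else None
            G.add_edge(i, j, cls=cls, frequency=freq)
    return GraphSpec(G, set(vp), set(vs), set(ep), set(es))


def graph_properties(g: GraphSpec | nx.Graph) -> dict:
    """Component structure, planarity and degree sequence of the graph."""
    G = g.graph if isinstance(g, GraphSpec) else g
    components = [sorted(c) for c in nx.connected_components(G)]
    components.sort(key=len, reverse=True)
    planar, _ = nx.check_planarity(G)
    return {
        "n_nodes": G.number_of_nodes(),
        "n_edges": G.number_of_edges(),
        "n_components": len(components),
        "component_sizes": [len(c) for c in components],
        "components": components,
        "planar": bool(planar),
        "degree_sequence": sorted((d for _, d in G.degree()), reverse=True),
    }


def select_representative_graph(
    lt: LinkTable, ci: pd.Series, n_bins: int = 10, min_freq: int = 7, round_to: int = 2
) -> GraphSpec:
    """Full selection chain from a link table and centrality indices.

    The cutoff is rounded to ``round_to`` decimals before the comparison,
    matching the printed precision of the published centrality tables.
    """
    cutoff = round(ci_cutoff(ci, n_bins=n_bins), round_to)
    vp = principal_vertices(ci, cutoff)
    ep = principal_edges(lt, vp)
    vs = secondary_vertices(lt, vp, min_freq=min_freq)
    es = secondary_edges(lt, vp, vs, min_freq=min_freq)
    return build_graph(vp, vs, ep, es, lt=lt)
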