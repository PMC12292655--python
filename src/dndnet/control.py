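"""Feedback-vertex-set prioritization of DND candidates.

A minimum Feedback Vertex Set (mFVS) is the smallest node set whose
removal leaves a directed graph acyclic; structurally, fixing those nodes
can steer the whole network, so they are master-regulator candidates.  The
exact solver decomposes into strongly connected components and searches
node subsets per component in increasing size with a deterministic
lexicographic tie-break; a reduction+greedy heuristic covers graphs beyond
the exact budget.  Drivers are the FVS nodes ranked by out-degree in the
background network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DataModelError, DirectedNet, SSNRecord

logger = logging.getLogger(__name__)

EXACT_BUDGET = 20  # max nontrivial SCC size for exhaustive search


@dataclass
class FvsResult:
    fvs_nodes: list[str]
    is_exact: bool
    residual_acyclic: bool
    out_degree: dict[str, int]


def induced_subgraph(net: DirectedNet, nodes) -> DirectedNet:
    """Subgraph on ``nodes`` with all edges among them; ids absent from the
    network are logged, an empty intersection is an error."""
    nodes = set(nodes)
    present = nodes & set(net.graph.nodes)
    missing = nodes - present
    if missing:
        logger.info("%d candidate ids absent from network: %s", len(missing), sorted(missing)[:10])
    if not present:
        raise DataModelError("no candidate ids present in the network")
    return net.subgraph(present)


def _is_acyclic(g: nx.DiGraph) -> bool:
    return nx.is_directed_acyclic_graph(g)


def _component_fvs_exact(comp: nx.DiGraph) -> list[str]:
    """Minimum FVS of one strongly connected component by subset search in
    increasing size; ties broken by lexicographically smallest node set."""
    nodes = sorted(comp.nodes)
    forced = sorted(u for u, v in nx.selfloop_edges(comp))
    rest = [n for n in nodes if n not in forced]
    base = comp.copy()
    base.remove_nodes_from(forced)
    if _is_acyclic(base):
        return forced
    for size in range(1, len(rest) + 1):
        for subset in combinations(rest, size):  # lexicographic order
            h = base.copy()
            h.remove_nodes_from(subset)
            if _is_acyclic(h):
                return sorted(forced + list(subset))
    return nodes  # unreachable: removing everything is always acyclic


def fvs_exact(net: DirectedNet, node_budget: int = EXACT_BUDGET) -> FvsResult:
    """Minimum feedback vertex set via per-SCC branch and bound.

    Cycles live entirely within strongly connected components, so the
    union of per-component optima is a global minimum FVS.  Components
    larger than ``node_budget`` raise, directing to :func:`fvs_heuristic`.
    """
    g = net.graph
    fvs: list[str] = []
    for scc in nx.strongly_connected_components(g):
        comp = g.subgraph(scc).copy()
        if len(scc) == 1:
            u = next(iter(scc))
            if comp.has_edge(u, u):
                fvs.append(u)
            continue
        if len(scc) > node_budget:
            raise DataModelError(
                f"SCC of size {len(scc)} exceeds exact budget {node_budget}; use fvs_heuristic"
            )
        fvs.extend(_component_fvs_exact(comp))
    fvs = sorted(set(fvs))
    resid = g.copy()
    resid.remove_nodes_from(fvs)
    return FvsResult(fvs, True, _is_acyclic(resid), {u: g.out_degree(u) for u in fvs})


def fvs_heuristic(net: DirectedNet) -> FvsResult:
    """Valid (not necessarily minimum) FVS: iterative source/sink deletion,
    self-loop forcing, then greedy removal of the node maximizing
    in-degree x out-degree, finished with a minimality-pruning pass."""
    g = net.graph.copy()
    fvs: list[str] = []

    def reduce(graph: nx.DiGraph) -> None:
        changed = True
        while changed:
            changed = False
            for u in list(graph.nodes):
                if graph.has_edge(u, u):
                    fvs.append(u)
                    graph.remove_node(u)
                    changed = True
                elif graph.in_degree(u) == 0 or graph.out_degree(u) == 0:
                    graph.remove_node(u)
                    changed = True

    reduce(g)
    while not _is_acyclic(g):
        u = max(g.nodes, key=lambda n: (g.in_degree(n) * g.out_degree(n), n))
        fvs.append(u)
        g.remove_node(u)
        reduce(g)

    # minimality: drop any node whose removal from the FVS keeps the residual acyclic
    fvs = sorted(set(fvs))
    changed = True
    while changed:
        changed = False
        for u in list(fvs):
            trial = [v for v in fvs if v != u]
            resid = net.graph.copy()
            resid.remove_nodes_from(trial)
            if _is_acyclic(resid):
                fvs = trial
                changed = True
                break
    resid = net.graph.copy()
    resid.remove_nodes_from(fvs)
    return FvsResult(
        sorted(fvs), False, _is_acyclic(resid), {u: net.graph.out_degree(u) for u in fvs}
    )


def fvs_auto(net: DirectedNet, mode: str = "auto", node_budget: int = EXACT_BUDGET) -> FvsResult:
    """Dispatch between exact and heuristic solvers."""
    if mode == "exact":
        return fvs_exact(net, node_budget)
    if mode == "heuristic":
        return fvs_heuristic(net)
    if mode != "auto":
        raise DataModelError(f"unknown FVS mode {mode!r}")
    largest = max(
        (len(c) for c in nx.strongly_connected_components(net.graph)), default=0
    )
    if largest <= node_budget:
        return fvs_exact(net, node_budget)
    logger.info("largest SCC has %d nodes; falling back to heuristic FVS", largest)
    return fvs_heuristic(net)


def rank_drivers(fvs: FvsResult, background: DirectedNet) -> list[str]:
    """FVS nodes sorted by background out-degree (descending), ties by id."""
    return sorted(fvs.fvs_nodes, key=lambda u: (-background.out_degree(u), u))


def degree_comparison(
    candidates, ssn_records: list[SSNRecord], features: list[str]
) -> tuple[pd.Series, pd.Series, float]:
    """Compare significant-edge degree of candidates vs non-candidates.

    Per feature, the degree (in + out over significant SSN edges) is
    averaged across the supplied samples (typically the final stage); a
    two-sided Wilcoxon rank-sum test compares the two groups.
    """
    candidates = set(candidates)
    non = [f for f in features if f not in candidates]
    cand = [f for f in features if f in candidates]
    if not cand or not non:
        raise DataModelError("degree comparison needs both candidate and non-candidate features")
    deg = pd.DataFrame(0.0, index=features, columns=range(len(ssn_records)))
    for j, rec in enumerate(ssn_records):
        sig = rec.significant_edges()
        counts = pd.concat([sig["source"], sig["target"]]).value_counts()
        deg[j] = counts.reindex(features).fillna(0.0)
    mean_deg = deg.mean(axis=1)
    a, b = mean_deg.loc[cand], mean_deg.loc[non]
    if a.nunique() == 1 and b.nunique() == 1 and a.iloc[0] == b.iloc[0]:
        return a, b, 1.0
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return a, b, float(p)
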