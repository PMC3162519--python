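"""Key Driver Analysis: rank genes by downstream reach in a causal network.

Given a directed acyclic gene network N and a gene set of interest G
(typically the genes residing in amplified recurrent CNV regions), each
node's h-layer neighborhood (HLN) is the set of nodes reachable from it
by directed paths of length <= h. Candidate drivers are the members of G
whose HLN size exceeds the network-wide mean by more than ``mu_mult``
standard deviations; candidates without any parent (root nodes) are
*global* drivers and the rest *local* regulators. Members of G whose
out-degree exceeds the network-wide mean out-degree by more than
``d_mult`` standard deviations are promoted to global drivers as hubs.
Both reference statistics are computed over all nodes of N, not just G.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bayesnet import DirectedNetwork

__all__ = ["DriverCall", "hln_sizes", "network_diameter", "classify_drivers"]

GLOBAL = "global"
LOCAL = "local"
NON_DRIVER = "non-driver"


@dataclass
class DriverCall:
    gene: object
    hln_size: int
    out_degree: int
    klass: str  # "global" | "local" | "non-driver"
    h_used: int


def _require_dag(net: DirectedNetwork) -> None:
    if not net.is_dag():
        raise ValueError("network contains directed cycles; run break_loops first")


def hln_sizes(net: DirectedNetwork, h: int) -> dict:
    """Number of distinct downstream nodes within h edges, per node (self
    excluded). Layered breadth-first search from every node."""
    if h < 1:
        raise ValueError("h must be >= 1")
    _require_dag(net)
    adj = net.adjacency()
    sizes = {}
    for g in net.nodes:
        seen = {g}
        frontier = [g]
        for _ in range(h):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        nxt.append(v)
            if not nxt:
                break
            frontier = nxt
        sizes[g] = len(seen) - 1
    return sizes


def network_diameter(net: DirectedNetwork) -> int:
    """Longest finite shortest directed path between any ordered node pair.

    Used as the default h: the deepest layer at which any node can still
    reach new downstream nodes. Returns 1 for edgeless networks so HLN
    computation stays well-defined.
    """
    _require_dag(net)
    adj = net.adjacency()
    best = 0
    for g in net.nodes:
        depth = 0
        seen = {g}
        frontier = [g]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        nxt.append(v)
            if nxt:
                depth += 1
            frontier = nxt
        best = max(best, depth)
    return max(best, 1)


def classify_drivers(
    net: DirectedNetwork,
    gene_set,
    h: int | None = None,
    mu_mult: float = 1.0,
    d_mult: float = 1.0,
) -> list[DriverCall]:
    """Classify every network node as global driver, local driver or neither.

    ``h`` defaults to the network diameter. Genes in ``gene_set`` missing
    from the network are skipped (logged via the return value simply not
    containing them). Thresholds are strict: with zero spread (e.g. a
    regular graph) nothing is called. Results are sorted by HLN size
    (descending), then gene ID.
    """
    if len(net.nodes) == 0:
        raise ValueError("empty network")
    _require_dag(net)
    if h is None:
        h = network_diameter(net)
    gene_set = {g for g in gene_set if g in set(net.nodes)}

    sizes = hln_sizes(net, h)
    out_deg = {g: 0 for g in net.nodes}
    has_parent = {g: False for g in net.nodes}
    for (u, v) in net.edges:
        out_deg[u] += 1
        has_parent[v] = True

    mu = np.array([sizes[g] for g in net.nodes], dtype=float)
    d = np.array([out_deg[g] for g in net.nodes], dtype=float)
    mu_thr = mu.mean() + mu_mult * mu.std(ddof=1 if len(mu) > 1 else 0)
    d_thr = d.mean() + d_mult * d.std(ddof=1 if len(d) > 1 else 0)

    calls = []
    for g in net.nodes:
        in_set = g in gene_set
        candidate = in_set and sizes[g] > mu_thr
        hub = in_set and out_deg[g] > d_thr
        if (candidate and not has_parent[g]) or hub:
            klass = GLOBAL
        elif candidate:
            klass = LOCAL
        else:
            klass = NON_DRIVER
        calls.append(DriverCall(gene=g, hln_size=sizes[g], out_degree=out_deg[g],
                                klass=klass, h_used=h))
    calls.sort(key=lambda c: (-c.hln_size, str(c.gene)))
    return calls
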