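"""Consensus Bayesian gene-regulatory networks from expression data.

Whether a downstream gene is regulated by one, both or neither of two
candidate regulators — conditioned on everything else measured — is a
model-selection problem over directed acyclic structures, so regulator
identification is realized directly as Bayesian-network structure
learning: expression is discretized into levels, candidate DAGs are
scored by BIC with multinomial local conditionals, and a Metropolis walk
over DAG space (add / delete / reverse edge moves) searches for
high-scoring structures. Because any single chain is one draw from a
rugged posterior landscape, many chains are run from different seeds and
only edges appearing in more than a threshold fraction of the resulting
networks (30% by default) enter the consensus; cross-study networks are
combined by union of directed links, and residual directed cycles are
broken by repeatedly deleting the most weakly supported edge of a cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DirectedNetwork",
    "DiscreteDataset",
    "SearchResult",
    "discretize_expression",
    "bic_score",
    "log_likelihood",
    "default_iterations",
    "mcmc_structure_search",
    "consensus_network",
    "break_loops",
    "union_networks",
    "write_edge_list",
    "read_edge_list",
]


@dataclass
class DirectedNetwork:
    """Directed graph over gene IDs with per-edge support frequency in (0, 1]."""

    nodes: list
    edges: dict = field(default_factory=dict)  # (parent, child) -> frequency

    def __post_init__(self) -> None:
        self.nodes = list(self.nodes)
        node_set = set(self.nodes)
        for (u, v), f in self.edges.items():
            if u == v:
                raise ValueError(f"self-edge {u}->{v} not allowed")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge {u}->{v} references unknown node")
            if not (0 < f <= 1):
                raise ValueError(f"edge frequency must lie in (0, 1], got {f}")

    def __contains__(self, edge) -> bool:
        return edge in self.edges

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def children(self, u) -> list:
        return [v for (p, v) in self.edges if p == u]

    def parents(self, v) -> list:
        return [p for (p, c) in self.edges if c == v]

    def adjacency(self) -> dict:
        adj: dict = {n: [] for n in self.nodes}
        for (u, v) in self.edges:
            adj[u].append(v)
        return adj

    def is_dag(self) -> bool:
        return _find_cycle(self.adjacency()) is None

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (u, v), f in self.edges.items():
            g.add_edge(u, v, frequency=f)
        return g

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"parent": u, "child": v, "frequency": f}
            for (u, v), f in sorted(self.edges.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1])))
        ]
        return pd.DataFrame(rows, columns=["parent", "child", "frequency"])


@dataclass
class DiscreteDataset:
    """Per-gene discrete expression levels (0..L-1) across a shared sample set."""

    values: np.ndarray  # genes x samples, integer levels
    genes: list
    L: int
    constant_genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.genes):
            raise ValueError("values must be genes x samples")
        if self.values.min(initial=0) < 0 or self.values.max(initial=0) >= self.L:
            raise ValueError(f"levels must lie in [0, {self.L})")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def discretize_expression(matrix, L: int = 3) -> DiscreteDataset:
    """Quantile-bin each gene into L levels (rank-based, so any monotone
    transform of a gene yields identical levels).

    Ties take the level of their first occurrence in value order. Constant
    genes map to the middle level and are flagged in ``constant_genes``.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    if isinstance(matrix, pd.DataFrame):
        genes = list(matrix.index)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        genes = list(range(X.shape[0]))
    n = X.shape[1]
    levels = np.empty_like(X, dtype=np.int64)
    constant = []
    for i in range(X.shape[0]):
        row = X[i]
        if row.max() == row.min():
            levels[i] = L // 2
            constant.append(genes[i])
            continue
        order = np.argsort(row, kind="stable")
        rank = np.empty(n, dtype=np.int64)
        rank[order] = np.arange(n)
        # equal values share the rank of their first occurrence
        first_rank: dict[float, int] = {}
        for idx in order:
            first_rank.setdefault(row[idx], rank[idx])
        shared = np.array([first_rank[v] for v in row])
        levels[i] = shared * L // n
    return DiscreteDataset(values=levels, genes=genes, L=L, constant_genes=constant)


# ---------------------------------------------------------------------------
# BIC scoring
# ---------------------------------------------------------------------------


def _family_stats(data: DiscreteDataset, child: int, parents: tuple[int, ...]):
    """(log-likelihood, n_free_params) for one multinomial family."""
    L = data.L
    x = data.values[child]
    if parents:
        config = np.zeros(data.n_samples, dtype=np.int64)
        for p in parents:
            config = config * L + data.values[p]
        joint = np.bincount(config * L + x, minlength=L ** len(parents) * L)
        joint = joint.reshape(-1, L)
    else:
        joint = np.bincount(x, minlength=L).reshape(1, L)
    row_tot = joint.sum(axis=1)
    nz = joint > 0
    ll = float(np.sum(joint[nz] * np.log(joint[nz] / row_tot[:, None].repeat(L, 1)[nz])))
    n_params = (L - 1) * L ** len(parents)
    return ll, n_params


def _family_score(data: DiscreteDataset, child: int, parents: tuple[int, ...]) -> float:
    ll, n_params = _family_stats(data, child, parents)
    return ll - 0.5 * n_params * math.log(data.n_samples)


def _resolve_parent_sets(dag: DirectedNetwork, data: DiscreteDataset) -> list[tuple[int, ...]]:
    index = {g: i for i, g in enumerate(data.genes)}
    parent_sets: list[list[int]] = [[] for _ in data.genes]
    for (u, v) in dag.edges:
        parent_sets[index[v]].append(index[u])
    return [tuple(sorted(ps)) for ps in parent_sets]


def log_likelihood(dag: DirectedNetwork, data: DiscreteDataset) -> float:
    """Maximum-likelihood multinomial log-likelihood of the DAG factorization."""
    return sum(
        _family_stats(data, i, ps)[0] for i, ps in enumerate(_resolve_parent_sets(dag, data))
    )


def bic_score(dag: DirectedNetwork, data: DiscreteDataset) -> float:
    """Decomposable BIC: sum over families of (ML log-likelihood minus
    0.5 * free-parameter count * log n_samples). Higher is better."""
    if not dag.is_dag():
        raise ValueError("bic_score requires an acyclic network")
    return sum(
        _family_score(data, i, ps) for i, ps in enumerate(_resolve_parent_sets(dag, data))
    )


# ---------------------------------------------------------------------------
# MCMC structure search
# ---------------------------------------------------------------------------


def default_iterations(n_nodes: int) -> int:
    """Default proposal count for one chain: 15 * n^2 for n network nodes."""
    return 15 * n_nodes * n_nodes


@dataclass
class SearchResult:
    network: DirectedNetwork
    score: float
    iterations: int
    accepted: int


def _reachable(adj: list[set], start: int, target: int) -> bool:
    """Is there a directed path start -> target? Iterative DFS."""
    if start == target:
        return True
    stack = [start]
    seen = {start}
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v == target:
                return True
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


def mcmc_structure_search(
    data: DiscreteDataset,
    seed: int = 0,
    iterations: int | None = None,
    max_parents: int = 3,
) -> SearchResult:
    """Metropolis walk over DAG space; returns the best-scoring DAG visited.

    Moves are edge addition, deletion and reversal; proposals that would
    create a cycle or exceed ``max_parents`` are rejected outright. A move
    is accepted with probability min(1, exp(delta BIC)) (natural log, no
    annealing). The chain starts from the empty graph; ``iterations``
    defaults to 15 * n^2 proposals for n nodes. Deterministic per seed.
    """
    n = len(data.genes)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if iterations is None:
        iterations = default_iterations(n)
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)

    parents: list[tuple[int, ...]] = [() for _ in range(n)]
    adj: list[set] = [set() for _ in range(n)]  # child sets
    cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def fam(child: int, ps: tuple[int, ...]) -> float:
        key = (child, ps)
        if key not in cache:
            cache[key] = _family_score(data, child, ps)
        return cache[key]

    score = sum(fam(i, ()) for i in range(n))
    best_score = score
    best_parents = list(parents)
    accepted = 0

    for _ in range(iterations):
        u = int(rng.integers(n))
        v = int(rng.integers(n - 1))
        if v >= u:
            v += 1
        has_uv = v in adj[u]
        if has_uv:
            move = "delete" if rng.random() < 0.5 else "reverse"
        else:
            move = "add"

        if move == "add":
            if len(parents[v]) >= max_parents or _reachable(adj, v, u):
                continue
            new_pv = tuple(sorted(parents[v] + (u,)))
            delta = fam(v, new_pv) - fam(v, parents[v])
            if delta >= 0 or rng.random() < math.exp(delta):
                parents[v] = new_pv
                adj[u].add(v)
                score += delta
                accepted += 1
        elif move == "delete":
            new_pv = tuple(p for p in parents[v] if p != u)
            delta = fam(v, new_pv) - fam(v, parents[v])
            if delta >= 0 or rng.random() < math.exp(delta):
                parents[v] = new_pv
                adj[u].discard(v)
                score += delta
                accepted += 1
        else:  # reverse u->v to v->u
            if len(parents[u]) >= max_parents:
                continue
            adj[u].discard(v)
            if _reachable(adj, u, v):
                adj[u].add(v)  # another path exists; reversal makes a cycle
                continue
            new_pv = tuple(p for p in parents[v] if p != u)
            new_pu = tuple(sorted(parents[u] + (v,)))
            delta = (fam(v, new_pv) - fam(v, parents[v])) + (fam(u, new_pu) - fam(u, parents[u]))
            if delta >= 0 or rng.random() < math.exp(delta):
                parents[v] = new_pv
                parents[u] = new_pu
                adj[v].add(u)
                score += delta
                accepted += 1
            else:
                adj[u].add(v)

        if score > best_score:
            best_score = score
            best_parents = list(parents)

    edges = {
        (data.genes[p], data.genes[c]): 1.0
        for c, ps in enumerate(best_parents)
        for p in ps
    }
    net = DirectedNetwork(nodes=list(data.genes), edges=edges)
    return SearchResult(network=net, score=best_score, iterations=iterations, accepted=accepted)


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------


def consensus_network(dags, threshold: float = 0.30) -> DirectedNetwork:
    """Edges appearing in strictly more than ``threshold`` of the input
    networks, with their frequency attached. May contain cycles."""
    dags = list(dags)
    if not dags:
        raise ValueError("need at least one input network")
    if not (0 <= threshold < 1):
        raise ValueError("threshold must lie in [0, 1)")
    counts: dict = {}
    nodes: list = []
    seen = set()
    for d in dags:
        for nd in d.nodes:
            if nd not in seen:
                seen.add(nd)
                nodes.append(nd)
        for e in d.edges:
            counts[e] = counts.get(e, 0) + 1
    total = len(dags)
    edges = {e: c / total for e, c in counts.items() if c / total > threshold}
    return DirectedNetwork(nodes=nodes, edges=edges)


def union_networks(nets) -> DirectedNetwork:
    """Union of directed links across networks; frequency = max over inputs.

    Conflicting directions are both retained (resolved later by
    :func:`break_loops`)."""
    nets = list(nets)
    if not nets:
        raise ValueError("need at least one input network")
    nodes: list = []
    seen = set()
    edges: dict = {}
    for net in nets:
        for nd in net.nodes:
            if nd not in seen:
                seen.add(nd)
                nodes.append(nd)
        for e, f in net.edges.items():
            edges[e] = max(edges.get(e, 0.0), f)
    return DirectedNetwork(nodes=nodes, edges=edges)


def _find_cycle(adj: dict) -> list | None:
    """Deterministic DFS cycle search: nodes and neighbors visited in sorted
    order, starting from the lexicographically smallest node. Returns the
    cycle as a list of (u, v) edges, or None."""
    order = sorted(adj, key=str)
    sorted_adj = {u: sorted(adj[u], key=str) for u in adj}
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {u: WHITE for u in adj}
    for root in order:
        if color[root] != WHITE:
            continue
        stack = [(root, iter(sorted_adj[root]))]
        color[root] = GRAY
        path = [root]
        while stack:
            u, it = stack[-1]
            advanced = False
            for v in it:
                if color[v] == GRAY:
                    i = path.index(v)
                    cyc_nodes = path[i:] + [v]
                    return list(zip(cyc_nodes[:-1], cyc_nodes[1:]))
                if color[v] == WHITE:
                    color[v] = GRAY
                    stack.append((v, iter(sorted_adj[v])))
                    path.append(v)
                    advanced = True
                    break
            if not advanced:
                color[u] = BLACK
                stack.pop()
                path.pop()
    return None


def break_loops(net: DirectedNetwork) -> DirectedNetwork:
    """Delete the most weakly supported edge of each directed cycle until the
    network is acyclic (ties broken by lexicographically smallest
    (parent, child) pair). Edges outside every cycle are never touched."""
    edges = dict(net.edges)
    adj: dict = {n: set() for n in net.nodes}
    for (u, v) in edges:
        adj[u].add(v)
    while True:
        cycle = _find_cycle(adj)
        if cycle is None:
            break
        victim = min(cycle, key=lambda e: (edges[e], str(e[0]), str(e[1])))
        del edges[victim]
        adj[victim[0]].discard(victim[1])
    return DirectedNetwork(nodes=list(net.nodes), edges=edges)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_edge_list(net: DirectedNetwork, path, sif: bool = False) -> None:
    """TSV edge list (parent, child, frequency); ``sif=True`` writes SIF."""
    df = net.to_dataframe()
    if sif:
        with open(path, "w") as fh:
            for _, row in df.iterrows():
                fh.write(f"{row['parent']}\tregulates\t{row['child']}\n")
    else:
        df.to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> DirectedNetwork:
    df = pd.read_csv(path, sep="\t")
    if "frequency" not in df.columns:
        df["frequency"] = 1.0
    nodes: list = []
    seen = set()
    for col in ("parent", "child"):
        for nd in df[col]:
            if nd not in seen:
                seen.add(nd)
                nodes.append(nd)
    edges = {(r["parent"], r["child"]): float(r["frequency"]) for _, r in df.iterrows()}
    return DirectedNetwork(nodes=nodes, edges=edges)
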