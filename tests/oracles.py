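"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a different route than the library:
explicit filter-cascade convolution for the wavelet smoother, per-bp
coverage arrays for interval recurrence, matrix-product reachability for
h-layer neighborhoods, exhaustive DAG enumeration for structure scoring,
and direct hypergeometric summation for enrichment p-values.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pywt


def equivalent_smoothing_kernel(filter_name: str, level: int) -> np.ndarray:
    """Impulse response of reconstruction-from-approximation at ``level``.

    Cascade of dilated analysis low-pass filters (levels 1..s) followed by
    the dilated synthesis low-pass filters (levels s..1); the undecimated
    inverse averages two shifted reconstructions per level, contributing a
    factor 1/2 each. For an orthogonal filter the kernel mass is 1.
    """
    w = pywt.Wavelet(filter_name)
    dec = np.asarray(w.dec_lo)
    rec = np.asarray(w.rec_lo)
    k = np.array([1.0])
    for j in range(level):
        up = np.zeros((len(dec) - 1) * 2**j + 1)
        up[:: 2**j] = dec
        k = np.convolve(k, up)
    for j in reversed(range(level)):
        up = np.zeros((len(rec) - 1) * 2**j + 1)
        up[:: 2**j] = rec
        k = np.convolve(k, up)
    return k / 2**level


def convolve_reflect(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct convolution under symmetric reflection padding (no library
    convolution routine; plain index arithmetic with reflected indices)."""
    n = len(x)
    m = len(kernel)
    half = (m - 1) // 2
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(m):
            # kernel centered at i; offset relative to signal
            idx = i + j - half
            # reflect (symmetric, repeating edge-mirror) into [0, n)
            period = 2 * n
            idx = idx % period
            if idx < 0:
                idx += period
            if idx >= n:
                idx = period - 1 - idx
            acc += kernel[m - 1 - j] * x[idx]
        out[i] = acc
    return out


def coverage_recurrent_bp(intervals_by_study: dict, k: int, axis_len: int):
    """Brute-force per-bp recurrence on a small integer axis.

    ``intervals_by_study`` maps study -> list of inclusive (start, end).
    Returns (core bp set covered by >= k studies, expected recurrent
    intervals after expansion to the union of intersecting regions and
    merging of overlaps).
    """
    cover = np.zeros(axis_len, dtype=int)
    for ivs in intervals_by_study.values():
        mask = np.zeros(axis_len, dtype=bool)
        for s, e in ivs:
            mask[s : e + 1] = True
        cover += mask
    core = {i for i in range(axis_len) if cover[i] >= k}
    # expand each maximal core run to union of intersecting intervals
    flat = [iv for ivs in intervals_by_study.values() for iv in ivs]
    expanded_bp: set[int] = set()
    i = 0
    while i < axis_len:
        if i not in core:
            i += 1
            continue
        j = i
        while j + 1 in core:
            j += 1
        for s, e in flat:
            if s <= j and e >= i:
                expanded_bp.update(range(s, e + 1))
        i = j + 1
    # maximal runs of expanded_bp
    out = []
    i = 0
    while i < axis_len:
        if i not in expanded_bp:
            i += 1
            continue
        j = i
        while j + 1 in expanded_bp:
            j += 1
        out.append((i, j))
        i = j + 1
    return core, out


def hln_by_matrix_power(edges: set, nodes: list, h: int) -> dict:
    """HLN sizes via boolean adjacency-matrix powers."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n), dtype=bool)
    for u, v in edges:
        A[idx[u], idx[v]] = True
    reach = np.zeros((n, n), dtype=bool)
    P = np.eye(n, dtype=bool)
    for _ in range(h):
        P = P @ A
        reach |= P
    np.fill_diagonal(reach, False)
    return {node: int(reach[idx[node]].sum()) for node in nodes}


def enumerate_dags(nodes: list):
    """All labelled DAGs over the nodes as edge sets (feasible for <= 4)."""
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    for bits in itertools.product([0, 1], repeat=len(pairs)):
        edges = {p for p, b in zip(pairs, bits) if b}
        if _acyclic(edges, nodes):
            yield edges


def _acyclic(edges: set, nodes: list) -> bool:
    adj = {n: [] for n in nodes}
    for u, v in edges:
        adj[u].append(v)
    state = {n: 0 for n in nodes}

    def dfs(u):
        state[u] = 1
        for v in adj[u]:
            if state[v] == 1 or (state[v] == 0 and not dfs(v)):
                return False
        state[u] = 2
        return True

    return all(state[n] or dfs(n) for n in nodes)


def multinomial_bic(edges: set, levels: np.ndarray, L: int) -> float:
    """BIC of a DAG over discrete data, written directly from counts."""
    n_nodes, n_samples = levels.shape
    parents = {i: sorted(u for (u, v) in edges if v == i) for i in range(n_nodes)}
    total = 0.0
    for child in range(n_nodes):
        ps = parents[child]
        counts: dict = {}
        for s in range(n_samples):
            key = tuple(levels[p, s] for p in ps)
            row = counts.setdefault(key, [0] * L)
            row[levels[child, s]] += 1
        ll = 0.0
        for row in counts.values():
            tot = sum(row)
            for c in row:
                if c:
                    ll += c * math.log(c / tot)
        total += ll - 0.5 * (L - 1) * (L ** len(ps)) * math.log(n_samples)
    return total


def hypergeom_upper_tail(a: int, bg: int, hits: int, target: int) -> float:
    """P(X >= a) for X ~ Hypergeom by direct summation of the pmf."""
    def pmf(x):
        return (
            math.comb(hits, x) * math.comb(bg - hits, target - x) / math.comb(bg, target)
        )

    lo, hi = max(0, hits + target - bg), min(hits, target)
    return sum(pmf(x) for x in range(max(a, lo), hi + 1))
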