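"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: Fisher p-values come
from exact integer/Fraction enumeration per margin set, betweenness from an
explicit DFS enumeration of every shortest path, BH from a literal
transcription of the step-up procedure.
"""

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np


def fisher_enumeration(N: int, n: int, Nf: int):
    """Two-sided Fisher p for every nf in the support of margins (N, n, Nf).

    Enumerates all tables with the fixed margins, computes each probability
    as an exact Fraction, and sums those <= the observed table's probability.
    Returns {nf: p}.
    """
    lo, hi = max(0, n + Nf - N), min(n, Nf)
    denom = comb(N, Nf)
    probs = [Fraction(comb(n, k) * comb(N - n, Nf - k), denom) for k in range(lo, hi + 1)]
    return {
        nf: float(sum(p for p in probs if p <= probs[nf - lo]))
        for nf in range(lo, hi + 1)
    }


def betweenness_enumeration(g: nx.DiGraph | nx.Graph) -> dict:
    """Relative betweenness via explicit shortest-path enumeration.

    For every ordered pair (s, t) all shortest paths are generated by a DFS
    restricted to distance-decreasing edges; a node's credit is the fraction
    of those paths containing it. Undirected graphs count each unordered
    pair once. Scaled by 2/((n-1)(n-2)).
    """
    nodes = list(g.nodes)
    n = len(nodes)
    if n < 3:
        return {v: 0.0 for v in nodes}
    directed = g.is_directed()
    dist = dict(nx.all_pairs_shortest_path_length(g))
    acc = {v: 0.0 for v in nodes}
    for si, s in enumerate(nodes):
        for ti, t in enumerate(nodes):
            if s == t or (not directed and ti <= si):
                continue
            if t not in dist.get(s, {}):
                continue
            target_len = dist[s][t]
            paths = []
            stack = [[s]]
            while stack:
                path = stack.pop()
                u = path[-1]
                if u == t:
                    paths.append(path)
                    continue
                nbrs = g.successors(u) if directed else g.neighbors(u)
                for w in nbrs:
                    if t in dist.get(w, {}) and len(path) + dist[w][t] == target_len:
                        stack.append(path + [w])
            sigma = len(paths)
            for v in nodes:
                if v in (s, t):
                    continue
                acc[v] += sum(1 for p in paths if v in p) / sigma
    scale = 2.0 / ((n - 1) * (n - 2))
    return {v: acc[v] * scale for v in nodes}


def bh_stepup(pvalues) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def random_directed_graphs(n_graphs: int, seed: int, n_max: int = 12):
    """Seeded stream of random directed graphs with string node labels."""
    rng = np.random.default_rng(seed)
    for _ in range(n_graphs):
        n = int(rng.integers(4, n_max + 1))
        p = float(rng.uniform(0.15, 0.5))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)), directed=True)
        yield nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
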