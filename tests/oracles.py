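"""Independent brute-force oracles for small instances.

Everything here is written with explicit loops and exact combinatorics,
deliberately sharing no code path with the package implementation, so
that agreement on small instances is evidence of correctness.
"""

import math
from fractions import Fraction


def mi_oracle(corpus, x, y, base=2.0):
    """Pointwise MI by direct counting over prescriptions (clamped at 0)."""
    n = len(corpus)
    cx = sum(1 for p in corpus if x in p.herbs)
    cy = sum(1 for p in corpus if y in p.herbs)
    cxy = sum(1 for p in corpus if x in p.herbs and y in p.herbs)
    if cxy == 0:
        return 0.0
    pxy, px, py = cxy / n, cx / n, cy / n
    return max(0.0, pxy * math.log(pxy / (px * py), base))


def distance_oracle(corpus, x, y):
    """Mean absolute positional gap over co-occurring prescriptions."""
    gaps = []
    for p in corpus:
        if x in p.herbs and y in p.herbs:
            gaps.append(abs(list(p.herbs).index(x) - list(p.herbs).index(y)))
    return sum(gaps) / len(gaps)


def score_oracle(corpus, x, y):
    cooc = any(x in p.herbs and y in p.herbs for p in corpus)
    if not cooc:
        return 0.0
    return mi_oracle(corpus, x, y) / distance_oracle(corpus, x, y)


def all_pairs_shortest_paths(nodes, edges):
    """Floyd-Warshall on an explicit edge list."""
    dist = {u: {v: math.inf for v in nodes} for u in nodes}
    for u in nodes:
        dist[u][u] = 0
    for u, v in edges:
        dist[u][v] = dist[v][u] = 1
    for w in nodes:
        for u in nodes:
            for v in nodes:
                if dist[u][w] + dist[w][v] < dist[u][v]:
                    dist[u][v] = dist[u][w] + dist[w][v]
    return dist


def topology_score_oracle(t1, t2, importance, nodes, edges):
    """Symmetrized importance-weighted exp decay via exhaustive evaluation."""
    dist = all_pairs_shortest_paths(nodes, edges)

    def directional(src, dst):
        weights = [importance[i] for i in src]
        if sum(weights) == 0:
            weights = [1.0] * len(src)
        num = 0.0
        for i, w in zip(src, weights):
            d = min(dist[i][j] for j in dst)
            num += w * (0.0 if math.isinf(d) else math.exp(-d))
        return num / sum(weights)

    return 0.5 * (directional(t1, t2) + directional(t2, t1))


def hypergeom_tail_oracle(k, n_total, n_term, n_query):
    """Exact P(X >= k) by rational-arithmetic enumeration of the PMF tail."""
    total = Fraction(0)
    denom = math.comb(n_total, n_query)
    for j in range(k, min(n_term, n_query) + 1):
        total += Fraction(
            math.comb(n_term, j) * math.comb(n_total - n_term, n_query - j),
            denom,
        )
    return float(total)


def bh_oracle(p_values):
    """Benjamini-Hochberg step-up by hand (returns adjusted p in input order)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, p_values[i] * m / rank)
        adj[i] = running
    return adj


def link_oracle(targets_a, targets_b, nodes, edges):
    """Overlap-or-adjacent predicate by explicit loops."""
    a = set(targets_a) & set(nodes)
    b = set(targets_b) & set(nodes)
    if a & b:
        return True
    edge_set = {frozenset(e) for e in edges}
    for u in a:
        for v in b:
            if frozenset((u, v)) in edge_set:
                return True
    return False
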