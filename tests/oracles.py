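"""Independent brute-force oracles used to validate the package's metrics.

Everything here is written in a deliberately naive style (explicit loops,
set arithmetic, breadth-first searches) and shares no code with the package
implementation it checks.
"""

from __future__ import annotations

import math
from collections import deque
from itertools import combinations


# ---------- graph helpers on plain adjacency dicts ----------

def adjacency(edges, nodes):
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def bfs_distances(adj, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


# ---------- edge metrics ----------

def jaccard_oracle(adj, u, v):
    nu = adj[u] - {v}
    nv = adj[v] - {u}
    union = nu | nv
    return len(nu & nv) / len(union) if union else 0.0


def common_neighbors_oracle(adj, u, v):
    return len((adj[u] - {v}) & (adj[v] - {u}))


def preferential_attachment_oracle(adj, u, v):
    return len(adj[u]) * len(adj[v])


def resource_allocation_oracle(adj, u, v):
    total = 0.0
    for z in (adj[u] - {v}) & (adj[v] - {u}):
        total += 1.0 / len(adj[z])
    return total


# ---------- node metrics ----------

def closeness_oracle(adj, u):
    """Component-scaled (Wasserman-Faust) closeness."""
    n_total = len(adj)
    dist = bfs_distances(adj, u)
    n_c = len(dist)
    if n_c < 2 or n_total < 2:
        return 0.0
    total = sum(dist.values())
    return ((n_c - 1) / (n_total - 1)) * ((n_c - 1) / total)


def eccentricity_oracle(adj, u):
    dist = bfs_distances(adj, u)
    return max(dist.values())


def clustering_oracle(adj, u):
    neigh = list(adj[u])
    k = len(neigh)
    if k < 2:
        return 0.0
    links = sum(1 for a, b in combinations(neigh, 2) if b in adj[a])
    return 2.0 * links / (k * (k - 1))


def betweenness_oracle(adj, nodes):
    """Normalized betweenness by explicit shortest-path enumeration.

    For every ordered pair (s, t) the shortest paths are enumerated by
    walking the BFS predecessor DAG; each intermediate vertex collects its
    fraction of the paths. Unordered pairs counted once, then divided by
    (N-1)(N-2)/2.
    """
    nodes = list(nodes)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        dist = bfs_distances(adj, s)
        if t not in dist:
            continue
        # enumerate all shortest s->t paths by backtracking from t
        paths = []

        def back(v, path):
            if v == s:
                paths.append(path)
                return
            for p in adj[v]:
                if p in dist and dist[p] == dist[v] - 1:
                    back(p, path + [p])

        back(t, [t])
        if not paths:
            continue
        for path in paths:
            for v in path:
                if v not in (s, t):
                    score[v] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    if norm <= 0:
        return {v: 0.0 for v in nodes}
    return {v: score[v] / norm for v in nodes}


def eigenvector_oracle(adj, nodes, tol=1e-12, max_iter=100000):
    """Naive power iteration on (A+I) per component, pure-python arithmetic."""
    nodes = list(nodes)
    # split into components
    seen, comps = set(), []
    for start in nodes:
        if start in seen:
            continue
        comp = sorted(bfs_distances(adj, start))
        seen.update(comp)
        comps.append(comp)
    best = None  # (eigval, size, comp, vec)
    for comp in comps:
        if len(comp) < 2:
            continue
        idx = {v: i for i, v in enumerate(comp)}
        m = len(comp)
        x = [1.0 / math.sqrt(m)] * m
        for _ in range(max_iter):
            y = [x[i] + sum(x[idx[w]] for w in adj[v] if w in idx)
                 for i, v in enumerate(comp)]
            norm = math.sqrt(sum(t * t for t in y))
            y = [t / norm for t in y]
            if max(abs(a - b) for a, b in zip(x, y)) < tol:
                x = y
                break
            x = y
        eigval = sum(
            x[i] * sum(x[idx[w]] for w in adj[v] if w in idx)
            for i, v in enumerate(comp)
        )
        key = (eigval, len(comp))
        if best is None or key > (best[0], best[1]):
            best = (eigval, len(comp), comp, x)
    out = {v: 0.0 for v in nodes}
    if best is not None:
        for v, value in zip(best[2], best[3]):
            out[v] = abs(value)
    return out


# ---------- statistics ----------

def pearson_oracle(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)


def welch_oracle(a, b):
    """Welch t statistic, Welch-Satterthwaite df, two-sided p (via scipy's
    t-distribution CDF only — the test logic itself is textbook arithmetic)."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return t, df, p


def hypergeom_tail_oracle(k, n, K, N):
    """P(X >= k) by explicit summation of combinatorial terms."""
    total = 0
    denom = math.comb(N, n)
    for i in range(k, min(n, K) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


def bh_oracle(pvals):
    """Benjamini-Hochberg step-up applied by hand."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        q[i] = running
    return q


# ---------- naive MCL ----------

def mcl_oracle(edges, nodes, expansion=2, inflation=2.0, self_loop=1.0,
               prune=1e-5, max_iter=100, tol=1e-8):
    """Naive Markov clustering with plain-python matrix loops."""
    nodes = sorted(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    m = [[0.0] * n for _ in range(n)]
    for u, v in edges:
        m[idx[u]][idx[v]] = 1.0
        m[idx[v]][idx[u]] = 1.0
    for i in range(n):
        m[i][i] += self_loop
    m = _norm_cols(m)
    for _ in range(max_iter):
        e = m
        for _ in range(expansion - 1):
            e = _matmul(e, m)
        f = [[e[i][j] ** inflation for j in range(n)] for i in range(n)]
        for i in range(n):
            for j in range(n):
                if f[i][j] < prune:
                    f[i][j] = 0.0
        new = _norm_cols(f)
        diff = max(
            abs(new[i][j] - m[i][j]) for i in range(n) for j in range(n)
        )
        m = new
        if diff < tol:
            break
    # attractors and cluster merge
    attractors = [i for i in range(n) if m[i][i] > 1e-9]
    if not attractors:
        attractors = list(range(n))
    support = {a: {j for j in range(n) if m[a][j] > 1e-9} for a in attractors}
    group = {a: a for a in attractors}

    def find(a):
        while group[a] != a:
            group[a] = group[group[a]]
            a = group[a]
        return a

    for a, b in combinations(attractors, 2):
        if support[a] & support[b]:
            ra, rb = find(a), find(b)
            if ra != rb:
                group[rb] = ra
    clusters = {}
    for j in range(n):
        best_a = max(attractors, key=lambda a: (m[a][j], -a))
        clusters.setdefault(find(best_a), set()).add(nodes[j])
    return sorted((frozenset(c) for c in clusters.values()),
                  key=lambda b: (-len(b), min(b)))


def _matmul(a, b):
    n = len(a)
    out = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for k in range(n):
            aik = a[i][k]
            if aik == 0.0:
                continue
            row_b = b[k]
            row_o = out[i]
            for j in range(n):
                row_o[j] += aik * row_b[j]
    return out


def _norm_cols(m):
    n = len(m)
    sums = [sum(m[i][j] for i in range(n)) or 1.0 for j in range(n)]
    return [[m[i][j] / sums[j] for j in range(n)] for i in range(n)]
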