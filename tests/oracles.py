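"""Independent reference implementations used only to check the package.

Each oracle is written from the mathematical definition, sharing no code
with the implementation it checks.
"""

from itertools import combinations


def brute_local_score(a: str, b: str, score, gap_open: int, gap_extend: int) -> int:
    """Optimal local alignment score by exhaustive enumeration.

    A local alignment is a pairing of an increasing subsequence of
    positions of ``a`` with one of ``b``; every internal run of skipped
    positions on either side is a gap costing gap_open + L * gap_extend.
    Flanks outside the first/last pair are free. The empty alignment
    scores 0. Feasible only for short sequences.
    """
    n, m = len(a), len(b)
    best = 0
    for k in range(1, min(n, m) + 1):
        for ai in combinations(range(n), k):
            for bj in combinations(range(m), k):
                total = sum(score[a[i]][b[j]] for i, j in zip(ai, bj))
                for t in range(k - 1):
                    ga = ai[t + 1] - ai[t] - 1
                    gb = bj[t + 1] - bj[t] - 1
                    if ga:
                        total -= gap_open + ga * gap_extend
                    if gb:
                        total -= gap_open + gb * gap_extend
                if total > best:
                    best = total
    return best


def mcl_reference(nodes, edges, inflation, expansion=2, selfloop=1.0,
                  prune=1e-5, tol=1e-9, max_iter=200):
    """Plain-Python Markov clustering: column-stochastic flow matrix,
    expansion by matrix power, entrywise inflation, pruning, and the
    attractor-support interpretation. Lists of floats throughout."""
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    M = [[0.0] * n for _ in range(n)]
    for (a, b), w in edges.items():
        i, j = index[a], index[b]
        M[i][j] = w
        M[j][i] = w
    for i in range(n):
        M[i][i] = selfloop

    def colnorm(mat):
        out = [[0.0] * n for _ in range(n)]
        for j in range(n):
            s = sum(mat[i][j] for i in range(n))
            if s > 0:
                for i in range(n):
                    out[i][j] = mat[i][j] / s
        return out

    def matmul(x, y):
        out = [[0.0] * n for _ in range(n)]
        for i in range(n):
            xi = x[i]
            for k in range(n):
                v = xi[k]
                if v:
                    yk = y[k]
                    oi = out[i]
                    for j in range(n):
                        oi[j] += v * yk[j]
        return out

    M = colnorm(M)
    for _ in range(max_iter):
        prev = M
        P = M
        for _ in range(expansion - 1):
            P = matmul(P, M)
        P = [[v ** inflation for v in row] for row in P]
        P = colnorm(P)
        P = [[0.0 if v < prune else v for v in row] for row in P]
        M = colnorm(P)
        delta = max(abs(M[i][j] - prev[i][j]) for i in range(n) for j in range(n))
        if delta < tol:
            break
    assigned = {}
    clusters = []
    for a in range(n):
        if M[a][a] <= 0.0:
            continue
        members = [j for j in range(n) if M[a][j] > 0.0 and j not in assigned]
        if not members:
            continue
        k = len(clusters)
        for j in members:
            assigned[j] = k
        clusters.append(members)
    for j in range(n):
        if j not in assigned:
            assigned[j] = len(clusters)
            clusters.append([j])
    return [frozenset(nodes[j] for j in members) for members in clusters]


def reachability_components(nodes, edge_pairs):
    """Connected components by transitive closure of the adjacency relation."""
    reach = {v: {v} for v in nodes}
    for a, b in edge_pairs:
        reach[a].add(b)
        reach[b].add(a)
    changed = True
    while changed:
        changed = False
        for v in nodes:
            new = set(reach[v])
            for u in reach[v]:
                new |= reach[u]
            if new != reach[v]:
                reach[v] = new
                changed = True
    seen = set()
    comps = []
    for v in nodes:
        if v not in seen:
            comps.append(frozenset(reach[v]))
            seen |= reach[v]
    return comps
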