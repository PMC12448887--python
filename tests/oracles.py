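"""Independent brute-force oracles used to verify the package.

Everything here is deliberately naive (literal loops over the definitions)
and shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools

import numpy as np


def naive_levenshtein(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance."""
    la, lb = len(a), len(b)
    d = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        d[i][0] = i
    for j in range(lb + 1):
        d[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1, d[i - 1][j - 1] + cost)
    return d[la][lb]


def naive_statistics(y, arcs, n, directed, X=None):
    """All ALAAM sufficient statistics by literal summation.

    ``arcs`` is a collection of ordered (i, j) pairs for directed networks
    or unordered-but-stored-once pairs for undirected ones.
    """
    y = list(y)
    arcset = set(arcs)
    if directed:
        w = lambda i, j: (i, j) in arcset
    else:
        w = lambda i, j: (i, j) in arcset or (j, i) in arcset
    dout = [sum(w(i, j) for j in range(n) if j != i) for i in range(n)]
    din = [sum(w(j, i) for j in range(n) if j != i) for i in range(n)]
    out = {
        "attribute_density": sum(y),
        "out_degree_activity": sum(y[i] * dout[i] for i in range(n)),
        "in_degree_activity": sum(y[i] * din[i] for i in range(n)),
    }
    if directed:
        out["direct_contagion"] = sum(y[i] * y[j] for (i, j) in arcset)
        out["reciprocal_contagion"] = sum(
            y[i] * y[j] for i in range(n) for j in range(i + 1, n)
            if w(i, j) and w(j, i))
        ind = closed = trans = 0
        for i in range(n):
            for k in range(n):
                if i == k:
                    continue
                two_paths = sum(1 for j in range(n) if j not in (i, k)
                                and w(i, j) and w(j, k))
                ind += y[i] * y[k] * two_paths
                if w(i, k):
                    closed += y[i] * y[k] * two_paths
        for i, j, k in itertools.permutations(range(n), 3):
            if w(i, j) and w(j, k) and w(i, k):
                trans += y[i] * y[j]
        out["indirect_contagion"] = ind
        out["closed_indirect_contagion"] = closed
        out["transitive_contagion"] = trans
    else:
        pairs = {(min(i, j), max(i, j)) for (i, j) in arcset}
        out["direct_contagion"] = sum(y[i] * y[j] for (i, j) in pairs)
    if X is not None:
        X = np.asarray(X, dtype=float)
        for c in range(X.shape[1]):
            out[f"cov{c}"] = sum(y[i] * X[i, c] for i in range(n))
    return out


def naive_statistic_vector(y, arcs, n, directed, terms, X=None):
    table = naive_statistics(y, arcs, n, directed, X=X)
    return np.array([table[t] for t in terms], dtype=float)


def enumerate_exact_distribution(arcs, n, directed, terms, theta, X=None):
    """Exact ALAAM distribution over all 2^n attribute vectors, computed
    entirely from the naive statistics (bitmask state order)."""
    theta = np.asarray(theta, dtype=float)
    logw = np.empty(2 ** n)
    for state in range(2 ** n):
        y = [(state >> i) & 1 for i in range(n)]
        z = naive_statistic_vector(y, arcs, n, directed, terms, X=X)
        logw[state] = float(theta @ z)
    logw -= logw.max()
    p = np.exp(logw)
    return p / p.sum()


def enumerate_statistic_table(arcs, n, directed, terms, X=None):
    """z(y) for every attribute vector, naive computation (2^n x p)."""
    Z = np.empty((2 ** n, len(terms)))
    for state in range(2 ** n):
        y = [(state >> i) & 1 for i in range(n)]
        Z[state] = naive_statistic_vector(y, arcs, n, directed, terms, X=X)
    return Z


def exact_likelihood_metropolis(Z, y_obs_state, prior_mean, prior_sd, n_iter,
                                seed, step=0.3):
    """Random-walk Metropolis on the exact (fully enumerated) posterior.

    ``Z`` is the naive statistic table; the likelihood is
    theta'z_obs - logsumexp(Z theta). Used as the independent oracle for the
    exchange sampler.
    """
    from scipy.special import logsumexp

    rng = np.random.default_rng(seed)
    p = Z.shape[1]
    z_obs = Z[y_obs_state]
    theta = np.zeros(p)

    def logpost(th):
        return float(th @ z_obs - logsumexp(Z @ th)
                     - 0.5 * np.sum(((th - prior_mean) / prior_sd) ** 2))

    lp = logpost(theta)
    draws = np.empty((n_iter, p))
    for it in range(n_iter):
        prop = theta + step * rng.standard_normal(p)
        lp_prop = logpost(prop)
        if np.log(rng.uniform()) < lp_prop - lp:
            theta, lp = prop, lp_prop
        draws[it] = theta
    return draws


# -- path-enumeration centralities (n <= 6) ---------------------------------

def _all_shortest_paths(nodes, w):
    """dict (s, t) -> (shortest length, count) by enumerating all simple
    paths with depth-first search."""
    info = {}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            best, cnt = None, 0
            stack = [(s, {s})]
            paths = []

            def dfs(v, visited, length):
                nonlocal best, cnt
                if v == t:
                    if best is None or length < best:
                        best, cnt = length, 1
                    elif length == best:
                        cnt += 1
                    return
                for u in nodes:
                    if u not in visited and w(v, u):
                        dfs(u, visited | {u}, length + 1)

            dfs(s, {s}, 0)
            info[(s, t)] = (best, cnt)
    return info


def brute_centralities(arcs, n, directed):
    """(betweenness, harmonic) per node by exhaustive path enumeration.

    Betweenness is unnormalized pair-dependency; harmonic sums 1/d over
    outgoing-path distances with 1/inf = 0.
    """
    arcset = set(arcs)
    if directed:
        w = lambda i, j: (i, j) in arcset
    else:
        w = lambda i, j: (i, j) in arcset or (j, i) in arcset
    nodes = list(range(n))
    info = _all_shortest_paths(nodes, w)
    betw = np.zeros(n)
    for s in nodes:
        for t in nodes:
            if s == t or info[(s, t)][0] is None:
                continue
            d_st, sigma_st = info[(s, t)]
            for v in nodes:
                if v in (s, t):
                    continue
                sv, vt = info.get((s, v)), info.get((v, t))
                if sv[0] is None or vt[0] is None:
                    continue
                if sv[0] + vt[0] == d_st:
                    betw[v] += sv[1] * vt[1] / sigma_st
    if not directed:
        betw /= 2.0  # each unordered pair contributes once
    harm = np.zeros(n)
    for i in nodes:
        for j in nodes:
            if i == j:
                continue
            d = info[(i, j)][0]
            if d is not None:
                harm[i] += 1.0 / d
    return betw, harm


def random_arcs(rng, n, p, directed):
    arcs = []
    for i in range(n):
        for j in range(n):
            if i == j or (not directed and j <= i):
                continue
            if rng.random() < p:
                arcs.append((i, j))
    return arcs
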