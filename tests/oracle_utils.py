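"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the code paths (and, where possible, the
libraries) used by the implementation: the exact-test oracle enumerates
hypergeometric tables with integer binomial coefficients, the posterior
oracle multiplies probabilities directly without log space, and the
centrality oracle works on the adjacency matrix with scipy's csgraph
distances and explicit shortest-path counting.
"""

import math

import numpy as np
from scipy.sparse.csgraph import shortest_path


def enumerate_fisher_p(c00, c01, c10, c11):
    """Two-sided Fisher p by full enumeration over fixed margins."""
    r1, k1 = c00 + c01, c00 + c10
    n = c00 + c01 + c10 + c11
    if r1 in (0, n) or k1 in (0, n):
        return 1.0
    denom = math.comb(n, r1)
    probs = {}
    for a in range(max(0, r1 + k1 - n), min(r1, k1) + 1):
        probs[a] = math.comb(k1, a) * math.comb(n - k1, r1 - a) / denom
    p_obs = probs[c00]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


def brute_posterior(model, b):
    """Direct-product naive-Bayes posterior (no log space)."""
    post = []
    for dk in model.deltas:
        prob = 1.0 / len(model.deltas)
        for c, bi in zip(model.classifiers, b):
            p1 = c.p1_older if dk > c.delta else c.p1_younger
            prob *= p1 if bi else (1 - p1)
        post.append(prob)
    post = np.array(post)
    return post / post.sum()


def adjacency_and_distances(graph):
    nodes = sorted(graph.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for u, v in graph.edges:
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = 1
    D = shortest_path(A, method="D", unweighted=True)
    return nodes, A, D


def brute_centralities(net):
    """Adjacency-matrix oracle for degree/betweenness/closeness/clustering
    (betweenness normalized by (N-1)(N-2)/2, endpoints excluded)."""
    nodes, A, D = adjacency_and_distances(net.graph)
    n = len(nodes)
    deg = A.sum(axis=1)
    clo = (n - 1) / D.sum(axis=1)
    clu = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(A[i])
        k = len(nb)
        if k >= 2:
            clu[i] = A[np.ix_(nb, nb)].sum() / (k * (k - 1))
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        for v in np.argsort(D[s]):
            if v == s or np.isinf(D[s, v]):
                continue
            preds = np.flatnonzero(A[v] * (D[s] == D[s, v] - 1))
            sigma[s, v] = sigma[s, preds].sum()
    btw = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for s in range(n):
            for t in range(s + 1, n):
                if s == i or t == i or np.isinf(D[s, t]):
                    continue
                if D[s, i] + D[i, t] == D[s, t]:
                    acc += sigma[s, i] * sigma[i, t] / sigma[s, t]
        btw[i] = acc / ((n - 1) * (n - 2) / 2.0)
    return nodes, deg, btw, clo, clu


def brute_cpl_within(graph, genes):
    nodes, _, D = adjacency_and_distances(graph)
    idx = {v: i for i, v in enumerate(nodes)}
    sel = [idx[g] for g in genes]
    vals = [
        D[sel[i], sel[j]] for i in range(len(sel)) for j in range(i + 1, len(sel))
    ]
    return float(np.mean(vals))


def brute_cpl_between(graph, genes_a, genes_b):
    nodes, _, D = adjacency_and_distances(graph)
    idx = {v: i for i, v in enumerate(nodes)}
    vals = [
        D[idx[a], idx[b]] for a in genes_a for b in genes_b if a != b
    ]
    return float(np.mean(vals))
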