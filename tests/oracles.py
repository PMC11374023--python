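"""Independent straight-line oracles used to cross-check vectorized code.

Everything here is written with explicit Python loops directly from the
defining formulas, deliberately sharing no code with the package.
"""

import math

import numpy as np


def pearson_pair(x, y) -> float:
    n = len(x)
    xbar = sum(x) / n
    ybar = sum(y) / n
    num = sum((x[i] - xbar) * (y[i] - ybar) for i in range(n))
    den = math.sqrt(sum((x[i] - xbar) ** 2 for i in range(n))
                    * sum((y[i] - ybar) ** 2 for i in range(n)))
    return num / den


def euclid_pair(p, q) -> float:
    return math.sqrt(sum((q[i] - p[i]) ** 2 for i in range(len(p))))


def laplacian_entrywise(A):
    n = A.shape[0]
    At = [[A[i][j] + (1.0 if i == j else 0.0) for j in range(n)] for i in range(n)]
    deg = [sum(At[i]) for i in range(n)]
    L = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            L[i, j] = At[i][j] / math.sqrt(deg[i] * deg[j])
    return L


def gcn_forward_nodewise(X, A, W0, b0, W1, b1):
    """Two-layer GCN logits via per-node neighbourhood sums (no batch norm)."""
    L = laplacian_entrywise(A)
    n, d = X.shape
    h_hidden = W0.shape[1]
    n_cls = W1.shape[1]
    H1 = np.zeros((n, h_hidden))
    for i in range(n):
        agg = np.zeros(d)
        for j in range(n):
            agg += L[i, j] * X[j]
        pre = np.zeros(h_hidden)
        for k in range(h_hidden):
            pre[k] = sum(agg[m] * W0[m, k] for m in range(d)) + b0[k]
        H1[i] = np.maximum(pre, 0.0)
    logits = np.zeros((n, n_cls))
    for i in range(n):
        agg = np.zeros(h_hidden)
        for j in range(n):
            agg += L[i, j] * H1[j]
        for k in range(n_cls):
            logits[i, k] = sum(agg[m] * W1[m, k] for m in range(h_hidden)) + b1[k]
    return logits


def snf_kernel_entrywise(dist, K, mu):
    """Scaled exponential kernel from a distance matrix, entry by entry."""
    n = dist.shape[0]
    mean_knn = []
    for i in range(n):
        others = sorted(dist[i][j] for j in range(n) if j != i)
        mean_knn.append(sum(others[:K]) / K)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            eps = (mean_knn[i] + mean_knn[j] + dist[i, j]) / 3.0
            W[i, j] = math.exp(-dist[i, j] ** 2 / (mu * eps)) if eps > 0 else 1.0
    return (W + W.T) / 2


def _normalize_rows(W):
    n = W.shape[0]
    P = np.zeros_like(W)
    for i in range(n):
        s = sum(W[i][j] for j in range(n) if j != i)
        for j in range(n):
            if i == j:
                P[i, j] = 0.5
            elif s > 0:
                P[i, j] = W[i, j] / (2.0 * s)
    return P


def _local_rows(W, K):
    n = W.shape[0]
    S = np.zeros_like(W)
    for i in range(n):
        cand = sorted((j for j in range(n) if j != i),
                      key=lambda j: (-W[i][j], j))[:K]
        s = sum(W[i][j] for j in cand)
        if s > 0:
            for j in cand:
                S[i, j] = W[i, j] / s
    return S


def snf_straightline(affinities, K, T):
    """Cross-diffusion fusion of fully observed affinities, step by step."""
    m = len(affinities)
    P = [( _normalize_rows(W) + _normalize_rows(W).T) / 2 for W in affinities]
    S = [_local_rows(W, K) for W in affinities]
    n = affinities[0].shape[0]
    for _ in range(T):
        nxt = []
        for v in range(m):
            M = np.zeros((n, n))
            for w in range(m):
                if w != v:
                    M += P[w]
            M /= (m - 1)
            raw = S[v] @ M @ S[v].T
            norm = _normalize_rows(raw)
            nxt.append((norm + norm.T) / 2)
        P = nxt
    fused = np.zeros((n, n))
    for Pv in P:
        fused += Pv
    fused /= m
    return (fused + fused.T) / 2


def median_of_ratios(counts):
    """DESeq2 size factors by direct evaluation of the defining procedure."""
    n, p = counts.shape
    usable = [j for j in range(p) if all(counts[i][j] > 0 for i in range(n))]
    log_gm = {j: sum(math.log(counts[i][j]) for i in range(n)) / n for j in usable}
    factors = []
    for i in range(n):
        ratios = sorted(math.log(counts[i][j]) - log_gm[j] for j in usable)
        k = len(ratios)
        med = ratios[k // 2] if k % 2 else (ratios[k // 2 - 1] + ratios[k // 2]) / 2
        factors.append(math.exp(med))
    return np.array(factors)
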