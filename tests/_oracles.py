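"""Independent brute-force / alternative-algorithm oracles used by the tests.

Everything here is deliberately written from first principles (plain loops,
BFS, closed forms) or routed through an unrelated library implementation
(sklearn coordinate-descent Lasso, Davis-Yin splitting) so the checks are
algorithmically independent of the package code they validate.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from sklearn.linear_model import Lasso


# -- graph metric oracles (plain loops + BFS) -------------------------------


def bfs_distances(adj: np.ndarray, src: int) -> np.ndarray:
    n = adj.shape[0]
    dist = np.full(n, np.inf)
    dist[src] = 0
    q = deque([src])
    while q:
        u = q.popleft()
        for v in np.flatnonzero(adj[u]):
            if dist[v] == np.inf:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def oracle_clustering(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = nbrs.size
        if k < 2:
            continue
        tri = 0
        for a in range(k):
            for b in range(a + 1, k):
                if adj[nbrs[a], nbrs[b]]:
                    tri += 1
        out[i] = 2.0 * tri / (k * (k - 1))
    return out


def oracle_local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = nbrs.size
        if k < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        total = 0.0
        for a in range(k):
            d = bfs_distances(sub, a)
            for b in range(k):
                if b != a and np.isfinite(d[b]):
                    total += 1.0 / d[b]
        out[i] = total / (k * (k - 1))
    return out


def oracle_path_length_global_eff(adj: np.ndarray) -> tuple[float, float]:
    n = adj.shape[0]
    dist_sum = inv_sum = 0.0
    n_finite = 0
    for i in range(n):
        d = bfs_distances(adj, i)
        for j in range(n):
            if j != i and np.isfinite(d[j]):
                dist_sum += d[j]
                inv_sum += 1.0 / d[j]
                n_finite += 1
    L = dist_sum / n_finite if n_finite else float("nan")
    return L, inv_sum / (n * (n - 1))


def oracle_betweenness(adj: np.ndarray) -> np.ndarray:
    """Count shortest paths through each node by explicit sigma counting."""
    n = adj.shape[0]
    dist = np.array([bfs_distances(adj, s) for s in range(n)])
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        for d_level in range(1, n):
            for v in range(n):
                if dist[s, v] == d_level:
                    sigma[s, v] = sum(
                        sigma[s, u] for u in np.flatnonzero(adj[v]) if dist[s, u] == d_level - 1
                    )
    b = np.zeros(n)
    for i in range(n):
        for h in range(n):
            for j in range(n):
                if h == j or h == i or j == i:
                    continue
                if not np.isfinite(dist[h, j]) or sigma[h, j] == 0:
                    continue
                if dist[h, i] + dist[i, j] == dist[h, j]:
                    b[i] += sigma[h, i] * sigma[i, j] / sigma[h, j]
    return b / ((n - 1) * (n - 2))


def oracle_participation(adj: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = adj[i].sum()
        if k == 0:
            continue
        acc = 0.0
        for mod in np.unique(assignment):
            k_m = adj[i, assignment == mod].sum()
            acc += (k_m / k) ** 2
        out[i] = 1.0 - acc
    return out


def oracle_avg_neighbor_degree(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    deg = adj.sum(axis=1)
    out = np.zeros(n)
    for i in range(n):
        if deg[i] > 0:
            out[i] = sum(deg[j] for j in np.flatnonzero(adj[i])) / deg[i]
    return out


def oracle_modularity(adj: np.ndarray, assignment: np.ndarray) -> float:
    two_e = adj.sum()
    deg = adj.sum(axis=1)
    n = adj.shape[0]
    q = 0.0
    for i in range(n):
        for j in range(n):
            if assignment[i] == assignment[j]:
                q += adj[i, j] - deg[i] * deg[j] / two_e
    return q / two_e


# -- convex-program oracles -------------------------------------------------


def slr_objective(X: np.ndarray, A: np.ndarray, lam1: float, lam2: float) -> float:
    val = np.linalg.norm(X - X @ A, "fro") ** 2 + lam1 * np.abs(A).sum()
    if lam2 > 0:
        val += lam2 * np.linalg.svd(A, compute_uv=False).sum()
    return float(val)


def constrained_ls_oracle(X: np.ndarray) -> np.ndarray:
    """Zero-diagonal least squares, solved column by column in closed form."""
    t, m = X.shape
    A = np.zeros((m, m))
    for i in range(m):
        others = [j for j in range(m) if j != i]
        coef, *_ = np.linalg.lstsq(X[:, others], X[:, i], rcond=None)
        A[others, i] = coef
    return A


def lasso_oracle(X: np.ndarray, lam1: float) -> np.ndarray:
    """Zero-diagonal l1 regression via sklearn coordinate descent.

    Per column: ||x_i - Z a||^2 + lam1 ||a||_1 equals 2t * (sklearn Lasso
    objective with alpha = lam1 / (2t)).
    """
    t, m = X.shape
    A = np.zeros((m, m))
    alpha = lam1 / (2.0 * t)
    for i in range(m):
        others = [j for j in range(m) if j != i]
        model = Lasso(alpha=alpha, fit_intercept=False, tol=1e-12, max_iter=200_000)
        model.fit(X[:, others], X[:, i])
        A[others, i] = model.coef_
    return A


def davis_yin_oracle(
    X: np.ndarray, lam1: float, lam2: float, n_iter: int = 20_000
) -> np.ndarray:
    """Davis-Yin three-operator splitting for the sparse low-rank program.

    Smooth part f(A) = ||X - XA||_F^2, g = lam1*l1 + zero-diagonal indicator
    (prox: soft-threshold then zero the diagonal), h = lam2 * trace norm
    (prox: singular-value shrinkage).  Fixed step 1/L with L = 2 lmax(X'X).
    """
    m = X.shape[1]
    G = X.T @ X
    L = 2.0 * np.linalg.eigvalsh(G).max()
    gamma = 1.0 / L
    Z = np.zeros((m, m))
    Ag = np.zeros((m, m))
    for _ in range(n_iter):
        Ag = np.sign(Z) * np.maximum(np.abs(Z) - gamma * lam1, 0.0)
        np.fill_diagonal(Ag, 0.0)
        grad = 2.0 * (G @ Ag - G)
        W = 2.0 * Ag - Z - gamma * grad
        u, s, vt = np.linalg.svd(W, full_matrices=False)
        Ah = (u * np.maximum(s - gamma * lam2, 0.0)) @ vt
        Z = Z + Ah - Ag
    return Ag
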