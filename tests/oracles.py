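"""Independent brute-force / closed-form oracles used by the test suite.

Every oracle recomputes a quantity by a route disjoint from the package's
implementation: direct summation, exhaustive enumeration, dense
eigendecomposition, or convex dual optimization.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp


def entropy_oracle(seq: str) -> float:
    """Tabulate residue counts and sum -p log2 p directly."""
    residues = [c for c in seq.upper() if c.isalpha()]
    counts = Counter(residues)
    n = sum(counts.values())
    return -sum((c / n) * np.log2(c / n) for c in counts.values())


def rmsf_oracle(ca: np.ndarray) -> np.ndarray:
    """Direct per-residue evaluation of the fluctuation sum (mean reference)."""
    S, N, _ = ca.shape
    out = np.zeros(N)
    for r in range(N):
        ref = ca[:, r, :].mean(axis=0)
        acc = 0.0
        for t in range(S):
            diff = ca[t, r, :] - ref
            acc += float(diff @ diff)
        out[r] = np.sqrt(acc / S)
    return out


def di_oracle(logW: np.ndarray, fs: np.ndarray, ft: np.ndarray) -> float:
    """Direct information via the convex Lagrangian dual of the KL projection.

    The two-site direct distribution is the KL projection of exp(logW)
    onto the marginal polytope {P : P 1 = fs, P^T 1 = ft}; its dual is the
    smooth convex function log Z(u, v) - u.fs - v.ft minimized here with
    L-BFGS — a route independent of the package's scaling iteration.
    """
    q = len(fs)

    def obj(z):
        u, v = z[:q], z[q:]
        lZ = logsumexp(u[:, None] + logW + v[None, :])
        P = np.exp(u[:, None] + logW + v[None, :] - lZ)
        grad = np.concatenate([P.sum(1) - fs, P.sum(0) - ft])
        return lZ - u @ fs - v @ ft, grad

    res = minimize(
        obj, np.zeros(2 * q), jac=True, method="L-BFGS-B",
        options={"maxiter": 20000, "ftol": 1e-18, "gtol": 1e-12},
    )
    u, v = res.x[:q], res.x[q:]
    logP = u[:, None] + logW + v[None, :]
    logP -= logsumexp(logP)
    P = np.exp(logP)
    return float(np.sum(P * (logP - np.log(np.outer(fs, ft)))))


def gnm_correlation_oracle(coords: np.ndarray, cutoff: float) -> np.ndarray:
    """Full-spectrum eigendecomposition route to the GNM correlation matrix."""
    from scipy.spatial.distance import cdist

    n = len(coords)
    d = cdist(coords, coords)
    contact = (d <= cutoff) & ~np.eye(n, dtype=bool)
    gamma = -contact.astype(float)
    np.fill_diagonal(gamma, contact.sum(axis=1))
    vals, vecs = np.linalg.eigh(gamma)
    ginv = np.zeros((n, n))
    for lam, v in zip(vals, vecs.T):
        if lam > 1e-10 * vals.max():
            ginv += np.outer(v, v) / lam
    diag = np.sqrt(np.diag(ginv))
    return ginv / np.outer(diag, diag)


def set_partitions(nodes):
    """All partitions of a node collection into disjoint non-empty blocks."""
    nodes = list(nodes)
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for p in set_partitions(rest):
        for i in range(len(p)):
            yield p[:i] + [p[i] | {first}] + p[i + 1 :]
        yield p + [{first}]


def modularity_oracle(A: np.ndarray, part) -> float:
    """Weighted modularity from the adjacency matrix, by direct summation."""
    d = A.sum(axis=1)
    m2 = A.sum()
    q = 0.0
    for block in part:
        idx = list(block)
        q += A[np.ix_(idx, idx)].sum() / m2 - (d[idx].sum() / m2) ** 2
    return q


def max_modularity_partition(graph) -> tuple[float, list]:
    """Exhaustive maximum-modularity partition of a (small) networkx graph."""
    import networkx as nx

    nodes = sorted(graph.nodes, key=str)
    A = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    best_q, best_p = -np.inf, None
    for p in set_partitions(range(len(nodes))):
        q = modularity_oracle(A, p)
        if q > best_q:
            best_q, best_p = q, p
    return best_q, [{nodes[i] for i in block} for block in best_p]


def pagerank_oracle(graph) -> dict:
    """Principal eigenvector of the dense weighted transition matrix.

    Valid for connected graphs with at least one edge; the stationary
    distribution is the (normalized) eigenvector of eigenvalue 1.
    """
    import networkx as nx

    nodes = sorted(graph.nodes, key=str)
    A = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    deg = A.sum(axis=1)
    T = A / deg[None, :]
    vals, vecs = np.linalg.eig(T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, k])
    v = np.abs(v)
    v /= v.sum()
    return dict(zip(nodes, v))


def betweenness_path_oracle(graph) -> dict:
    """Betweenness by explicit shortest-path enumeration (unit weights)."""
    import networkx as nx

    nodes = sorted(graph.nodes, key=str)
    n = len(nodes)
    counts = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            counts[v] += through / len(paths)
    scale = (n - 1) * (n - 2) / 2
    return {v: c / scale if scale else 0.0 for v, c in counts.items()}
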