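"""Independent brute-force reference implementations used only by tests.

Everything here is written directly from the mathematical definitions with
plain double loops, deliberately sharing no code path with the package.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

from schoml.graphs import GraphConfig, build_laplacian_stack


def knn_affinity_bruteforce(X, k, sigma, symmetrize="union"):
    """KNN Gaussian affinity by exhaustive pairwise distances."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    d2 = np.array([[np.sum((X[j] - X[t]) ** 2) for t in range(n)] for j in range(n)])
    directed = np.zeros((n, n), dtype=bool)
    for j in range(n):
        order = sorted((t for t in range(n) if t != j), key=lambda t: (d2[j, t], t))
        directed[j, order[:k]] = True
    if symmetrize == "union":
        conn = directed | directed.T
    else:
        conn = directed & directed.T
    W = np.zeros((n, n))
    for j in range(n):
        for t in range(n):
            if j != t and conn[j, t]:
                W[j, t] = math.exp(-d2[j, t] / (2.0 * sigma**2))
    return W


def high_order_bruteforce(W_prev, sigma):
    """Second-order adjacency by direct double-loop evaluation."""
    W_prev = np.asarray(W_prev, dtype=float)
    n = W_prev.shape[0]
    W = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            shares = any(W_prev[j, t] > 0 and W_prev[k, t] > 0 for t in range(n))
            if shares:
                W[j, k] = math.exp(
                    -float(np.sum((W_prev[j] - W_prev[k]) ** 2)) / (2.0 * sigma**2)
                )
    return W


def silhouette_bruteforce(D, labels):
    """Mean silhouette width from the per-sample definition.

    Singleton-cluster members contribute 0.
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    vals = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            vals.append(0.0)
            continue
        a = sum(D[i, j] for j in own) / len(own)
        b = min(
            sum(D[i, j] for j in range(n) if labels[j] == lab)
            / sum(1 for j in range(n) if labels[j] == lab)
            for lab in set(labels)
            if lab != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def scatter_traces(H, labels):
    """(between, within, total) scatter-matrix traces by direct summation."""
    H = np.asarray(H, dtype=float)
    labels = np.asarray(labels)
    grand = H.mean(axis=0)
    between = within = 0.0
    for lab in set(labels.tolist()):
        block = H[labels == lab]
        c = block.mean(axis=0)
        between += len(block) * float(np.sum((c - grand) ** 2))
        within += float(np.sum((block - c) ** 2))
    total = float(np.sum((H - grand) ** 2))
    return between, within, total


def variance_ratio_bruteforce(H, labels):
    between, within, _ = scatter_traces(H, labels)
    n = len(labels)
    k = len(set(np.asarray(labels).tolist()))
    return (between / (k - 1)) / (within / (n - k))


def ari_contingency(truth, pred):
    """Adjusted Rand index from the pair-counting contingency formula."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    n = len(truth)
    t_labs, p_labs = sorted(set(truth.tolist())), sorted(set(pred.tolist()))
    cont = np.array(
        [[int(np.sum((truth == a) & (pred == b))) for b in p_labs] for a in t_labs]
    )
    sum_comb = sum(math.comb(int(x), 2) for x in cont.ravel())
    a_comb = sum(math.comb(int(x), 2) for x in cont.sum(axis=1))
    b_comb = sum(math.comb(int(x), 2) for x in cont.sum(axis=0))
    total = math.comb(n, 2)
    expected = a_comb * b_comb / total
    max_index = (a_comb + b_comb) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_comb - expected) / (max_index - expected)


def nmi_entropy(truth, pred):
    """NMI (arithmetic normalization) from the entropy definitions."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    n = len(truth)

    def entropy(labels):
        h = 0.0
        for lab in set(labels.tolist()):
            p = np.mean(labels == lab)
            h -= p * math.log(p)
        return h

    mi = 0.0
    for a in set(truth.tolist()):
        for b in set(pred.tolist()):
            pab = float(np.sum((truth == a) & (pred == b))) / n
            if pab > 0:
                pa, pb = float(np.mean(truth == a)), float(np.mean(pred == b))
                mi += pab * math.log(pab / (pa * pb))
    ht, hp = entropy(truth), entropy(pred)
    if ht == 0 and hp == 0:
        return 1.0
    denom = (ht + hp) / 2.0
    return mi / denom if denom > 0 else 0.0


def objective_dense(lam, mu, W, Lam, H, laplacians):
    """Fusion objective by literal matrix arithmetic."""
    n = W.shape[0]
    orders = len(laplacians[0])
    L1 = sum(m * mats[0] for m, mats in zip(mu, laplacians))
    L2 = sum(m * mats[min(1, orders - 1)] for m, mats in zip(mu, laplacians))
    M = np.eye(n) - W @ np.diag(Lam) @ W.T
    G = lam * L1 + (1 - lam) * L2
    return float(np.trace(H.T @ M @ H) + np.sum((M - G) ** 2))


def simplex_lattice(V, step=0.05):
    """All lattice points with the given step on the V-simplex."""
    m = round(1.0 / step)
    pts = []
    for combo in product(range(m + 1), repeat=V - 1):
        if sum(combo) <= m:
            pt = [c / m for c in combo]
            pt.append(1.0 - sum(pt))
            pts.append(np.array(pt))
    return pts


def make_random_stack(rng, n=15, V=2, k=4, d=6):
    """A small two-order Laplacian stack from random modality data."""
    mods = [rng.standard_normal((n, d)) for _ in range(V)]
    return build_laplacian_stack(mods, GraphConfig(k=k, max_order=2))


def random_valid_state(rng, n, c, V):
    """A random state satisfying all the optimizer's constraints."""
    from schoml.fusion import FusionState

    W, _ = np.linalg.qr(rng.standard_normal((n, c)))
    H, _ = np.linalg.qr(rng.standard_normal((n, c)))
    mu = rng.random(V) + 0.1
    mu /= mu.sum()
    return FusionState(
        lam=float(rng.random()),
        mu=mu,
        W=W,
        Lambda=rng.random(c),
        H=H,
    )
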