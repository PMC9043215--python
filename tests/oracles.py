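"""Independent straight-line reference implementations used as test oracles.

Everything here is written with explicit scalar loops, deliberately sharing
no code with the package, so agreement is evidence of correctness rather
than tautology.
"""

import numpy as np


def loop_pairwise_distance(X):
    n, d = X.shape
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = 0.0
            for k in range(d):
                s += (X[i, k] - X[j, k]) ** 2
            D[i, j] = np.sqrt(s)
    return D


def loop_knn_means(D, K):
    """Mean distance of each point to its K nearest others (stable ties)."""
    n = D.shape[0]
    mu = np.zeros(n)
    for i in range(n):
        others = [(D[i, j], j) for j in range(n) if j != i]
        others.sort(key=lambda t: (t[0], t[1]))
        mu[i] = np.mean([d for d, _ in others[:K]])
    return mu


def loop_affinity(D, K, alpha):
    """Scaled exponential kernel, scalar by scalar."""
    n = D.shape[0]
    mu = loop_knn_means(D, K)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            gamma = (mu[i] + mu[j] + D[i, j]) / 3.0
            W[i, j] = np.exp(-(D[i, j] ** 2) / (alpha * gamma))
    return W


def loop_normalize_full(W):
    n = W.shape[0]
    P = np.zeros((n, n))
    for i in range(n):
        s = 0.0
        for k in range(n):
            if k != i:
                s += W[i, k]
        for j in range(n):
            P[i, j] = 0.5 if j == i else W[i, j] / (2.0 * s)
    return P


def loop_local_affinity(W, K):
    """Row-normalized K-neighborhood restriction (row-index denominator)."""
    n = W.shape[0]
    S = np.zeros((n, n))
    for i in range(n):
        others = [(-W[i, j], j) for j in range(n) if j != i]
        others.sort()
        nbrs = [j for _, j in others[:K]]
        denom = sum(W[i, k] for k in nbrs)
        for j in nbrs:
            S[i, j] = W[i, j] / denom
    return S


def loop_snf_fuse(Ws, K, T):
    """Cross-diffusion fusion with explicit loops over views and rounds."""
    m = len(Ws)
    Ps = [loop_normalize_full(W) for W in Ws]
    Ss = [loop_local_affinity(W, K) for W in Ws]
    for _ in range(T):
        new = []
        for h in range(m):
            avg = np.zeros_like(Ps[0])
            for k in range(m):
                if k != h:
                    avg = avg + Ps[k]
            avg = avg / (m - 1)
            new.append(Ss[h] @ avg @ Ss[h].T)
        Ps = [loop_normalize_full(P) for P in new]
    fused = sum(Ps) / m
    return (fused + fused.T) / 2.0


def loop_normalize_adjacency(A):
    n = A.shape[0]
    A_hat = A + np.eye(n)
    deg = A_hat.sum(axis=1)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = A_hat[i, j] / np.sqrt(deg[i]) / np.sqrt(deg[j])
    return out


def loop_gcn_layer(H, A_norm, W, b):
    n, f = H.shape
    f_out = W.shape[1]
    agg = np.zeros((n, f))
    for i in range(n):
        for k in range(n):
            for c in range(f):
                agg[i, c] += A_norm[i, k] * H[k, c]
    out = np.zeros((n, f_out))
    for i in range(n):
        for o in range(f_out):
            s = b[o]
            for c in range(f):
                s += agg[i, c] * W[c, o]
            out[i, o] = max(s, 0.0)
    return out


def straightline_densegcn_forward(X, A_norm, params, n_layers):
    """Reference dense forward with explicit concatenations, no sharing."""
    hs = []
    for ell in range(n_layers):
        H_in = np.hstack([X] + hs) if hs else X
        pre = A_norm @ H_in @ params[f"W{ell}"] + params[f"b{ell}"]
        hs.append(np.maximum(pre, 0.0))
    emb = np.hstack([X] + hs)
    logits = emb @ params["Wc"] + params["bc"]
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs = e / e.sum(axis=1, keepdims=True)
    return emb, probs
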