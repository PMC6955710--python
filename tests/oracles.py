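"""Brute-force enumeration oracles for graph metrics.

Deliberately naive loop implementations, independent of the vectorized
code paths they check.  Orientation convention matches the package:
W[i, j] = weight of the edge j -> i (row = receiver).
"""

import numpy as np


def oracle_degrees(W):
    m = W.shape[0]
    d_in = np.zeros(m, dtype=int)
    d_out = np.zeros(m, dtype=int)
    for i in range(m):
        for j in range(m):
            if i != j and W[i, j] != 0:
                d_in[i] += 1   # j sends into i
                d_out[j] += 1
    return d_in, d_out, d_in + d_out


def oracle_strength(W):
    m = W.shape[0]
    ns = np.zeros(m)
    for i in range(m):
        for j in range(m):
            if i != j:
                ns[i] += W[i, j] + W[j, i]
    return ns


def oracle_clustering(W):
    """Triangle enumeration for Fagiolo's directed weighted clustering."""
    m = W.shape[0]
    A = (W != 0).astype(int)
    C = np.zeros(m)
    for i in range(m):
        d_tot = sum(A[i, j] + A[j, i] for j in range(m) if j != i)
        d_bi = sum(A[i, j] * A[j, i] for j in range(m) if j != i)
        denom = 2.0 * (d_tot * (d_tot - 1) - 2 * d_bi)
        if denom <= 0:
            continue
        total = 0.0
        for j in range(m):
            for h in range(m):
                if j == i or h == i or j == h:
                    continue
                total += (
                    (np.cbrt(W[j, i]) + np.cbrt(W[i, j]))
                    * (np.cbrt(W[h, j]) + np.cbrt(W[j, h]))
                    * (np.cbrt(W[i, h]) + np.cbrt(W[h, i]))
                )
        C[i] = total / denom
    return C


def oracle_path_length(W):
    """Floyd-Warshall on reciprocal weights; mean over finite ordered pairs."""
    m = W.shape[0]
    INF = np.inf
    D = np.full((m, m), INF)
    for i in range(m):
        D[i, i] = 0.0
    for i in range(m):
        for j in range(m):
            if i != j and W[j, i] != 0:  # edge i -> j has weight W[j, i]
                D[i, j] = 1.0 / W[j, i]
    for k in range(m):
        for i in range(m):
            for j in range(m):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    finite = []
    unreachable = 0
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            if np.isfinite(D[i, j]):
                finite.append(D[i, j])
            else:
                unreachable += 1
    if not finite:
        raise ValueError("no connected pair")
    return float(np.mean(finite)), unreachable / (m * (m - 1))


def oracle_hif_outflow(block):
    """Loop-based per-sender outflow of a (receivers x senders) block."""
    n_recv, n_send = block.shape
    out = np.zeros(n_send)
    for j in range(n_send):
        for i in range(n_recv):
            out[j] += block[i, j]
    return out
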