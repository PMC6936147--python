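"""Independent brute-force reference implementations used as test oracles.

Everything here is written with explicit pair-by-pair loops and deliberately
shares no code with the package, so agreement is meaningful.
"""

import math

import numpy as np


def brute_force_pcc(values, cutoff, min_samples=3):
    """Pairwise Pearson correlations, thresholded: |r| > cutoff kept as |r|.

    ``values`` is a samples x genes array; NaNs handled pairwise-complete.
    """
    n_genes = values.shape[1]
    out = np.zeros((n_genes, n_genes))
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            x, y = values[:, i], values[:, j]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < min_samples:
                continue
            x, y = x[ok], y[ok]
            mx, my = x.mean(), y.mean()
            sxx = ((x - mx) ** 2).sum()
            syy = ((y - my) ** 2).sum()
            if sxx == 0 or syy == 0:
                continue
            r = ((x - mx) * (y - my)).sum() / math.sqrt(sxx * syy)
            if abs(r) > cutoff:
                out[i, j] = out[j, i] = abs(r)
    return out


def brute_force_ecc(W, classic=False):
    """Edge clustering coefficients by explicit common-neighbor enumeration.

    ECC(i,j) = sum_{k in N_i ^ N_j} (W_ik + W_jk) / min(d_i, d_j) on the
    support of W, zero elsewhere.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    nbrs = [set(np.flatnonzero(W[i] != 0)) for i in range(n)]
    deg = [len(s) for s in nbrs]
    out = np.zeros_like(W)
    for i in range(n):
        for j in range(n):
            if i == j or W[i, j] == 0:
                continue
            num = 0.0
            for k in nbrs[i] & nbrs[j]:
                num += W[i, k] + W[j, k]
            if classic:
                denom = max(min(deg[i] - 1, deg[j] - 1), 1)
            else:
                denom = min(deg[i], deg[j])
            out[i, j] = num / denom
    return out


def random_weighted_graph(rng, n_nodes, edge_prob):
    """Symmetric nonnegative weight matrix of a random graph, U(0,1) weights."""
    W = np.zeros((n_nodes, n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                W[i, j] = W[j, i] = rng.random()
    return W
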