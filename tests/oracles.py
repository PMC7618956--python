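"""Independent brute-force oracle implementations used by the tests.

Everything here is written as plain loops, kept deliberately separate
from the vectorised/autodiff implementations in the package so the two
routes can be compared.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def trilinear_point(volume: np.ndarray, z: float, y: float, x: float) -> float:
    """Trilinear interpolation at one (interior) point, eight-corner sum."""
    z0, y0, x0 = int(math.floor(z)), int(math.floor(y)), int(math.floor(x))
    fz, fy, fx = z - z0, y - y0, x - x0
    total = 0.0
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                w = ((fz if dz else 1 - fz)
                     * (fy if dy else 1 - fy)
                     * (fx if dx else 1 - fx))
                total += w * float(volume[z0 + dz, y0 + dy, x0 + dx])
    return total


def recon_loss_loops(x: np.ndarray, mu_x: np.ndarray, sizes: np.ndarray) -> float:
    """(1/b) sum_i sum_j ||x_ij - mu_ij||^2 / a_ij^3 with explicit loops."""
    b, r = x.shape[:2]
    total = 0.0
    for i in range(b):
        for j in range(r):
            sse = 0.0
            for v in (x[i, j] - mu_x[i, j]).ravel():
                sse += float(v) * float(v)
            total += sse / float(sizes[i, j]) ** 3
    return total / b


def kl_loss_loops(mu: np.ndarray, sigma: np.ndarray, b: int) -> float:
    """(1/(b d)) sum of 0.5 (mu^2 + sigma^2 - 1 - ln sigma^2), looped."""
    d = mu.shape[-1]
    total = 0.0
    for m, s in zip(mu.reshape(-1, d), sigma.reshape(-1, d)):
        for k in range(d):
            total += 0.5 * (m[k] ** 2 + s[k] ** 2 - 1.0
                            - math.log(s[k] ** 2))
    return total / (b * d)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(u @ v) / (nu * nv)


def similarity_tensor_loops(emb: np.ndarray) -> np.ndarray:
    """S[j,i,k,l] = cos(emb[i,j], emb[l,k]) by quadruple loop."""
    b, r, _ = emb.shape
    S = np.zeros((r, b, r, b))
    for j in range(r):
        for i in range(b):
            for k in range(r):
                for l in range(b):
                    S[j, i, k, l] = cosine(emb[i, j], emb[l, k])
    return S


def multi_similarity_loops(S: np.ndarray, alpha: float, beta: float,
                           lam: float) -> float:
    """Scalar quadruple-loop multi-similarity loss."""
    r, b = S.shape[0], S.shape[1]
    total = 0.0
    for i in range(b):
        for j in range(r):
            pos = 0.0
            for k in range(r):
                if k != j:
                    pos += math.exp(-alpha * (S[j, i, k, i] - lam))
            neg = 0.0
            for k in range(r):
                for l in range(b):
                    if l != i:
                        neg += math.exp(beta * (S[j, i, k, l] - lam))
            total += math.log(1 + pos) / alpha + math.log(1 + neg) / beta
    return total / (b * r)


def best_partial_bijection_mean(D: np.ndarray) -> float:
    """Maximum over all partial bijections of size min(n, m) of the mean
    of selected entries — exhaustive enumeration (small matrices only)."""
    n, m = D.shape
    k = min(n, m)
    best = -np.inf
    rows_iter = itertools.permutations(range(n), k) if n >= m else [tuple(range(n))]
    for rows in rows_iter:
        cols_iter = [tuple(range(m))] if n >= m else itertools.permutations(range(m), k)
        for cols in cols_iter:
            total = sum(D[r, c] for r, c in zip(rows, cols))
            best = max(best, total / k)
    return best
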