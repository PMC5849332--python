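"""Independent brute-force reference implementations used only by the tests.

These deliberately avoid the package's vectorised code paths: Spearman comes
from scipy.stats.spearmanr, empirical link probabilities from explicit
counting loops, and scores from dictionary arithmetic.
"""
import math

import numpy as np
from scipy.stats import spearmanr


def brute_rho_matrix(matrix: np.ndarray) -> np.ndarray:
    # quantized at 1e-9, matching the network's tie-stability convention
    rho = spearmanr(matrix.T).statistic
    return np.round(np.atleast_2d(rho), 9)


def brute_link_weights(rho: np.ndarray, subset: list[int]) -> dict:
    """-log10 empirical link p for every ordered pair in subset (counting loop)."""
    n = rho.shape[0]
    W = {}
    for i in subset:
        bg = [rho[i, k] for k in range(n) if k != i]
        N = len(bg)
        for j in subset:
            if j == i:
                continue
            x = rho[i, j]
            cnt = sum(1 for r in bg if r > x)
            p = (cnt + 1) / (N + 1)
            W[(i, j)] = 0.0 if x <= 0 else -math.log10(p)
    return W


def brute_link_pvalues(rho: np.ndarray, subset: list[int]) -> dict:
    n = rho.shape[0]
    P = {}
    for i in subset:
        bg = [rho[i, k] for k in range(n) if k != i]
        N = len(bg)
        for j in subset:
            if j == i:
                continue
            cnt = sum(1 for r in bg if r > rho[i, j])
            P[(i, j)] = (cnt + 1) / (N + 1)
    return P


def brute_scores(W: dict, subset: list[int]) -> tuple[dict, dict]:
    """Initial and iterative NDA scores from a pairwise weight dictionary."""
    s = {i: sum(W[(i, j)] for j in subset if j != i) for i in subset}
    s_iter = {}
    for i in subset:
        kept = [j for j in subset if j != i and s[j] <= s[i]]
        s_iter[i] = sum(W[(i, j)] for j in kept)
    return s, s_iter


def brute_bh(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values, step-up with monotone enforcement."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda k: pvalues[k])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        k = order[rank_from_top - 1]
        val = min(prev, pvalues[k] * m / rank_from_top)
        adj[k] = val
        prev = val
    return adj


def brute_ks_statistic(a: list[float], b: list[float]) -> float:
    """Two-sample KS statistic from explicit ECDF evaluation."""
    points = sorted(set(a) | set(b))
    d = 0.0
    for x in points:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        d = max(d, abs(fa - fb))
    return d
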