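"""Network density scores.

For a chosen subset of network nodes, each node's NDA score is

    s = sum over subset partners j of -log10 p(node -> j)

with anti-correlated links contributing zero.  The iterative recalculation
then guards against inflation by strong neighbours: nodes are ranked by their
initial score, and each node's score is recomputed over the subset with all
strictly-stronger nodes removed (ties share a rank and stay in together).
The corrected coexpression score ccs = s / n_res (n_res = number of
independent region groups) makes scores comparable across analyses of
different sizes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .atlas import CoexpressionNetwork


@dataclass
class NdaScore:
    node: str
    s: float
    s_iterative: float
    ccs: float


def subset_scores(weights: np.ndarray) -> np.ndarray:
    """Initial NDA score per node: row sums of the -log10 p weight matrix."""
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weights must be a square matrix")
    return W.sum(axis=1)


def iterative_scores(weights: np.ndarray, initial: np.ndarray | None = None) -> np.ndarray:
    """Recompute each node's score after removing all strictly stronger nodes.

    The ranking is taken once, from the initial scores; the top node keeps its
    full score, and equal-scoring nodes are kept together.
    """
    W = np.asarray(weights, dtype=float)
    s = subset_scores(W) if initial is None else np.asarray(initial, dtype=float)
    keep = s[None, :] <= s[:, None]  # j kept for i unless s_j > s_i
    return (W * keep).sum(axis=1)


def corrected_score(s: float | np.ndarray, n_res: int) -> float | np.ndarray:
    """ccs = s / n_res; n_res is the number of independent region groups."""
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    return s / n_res


def nda_score(node: str, subset: Sequence[str], network: CoexpressionNetwork) -> float:
    """NDA score of a single node within *subset* (which must contain it)."""
    if node not in subset:
        raise ValueError("node must be a member of the subset")
    if len(subset) == 1:
        return 0.0
    idx = network.indices_of(list(subset))
    W = network.weight_matrix(idx)
    return float(W[list(subset).index(node)].sum())


def score_subset(
    network: CoexpressionNetwork, subset_ids: Sequence[str], n_res: int | None = None
) -> list[NdaScore]:
    """Initial, iterative and corrected scores for every member of a subset."""
    idx = network.indices_of(list(subset_ids))
    W = network.weight_matrix(idx)
    s = subset_scores(W)
    s_it = iterative_scores(W, s)
    n_res = n_res if n_res is not None else len(subset_ids)
    ccs = corrected_score(s_it, n_res)
    return [
        NdaScore(node=r, s=float(a), s_iterative=float(b), ccs=float(c))
        for r, a, b, c in zip(subset_ids, s, s_it, ccs)
    ]
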