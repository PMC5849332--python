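"""Expression atlas and the coexpression network built on it.

Pairwise relationships between regulatory regions are Spearman rank
correlations of their activity profiles across samples.  Each correlation is
then converted into a node-specific, *directional* empirical link probability:
for index node i with observed correlation x to node j,

    p(i -> j) = (#{r > x} + 1) / (N + 1)

where r runs over all N correlations of node i against every other node in
the whole network A.  The add-one pseudo-count keeps p strictly positive (the
literal count ratio can reach zero, which would make the -log10 link weight
infinite).  Using the node's own empirical distribution controls for hub
nodes whose expression profile resembles many others.  Anti-correlated pairs
(x <= 0) receive zero weight downstream but remain part of each node's
background distribution.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

log = logging.getLogger(__name__)


@dataclass
class ExpressionAtlas:
    """Regions × samples non-negative activity matrix with sample annotations."""

    matrix: np.ndarray
    region_ids: list[str]
    sample_ids: list[str]
    cell_types: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n, m = self.matrix.shape
        if n != len(self.region_ids) or m != len(self.sample_ids) or m != len(self.cell_types):
            raise ValueError("atlas dimensions inconsistent with annotations")
        if (self.matrix < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def expressed_mask(self, threshold: float = 0.0) -> np.ndarray:
        """True for regions with activity above *threshold* in at least one sample."""
        return (self.matrix > threshold).any(axis=1)

    def subset_regions(self, mask_or_ids) -> "ExpressionAtlas":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            pos = {rid: i for i, rid in enumerate(self.region_ids)}
            idx = np.array([pos[r] for r in mask_or_ids], dtype=int)
        return ExpressionAtlas(
            matrix=self.matrix[idx],
            region_ids=[self.region_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            cell_types=list(self.cell_types),
        )

    def celltype_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Mean activity per cell type (regions × cell types, types sorted)."""
        types = sorted(set(self.cell_types))
        cols = np.empty((self.n_regions, len(types)))
        ct = np.asarray(self.cell_types)
        for k, t in enumerate(types):
            cols[:, k] = self.matrix[:, ct == t].mean(axis=1)
        return cols, types


@dataclass(frozen=True)
class LinkP:
    """A directional empirical link probability between two network nodes."""

    source: str
    target: str
    rho: float
    p: float


def spearman(u: Sequence[float], v: Sequence[float]) -> float:
    """Spearman rank correlation with midranks for ties.

    Returns NaN (with a warning) when either vector has zero variance.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or len(u) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    ru, rv = rankdata(u), rankdata(v)
    su, sv = ru.std(), rv.std()
    if su == 0 or sv == 0:
        warnings.warn("zero-variance vector: Spearman undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(ru, rv)[0, 1])


def _rank_rows(matrix: np.ndarray) -> np.ndarray:
    ranks = np.apply_along_axis(rankdata, 1, matrix)
    return ranks


def spearman_matrix(matrix: np.ndarray, chunk: int = 512) -> np.ndarray:
    """All pairwise Spearman correlations between rows, computed in row blocks.

    Results are independent of the chunk size; rows with zero rank variance
    yield NaN against every partner.
    """
    ranks = _rank_rows(np.asarray(matrix, dtype=float))
    mu = ranks.mean(axis=1, keepdims=True)
    z = ranks - mu
    norm = np.sqrt((z**2).sum(axis=1))
    bad = norm == 0
    norm[bad] = 1.0
    z /= norm[:, None]
    n = z.shape[0]
    out = np.empty((n, n))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        out[lo:hi] = z[lo:hi] @ z.T
    out = np.clip(out, -1.0, 1.0)
    np.fill_diagonal(out, 1.0)
    if bad.any():  # zero-variance rows stay NaN, including on the diagonal
        out[bad, :] = np.nan
        out[:, bad] = np.nan
    return out


class CoexpressionNetwork:
    """The whole-atlas network A: correlations plus per-node empirical backgrounds.

    Nodes are the expressed regions of the atlas.  Regions with constant
    expression across samples (undefined correlation) are excluded with a
    warning.
    """

    def __init__(
        self,
        atlas: ExpressionAtlas,
        min_background: int = 50,
        expression_threshold: float = 0.0,
    ):
        expressed = atlas.expressed_mask(expression_threshold)
        if not expressed.all():
            log.info("excluding %d non-expressed regions from the network", int((~expressed).sum()))
        sub = atlas.subset_regions(expressed)
        # quantize at 1e-9: rank correlations are rationals on a much coarser
        # grid, and strict-inequality counts must not depend on summation order
        rho = np.round(spearman_matrix(sub.matrix), 9)
        defined = ~np.isnan(rho).all(axis=1)
        # constant rows produce all-NaN correlations
        const = np.isnan(np.diag(rho)) | ~defined
        variable = ~const
        if const.any():
            warnings.warn(
                f"excluding {int(const.sum())} constant-expression regions (Spearman undefined)"
            )
            sub = sub.subset_regions(variable)
            rho = rho[np.ix_(variable, variable)]
        n = rho.shape[0]
        if n - 1 < min_background:
            raise ValueError(
                f"only {n - 1} comparison nodes; empirical distributions need >= {min_background}"
            )
        self.atlas = sub
        self.region_ids = list(sub.region_ids)
        self._pos = {rid: i for i, rid in enumerate(self.region_ids)}
        self.rho = rho
        # per-node sorted background: all correlations of node i in A (self excluded)
        bg = rho.copy()
        np.fill_diagonal(bg, -np.inf)
        self._sorted_bg = np.sort(bg, axis=1)  # first column is the -inf self slot
        self.n_background = n - 1

    @property
    def n_nodes(self) -> int:
        return len(self.region_ids)

    def index_of(self, region_id: str) -> int:
        return self._pos[region_id]

    def node_empirical_distribution(self, i: int | str) -> np.ndarray:
        """Sorted correlations of node i versus every other node in A."""
        if isinstance(i, str):
            i = self.index_of(i)
        return self._sorted_bg[i, 1:].copy()

    def _pvalues_for_row(self, i: int, x: np.ndarray) -> np.ndarray:
        N = self.n_background
        # count of background correlations strictly greater than x
        cnt = N - (np.searchsorted(self._sorted_bg[i], x, side="right") - 1)
        return (cnt + 1.0) / (N + 1.0)

    def link_p(self, i: int | str, j: int | str) -> LinkP:
        """Directional empirical probability of a correlation >= rho(i, j) by chance."""
        ii = self.index_of(i) if isinstance(i, str) else i
        jj = self.index_of(j) if isinstance(j, str) else j
        if ii == jj:
            raise ValueError("self-links are undefined")
        x = self.rho[ii, jj]
        p = float(self._pvalues_for_row(ii, np.array([x]))[0])
        return LinkP(source=self.region_ids[ii], target=self.region_ids[jj], rho=float(x), p=p)

    def pvalue_matrix(self, subset: Sequence[int]) -> np.ndarray:
        """Directional link p-values among *subset* (diagonal = 1), sign ignored.

        Used by the grouping step, where the correlation p-value itself is
        thresholded.
        """
        idx = np.asarray(subset, dtype=int)
        k = len(idx)
        P = np.ones((k, k))
        for a, i in enumerate(idx):
            P[a] = self._pvalues_for_row(i, self.rho[i, idx])
        np.fill_diagonal(P, 1.0)
        return P

    def weight_matrix(self, subset: Sequence[int]) -> np.ndarray:
        """-log10 link p among *subset*; anti-correlated pairs (rho <= 0) weigh 0."""
        idx = np.asarray(subset, dtype=int)
        k = len(idx)
        W = np.zeros((k, k))
        for a, i in enumerate(idx):
            x = self.rho[i, idx]
            w = -np.log10(self._pvalues_for_row(i, x))
            w[x <= 0] = 0.0
            W[a] = w
        np.fill_diagonal(W, 0.0)
        return W

    def indices_of(self, region_ids: Sequence[str]) -> np.ndarray:
        return np.array([self._pos[r] for r in region_ids], dtype=int)
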