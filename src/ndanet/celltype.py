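"""Cell-type and tissue specificity of significantly coexpressed regions.

For each region of the significant set, cell types are ranked by that
region's activity (cell types in which the region is inactive share the tail
midrank, so all lists have equal length).  The per-region lists are combined
by robust rank aggregation (RRA): for each cell type the vector of normalized
ranks r across the n lists is sorted and scored

    rho = min_k  P( Beta(k, n - k + 1) <= r_(k) ),

the smallest order-statistic p-value; the reported rra_p = min(1, rho * n)
is Bonferroni-corrected over k.  Because sample composition biases raw RRA
(well-represented or broadly active cell types rank high for any region
set), each cell type's rho is then compared with rho values from many random
selections of n regions, giving an empirical p, followed by BH FDR across
cell types.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import betainc
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .atlas import ExpressionAtlas

log = logging.getLogger(__name__)


@dataclass
class CellTypeResult:
    cell_type: str
    rra_rho: float
    rra_p: float
    empirical_p: float
    fdr: float
    n_regions_used: int


def rank_samples_per_region(expression: Sequence[float], active_threshold: float = 0.0) -> np.ndarray:
    """Rank cell types for one region: 1 = most active; ties get midranks.

    Cell types in which the region is inactive (expression <= threshold) share
    the worst rank m, so the normalized rank is 1 and the Beta order-statistic
    score treats inactivity as carrying no evidence of specificity (rather
    than as an unusually consistent mid-list placement).
    """
    e = np.asarray(expression, dtype=float)
    ranks = np.full(len(e), float(len(e)))
    active = e > active_threshold
    if active.any():
        ranks[active] = rankdata(-e[active], method="average")
    return ranks


def normalized_rank_matrix(
    ct_matrix: np.ndarray, active_threshold: float = 0.0
) -> np.ndarray:
    """Normalized (rank / m) cell-type ranks for every region (regions × cell types)."""
    n, m = ct_matrix.shape
    out = np.empty((n, m))
    for i in range(n):
        out[i] = rank_samples_per_region(ct_matrix[i], active_threshold) / m
    return out


def _beta_scores(sorted_r: np.ndarray) -> np.ndarray:
    """rho per column: min over k of Beta(k, n-k+1) CDF at the k-th order statistic.

    *sorted_r* has shape (n_lists, ...) with normalized ranks sorted ascending
    along axis 0.
    """
    n = sorted_r.shape[0]
    k = np.arange(1, n + 1, dtype=float).reshape((n,) + (1,) * (sorted_r.ndim - 1))
    cdf = betainc(k, n - k + 1, np.clip(sorted_r, 0.0, 1.0))
    return cdf.min(axis=0)


def rra_aggregate(norm_ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Robust rank aggregation of n lists (rows) over m items (columns).

    Returns (rho, rra_p) per item, where rra_p = min(1, rho * n).
    """
    r = np.asarray(norm_ranks, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2:
        raise ValueError("need at least 2 ranked lists")
    rho = _beta_scores(np.sort(r, axis=0))
    return rho, np.minimum(1.0, rho * r.shape[0])


def celltype_empirical(
    selected_region_ids: Sequence[str],
    atlas: ExpressionAtlas,
    n_perms: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    fdr_threshold: float = 0.05,
    active_threshold: float = 0.0,
    chunk: int = 200,
) -> pd.DataFrame:
    """Permutation-controlled cell-type specificity for a selected region set.

    Permutations redraw *n* regions uniformly (without replacement) from all
    expressed atlas regions and recompute the RRA score, so cell types that
    rank high for any random region set are not called.  empirical_p uses the
    add-one rule; FDR is BH across cell types.
    """
    n_sel = len(selected_region_ids)
    if n_sel < 2:
        raise ValueError("need at least 2 selected regions for rank aggregation")
    rng = rng or np.random.default_rng()

    expressed = atlas.expressed_mask(active_threshold)
    pool_atlas = atlas.subset_regions(expressed)
    ct_matrix, cell_types = pool_atlas.celltype_matrix()
    norm_ranks = normalized_rank_matrix(ct_matrix, active_threshold)

    pos = {rid: i for i, rid in enumerate(pool_atlas.region_ids)}
    sel_idx = np.array([pos[r] for r in selected_region_ids], dtype=int)
    obs_rho, obs_rra_p = rra_aggregate(norm_ranks[sel_idx])

    n_pool_regions = norm_ranks.shape[0]
    worse = np.zeros(len(cell_types), dtype=np.int64)
    done = 0
    while done < n_perms:
        b = min(chunk, n_perms - done)
        draws = np.stack(
            [rng.choice(n_pool_regions, size=n_sel, replace=False) for _ in range(b)]
        )  # (b, n_sel)
        ranks = norm_ranks[draws]  # (b, n_sel, m)
        perm_rho = _beta_scores(np.sort(np.swapaxes(ranks, 0, 1), axis=0))  # (b, m)
        worse += (perm_rho <= obs_rho[None, :]).sum(axis=0)
        done += b
    empirical_p = (1.0 + worse) / (1.0 + n_perms)
    fdr = multipletests(empirical_p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "cell_type": cell_types,
            "rra_rho": obs_rho,
            "rra_p": obs_rra_p,
            "empirical_p": empirical_p,
            "fdr": fdr,
            "n_regions_used": n_sel,
            "significant": fdr < fdr_threshold,
        }
    )
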