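"""Circular-permutation null models and empirical significance.

The null for the NDA score must preserve the positional structure of the
input: SNPs cluster in linkage blocks, and regulatory regions cluster on the
genome.  Two circular schemes are used.  *Pre-mapping* permutations rotate
the putatively-significant SNP set K on the concatenated circular genome and
re-map it to regulatory regions; the resulting p-value mixes coexpression
with the enrichment of trait SNPs in regulatory sequence.  *Post-mapping*
permutations rotate the indices of the observed (grouped) region set on the
genomically-ordered list of all network nodes, preserving the number of
nodes; the resulting p-value isolates the coexpression signal and is the
default.

Each permuted subset is grouped by the same distance/correlation rules as
the observed set.  If the permuted grouping does not reproduce the observed
group-size multiset, the permutation is redrawn up to 8 times; after that
the nearest-sized permuted groups are padded with consecutive neighbouring
regions (and oversized ones trimmed) until the multiset matches exactly.

Observed scores are converted to empirical p-values against the pooled
distribution of permuted scores, with an add-one pseudo-count, and corrected
across nodes by Benjamini-Hochberg.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from statsmodels.stats.multitest import multipletests

from .atlas import CoexpressionNetwork
from .grouping import RegionGroup, build_groups
from .nda_core import iterative_scores, subset_scores
from .regions import RegulatoryRegion, SnpRecord, map_snps_to_regions

log = logging.getLogger(__name__)


@dataclass
class PermutationSet:
    mode: str  # pre_mapping | post_mapping
    n_perms: int
    offsets: list[int] = field(default_factory=list)
    subset_sizes: list[int] = field(default_factory=list)
    group_sizes: list[list[int]] = field(default_factory=list)  # realized, sorted desc
    scores: list[np.ndarray] = field(default_factory=list)
    n_repaired: int = 0

    def pooled(self) -> np.ndarray:
        if not self.scores:
            return np.empty(0)
        return np.concatenate(self.scores)


def circular_shift_snps(
    snps: Sequence[SnpRecord], genome: Sequence[tuple[str, int]], offset: int
) -> list[SnpRecord]:
    """Rotate SNP positions by *offset* bp on the concatenated circular genome."""
    chroms = [c for c, _ in genome]
    lengths = np.array([l for _, l in genome], dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    total = int(lengths.sum())
    if offset % total == 0:
        raise ValueError("offset equivalent to the identity permutation")
    start_of = dict(zip(chroms, starts))
    out = []
    for s in snps:
        if s.chrom not in start_of:
            raise ValueError(f"SNP chromosome {s.chrom} not in genome table")
        coord = (start_of[s.chrom] + s.pos - 1 + offset) % total
        ci = int(np.searchsorted(starts, coord, side="right") - 1)
        out.append(SnpRecord(s.snp_id, chroms[ci], int(coord - starts[ci]) + 1, s.pvalue))
    return out


def circular_shift_regions(subset_idx: Sequence[int], n_list: int, offset: int) -> np.ndarray:
    """Shift list indices by *offset* places on the circular ordered region list."""
    if offset % n_list == 0:
        raise ValueError("offset equivalent to the identity permutation")
    return (np.asarray(subset_idx, dtype=int) + offset) % n_list


def _quick_representatives(network: CoexpressionNetwork, groups: Sequence[RegionGroup]) -> list[str]:
    """One-round representative choice for permuted groupings (cheap path)."""
    reps = []
    for g in groups:
        if len(g.members) == 1:
            reps.append(g.members[0])
            continue
        opponents = [m for h in groups if h is not g for m in h.members]
        best, best_score = g.members[0], -np.inf
        for m in sorted(g.members):
            W = network.weight_matrix(network.indices_of([m] + opponents))
            score = float(W[0].sum())
            if score > best_score + 1e-12:
                best, best_score = m, score
        reps.append(best)
    return reps


def _repair_grouping(
    groups: list[list[int]],
    target_sizes: list[int],
    n_list: int,
    used: set[int],
    rng: np.random.Generator,
) -> list[list[int]]:
    """Force a permuted grouping to the observed group-size multiset.

    Groups are matched to target sizes in decreasing order.  Undersized groups
    are padded with consecutive neighbouring positions on the ordered region
    list (alternating after/before the group's span); oversized ones are
    trimmed from the end; surplus groups are dropped and missing ones are
    seeded at random unused positions.
    """
    targets = sorted(target_sizes, reverse=True)
    groups = sorted(groups, key=lambda g: (-len(g), g[0]))

    def pad(members: list[int], size: int) -> list[int]:
        members = list(members)
        lo, hi = min(members), max(members)
        step = 1
        while len(members) < size:
            for cand in ((hi + step) % n_list, (lo - step) % n_list):
                if cand not in used and len(members) < size:
                    members.append(cand)
                    used.add(cand)
            step += 1
            if step > n_list:
                raise RuntimeError("cannot pad group: ordered region list exhausted")
        return members

    repaired: list[list[int]] = []
    for k, size in enumerate(targets):
        if k < len(groups):
            members = groups[k][:size]  # trim if oversized
            for m in groups[k][size:]:
                used.discard(m)
        else:
            seed = int(rng.integers(0, n_list))
            while seed in used:
                seed = (seed + 1) % n_list
            used.add(seed)
            members = [seed]
        repaired.append(pad(members, size))
    for g in groups[len(targets):]:  # surplus groups dropped
        for m in g:
            used.discard(m)
    return repaired


def post_mapping_null(
    network: CoexpressionNetwork,
    ordered_ids: Sequence[str],
    observed_groups: Sequence[RegionGroup],
    n_perms: int,
    rng: np.random.Generator,
    distance: int = 100_000,
    p_cut: float = 0.1,
    regions_by_id: Optional[dict[str, RegulatoryRegion]] = None,
    use_iterative: bool = True,
    max_retries: int = 8,
) -> PermutationSet:
    """Scores of circularly-permuted region subsets, group-structure matched.

    *ordered_ids* is the genomically-ordered list of all network nodes (the
    list A the rotation acts on); *observed_groups* define the subset and the
    group-size multiset every permutation must reproduce.
    """
    n_list = len(ordered_ids)
    pos = {rid: i for i, rid in enumerate(ordered_ids)}
    obs_idx = np.array([pos[m] for g in observed_groups for m in g.members], dtype=int)
    target_sizes = sorted((len(g.members) for g in observed_groups), reverse=True)
    n_nodes = len(observed_groups)
    all_singletons = all(s == 1 for s in target_sizes)

    # distinct nonzero offsets so no two permutations coincide
    if n_perms > n_list - 1:
        raise ValueError(f"cannot draw {n_perms} distinct offsets from a list of {n_list}")
    offsets = rng.choice(np.arange(1, n_list), size=n_perms, replace=False)

    result = PermutationSet(mode="post_mapping", n_perms=n_perms)

    def group_indices(idx: np.ndarray) -> list[list[int]]:
        if regions_by_id is None:
            return [[int(i)] for i in idx]
        regs = [regions_by_id[ordered_ids[i]] for i in idx]
        grps = build_groups(regs, network, distance=distance, p_cut=p_cut)
        return [[pos[m] for m in g.members] for g in grps]

    for off in offsets:
        idx = circular_shift_regions(obs_idx, n_list, int(off))
        grp_idx = group_indices(idx)
        sizes = sorted((len(g) for g in grp_idx), reverse=True)
        tries = 0
        while sizes != target_sizes and tries < max_retries:
            off2 = int(rng.integers(1, n_list))  # fresh rotation for the retry
            idx = circular_shift_regions(obs_idx, n_list, off2)
            grp_idx = group_indices(idx)
            sizes = sorted((len(g) for g in grp_idx), reverse=True)
            tries += 1
        if sizes != target_sizes:
            used = {m for g in grp_idx for m in g}
            grp_idx = _repair_grouping(grp_idx, target_sizes, n_list, used, rng)
            result.n_repaired += 1
        result.group_sizes.append(sorted((len(g) for g in grp_idx), reverse=True))

        if all_singletons:
            node_idx = np.array([g[0] for g in grp_idx], dtype=int)
        else:
            grps = [
                RegionGroup(
                    group_id=f"p{k}", chrom="", members=[ordered_ids[i] for i in g],
                    representative=ordered_ids[g[0]], span=(0, 0),
                )
                for k, g in enumerate(grp_idx)
            ]
            reps = _quick_representatives(network, grps)
            node_idx = network.indices_of(reps)
        W = network.weight_matrix(node_idx)
        s = subset_scores(W)
        scores = iterative_scores(W, s) if use_iterative else s
        result.offsets.append(int(off))
        result.subset_sizes.append(n_nodes)
        result.scores.append(scores)
    if result.n_repaired:
        log.info("post-mapping null: %d/%d permutations needed grouping repair", result.n_repaired, n_perms)
    return result


def pre_mapping_null(
    network: CoexpressionNetwork,
    snps_k: Sequence[SnpRecord],
    catalog_regions: Sequence[RegulatoryRegion],
    genome: Sequence[tuple[str, int]],
    n_perms: int,
    rng: np.random.Generator,
    distance: int = 100_000,
    p_cut: float = 0.1,
    use_iterative: bool = True,
) -> PermutationSet:
    """Scores of subsets obtained by rotating the SNP set K and re-mapping."""
    total = sum(l for _, l in genome)
    if n_perms > total - 1:
        raise ValueError("more permutations than available offsets")
    offsets = rng.choice(np.arange(1, total, dtype=np.int64), size=n_perms, replace=False)
    node_ids = set(network.region_ids)
    result = PermutationSet(mode="pre_mapping", n_perms=n_perms)
    for off in offsets:
        shifted = circular_shift_snps(snps_k, genome, int(off))
        mapping = map_snps_to_regions(shifted, catalog_regions)
        regs = [r for r in mapping.regions if r.id in node_ids]
        result.offsets.append(int(off))
        if len(regs) < 2:
            result.subset_sizes.append(len(regs))
            result.scores.append(np.zeros(len(regs)))
            continue
        grps = build_groups(regs, network, distance=distance, p_cut=p_cut)
        reps = _quick_representatives(network, grps)
        node_idx = network.indices_of(reps)
        W = network.weight_matrix(node_idx)
        s = subset_scores(W)
        result.subset_sizes.append(len(grps))
        result.scores.append(iterative_scores(W, s) if use_iterative else s)
    return result


def empirical_significance(
    node_ids: Sequence[str],
    observed_scores: Sequence[float],
    permuted_scores: np.ndarray,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Empirical p per node against the pooled permuted-score distribution.

    raw_p = (1 + #{permuted >= observed}) / (1 + n_permuted); BH step-up FDR
    across the tested nodes.
    """
    pool = np.sort(np.asarray(permuted_scores, dtype=float))
    n_pool = len(pool)
    if n_pool < 100:
        log.warning("only %d permuted scores: empirical p floor is coarse", n_pool)
    obs = np.asarray(observed_scores, dtype=float)
    n_ge = n_pool - np.searchsorted(pool, obs, side="left")
    raw_p = (1.0 + n_ge) / (1.0 + n_pool)
    fdr = multipletests(raw_p, method="fdr_bh")[1] if len(raw_p) else np.empty(0)
    return pd.DataFrame(
        {
            "node": list(node_ids),
            "s_iterative": obs,
            "raw_p": raw_p,
            "fdr": fdr,
            "significant": fdr < fdr_threshold,
        }
    )


def ks_compare(observed_scores, permuted_scores) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of observed vs permuted scores."""
    obs = np.asarray(observed_scores, dtype=float)
    perm = np.asarray(permuted_scores, dtype=float)
    if len(obs) == 0 or len(perm) == 0:
        raise ValueError("both score samples must be non-empty")
    if np.ptp(obs) == 0 and np.ptp(perm) == 0:
        log.warning("degenerate (constant) samples: KS p approximate")
    res = ks_2samp(obs, perm, method="asymp")
    return float(res.statistic), float(res.pvalue)
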