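"""Collapsing nearby, correlated regulatory regions into single network nodes.

SNPs from a GWAS travel in linkage blocks, and neighbouring regulatory
regions often share local regulatory influences (chromatin state, shared
enhancers).  Both effects can fake coexpression.  Two trait-associated
regions are therefore merged when their genomic gap is at most 100 kb *and*
their correlation p-value (either direction) is below 0.1; merging is closed
transitively (single linkage), and each group is represented by the member
with the largest NDA score against all the other groups.  The number of
groups, n_res, is the count of independent units entering the analysis.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .atlas import CoexpressionNetwork
from .nda_core import subset_scores
from .regions import RegulatoryRegion


@dataclass
class RegionGroup:
    group_id: str
    chrom: str
    members: list[str]  # region ids, genomic order
    representative: str
    span: tuple[int, int]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _gap(a: RegulatoryRegion, b: RegulatoryRegion) -> int:
    """Inner gap in bp between two intervals on the same chromosome (0 if touching/overlapping)."""
    if b.start > a.end:
        return b.start - a.end - 1
    if a.start > b.end:
        return a.start - b.end - 1
    return 0


def build_groups(
    regions: Sequence[RegulatoryRegion],
    network: CoexpressionNetwork,
    distance: int = 100_000,
    p_cut: float = 0.1,
) -> list[RegionGroup]:
    """Partition the trait-associated regions into independent groups.

    Regions on the same chromosome merge iff gap <= *distance* and
    min(p(i->j), p(j->i)) < *p_cut*; chained merges close transitively.
    Representatives start as the earliest member and are refined by
    :func:`choose_representatives`.
    """
    regs = sorted(regions, key=lambda r: (r.chrom, r.start, r.id))
    n = len(regs)
    if n == 0:
        return []
    idx = network.indices_of([r.id for r in regs])
    P = network.pvalue_matrix(idx)
    uf = _UnionFind(n)
    for a in range(n):
        for b in range(a + 1, n):
            if regs[b].chrom != regs[a].chrom:
                break
            if regs[b].start - regs[a].end - 1 > distance and regs[b].start > regs[a].end:
                break  # regions sorted by start: all later b are farther
            if _gap(regs[a], regs[b]) <= distance and min(P[a, b], P[b, a]) < p_cut:
                uf.union(a, b)

    clusters: dict[int, list[int]] = {}
    for a in range(n):
        clusters.setdefault(uf.find(a), []).append(a)

    groups = []
    for root in sorted(clusters):
        members = clusters[root]
        regs_m = [regs[a] for a in members]
        span = (min(r.start for r in regs_m), max(r.end for r in regs_m))
        groups.append(
            RegionGroup(
                group_id=f"grp{len(groups):04d}",
                chrom=regs_m[0].chrom,
                members=[r.id for r in regs_m],
                representative=regs_m[0].id,  # refined later
                span=span,
            )
        )
    return groups


def choose_representatives(
    groups: Sequence[RegionGroup],
    network: CoexpressionNetwork,
    regions_by_id: Optional[dict[str, RegulatoryRegion]] = None,
    rounds: int = 2,
) -> list[RegionGroup]:
    """Pick each group's representative: the member with the largest NDA score
    against the other groups.

    The definition is circular (scores need representatives, representatives
    need scores), so a fixed point is approached iteratively: round 0 scores
    members against the union of all other groups' members, later rounds
    against the current representatives; capped at *rounds* refinements.  Ties
    break to the smaller start coordinate, then the lexicographically smaller
    id.
    """
    groups = [RegionGroup(**vars(g)) for g in groups]
    if not groups:
        return []

    def member_key(rid: str) -> tuple:
        if regions_by_id and rid in regions_by_id:
            return (regions_by_id[rid].start, rid)
        return (0, rid)

    # round 0: against all members of other groups
    def refine(opponents_of) -> bool:
        changed = False
        for g in groups:
            if len(g.members) == 1:
                if g.representative != g.members[0]:
                    g.representative = g.members[0]
                    changed = True
                continue
            opponents = opponents_of(g)
            best, best_score = None, -np.inf
            for m in sorted(g.members, key=member_key):
                if not opponents:
                    score = 0.0
                else:
                    ids = [m] + opponents
                    W = network.weight_matrix(network.indices_of(ids))
                    score = float(subset_scores(W)[0])
                if score > best_score + 1e-12:
                    best, best_score = m, score
            if g.representative != best:
                g.representative = best
                changed = True
        return changed

    refine(lambda g: [m for h in groups if h is not g for m in h.members])
    for _ in range(rounds - 1):
        if not refine(lambda g: [h.representative for h in groups if h is not g]):
            break
    return groups


def check_ld_independence(
    groups: Sequence[RegionGroup],
    snps_by_region: dict[str, list],
    ld_table: Optional[pd.DataFrame] = None,
    r2_threshold: float = 0.8,
) -> pd.DataFrame:
    """Diagnostic report of LD between representatives of distinct groups.

    *ld_table* is a user-supplied pairwise table with columns snp_a, snp_b,
    r2.  Pairs of SNPs from different groups' representative regions with
    r² >= *r2_threshold* are reported; this never filters the analysis.
    """
    cols = ["group_a", "group_b", "snp_a", "snp_b", "r2"]
    if ld_table is None or ld_table.empty:
        return pd.DataFrame(columns=cols)
    snp_group: dict[str, str] = {}
    for g in groups:
        for hit in snps_by_region.get(g.representative, []):
            snp_group[hit.snp.snp_id] = g.group_id
    rows = []
    for rec in ld_table.itertuples(index=False):
        ga, gb = snp_group.get(str(rec.snp_a)), snp_group.get(str(rec.snp_b))
        if ga is None or gb is None or ga == gb:
            continue
        if float(rec.r2) >= r2_threshold:
            rows.append((min(ga, gb), max(ga, gb), str(rec.snp_a), str(rec.snp_b), float(rec.r2)))
    return pd.DataFrame(rows, columns=cols).drop_duplicates().reset_index(drop=True)
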