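"""SNP selection and mapping into regulatory regions.

A GWAS summary table is filtered to the "putatively significant" SNP set K
(association p below a permissive threshold, 5e-6 by default).  Members of K
are then intersected with promoter windows (-300/+100 bp around a TSS, in
transcription direction) and enhancer spans (the extent of bidirectional eRNA
transcription).  Regions containing at least one K-SNP form the
trait-associated set R = P ∪ E, the node subset scored by network density
analysis.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

log = logging.getLogger(__name__)

PROMOTER_UPSTREAM = 300
PROMOTER_DOWNSTREAM = 100


@dataclass(frozen=True)
class RegulatoryRegion:
    """A promoter window or enhancer span; coordinates 1-based inclusive."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "."  # '+', '-', or '.' (unstranded)
    kind: str = "promoter"  # 'promoter' | 'enhancer'
    annotation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.kind not in ("promoter", "enhancer"):
            raise ValueError(f"unknown region kind {self.kind!r}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class SnpRecord:
    snp_id: str
    chrom: str
    pos: int
    pvalue: float


@dataclass(frozen=True)
class SnpHit:
    """One SNP falling inside one regulatory region."""

    snp: SnpRecord
    region_id: str
    offset: int  # bp from region start


@dataclass
class MappingResult:
    """The trait-associated region set R with its supporting SNP evidence."""

    regions: list[RegulatoryRegion]  # genomic order
    hits: dict[str, list[SnpHit]] = field(default_factory=dict)

    @property
    def region_ids(self) -> list[str]:
        return [r.id for r in self.regions]

    def best_pvalue(self, region_id: str) -> float:
        return min(h.snp.pvalue for h in self.hits[region_id])

    def n_hits(self) -> int:
        return sum(len(v) for v in self.hits.values())


def filter_putative_snps(records: Iterable[SnpRecord], threshold: float = 5e-6) -> list[SnpRecord]:
    """Select the input SNP set K: associations with p strictly below *threshold*."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return [r for r in records if r.pvalue < threshold]


def promoter_window(
    tss_pos: int, strand: str, chrom_length: Optional[int] = None
) -> tuple[int, int]:
    """Window -300 bp upstream to +100 bp downstream of a TSS, in transcription direction.

    Unstranded TSS are treated as '+'.  The window is clipped to [1, chrom_length].
    """
    if tss_pos < 1:
        raise ValueError("tss_pos must be >= 1")
    if strand == "-":
        start, end = tss_pos - PROMOTER_DOWNSTREAM, tss_pos + PROMOTER_UPSTREAM
    else:
        start, end = tss_pos - PROMOTER_UPSTREAM, tss_pos + PROMOTER_DOWNSTREAM
    start = max(1, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return start, end


def map_snps_to_regions(
    snps: Sequence[SnpRecord], regions: Sequence[RegulatoryRegion]
) -> MappingResult:
    """Intersect SNP set K with regulatory regions, yielding R and per-region hits.

    A SNP inside two overlapping regions hits both.  The returned region list
    follows genomic order (chromosome as ordered in the catalog, then start).
    """
    trees: dict[str, IntervalTree] = {}
    by_id = {r.id: r for r in regions}
    for r in regions:
        # interval tree is half-open; store [start, end+1)
        trees.setdefault(r.chrom, IntervalTree())[r.start : r.end + 1] = r.id

    hits: dict[str, list[SnpHit]] = {}
    for snp in snps:
        tree = trees.get(snp.chrom)
        if tree is None:
            continue
        for iv in tree[snp.pos]:
            rid = iv.data
            region = by_id[rid]
            hits.setdefault(rid, []).append(
                SnpHit(snp=snp, region_id=rid, offset=snp.pos - region.start)
            )

    chrom_order = {c: i for i, c in enumerate(dict.fromkeys(r.chrom for r in regions))}
    hit_regions = sorted(
        (by_id[rid] for rid in hits),
        key=lambda r: (chrom_order[r.chrom], r.start, r.id),
    )
    log.info("mapped %d/%d SNPs into %d regions", sum(len(v) for v in hits.values()), len(snps), len(hit_regions))
    return MappingResult(regions=hit_regions, hits=hits)


def _union_length(regions: Sequence[RegulatoryRegion]) -> int:
    """Total bp covered by the regions, counting overlaps once."""
    total = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for spans in by_chrom.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        total += cur_e - cur_s + 1
    return total


def enrichment_per_mb(
    snps: Sequence[SnpRecord],
    mapping: MappingResult,
    regions: Sequence[RegulatoryRegion],
    genome: Sequence[tuple[str, int]],
) -> float:
    """Fold enrichment of K-SNPs in regulatory sequence.

    (distinct SNPs hitting regions / Mb of region sequence) divided by
    (|K| / Mb of genome).  Overlapping regions are counted once.
    """
    if not regions:
        raise ValueError("no regions: zero total region length")
    region_bp = _union_length(regions)
    genome_bp = sum(length for _, length in genome)
    if region_bp == 0 or genome_bp == 0:
        raise ValueError("zero region or genome length")
    hit_snps = {h.snp.snp_id for hs in mapping.hits.values() for h in hs}
    if not snps:
        return 0.0
    observed = len(hit_snps) / (region_bp / 1e6)
    expected = len(snps) / (genome_bp / 1e6)
    return observed / expected
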