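"""External file formats and run configuration.

Readers for GWAS summary tables (delimited text, configurable columns),
BED6 region catalogs (promoter TSS and enhancer spans), and expression
matrices with sample metadata.  Writers for the result tables and the JSON
run manifest.  Internal coordinates are 1-based inclusive throughout; BED
input/output converts explicitly from/to 0-based half-open.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .regions import RegulatoryRegion, SnpRecord, promoter_window

log = logging.getLogger(__name__)

DEFAULT_GWAS_COLUMNS = {"snp_id": "snp_id", "chrom": "chrom", "pos": "pos", "pvalue": "pvalue"}


@dataclass
class GwasTable:
    """Full per-SNP output of a GWAS: the background for circular permutations."""

    records: list[SnpRecord]
    provenance: str = ""
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [r.snp_id for r in self.records],
                "chrom": [r.chrom for r in self.records],
                "pos": [r.pos for r in self.records],
                "pvalue": [r.pvalue for r in self.records],
            }
        )


@dataclass
class RegionCatalog:
    """All regulatory regions of the atlas plus the genome they live on."""

    entries: list[RegulatoryRegion]
    genome: list[tuple[str, int]]  # ordered (chrom, length)

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate region ids in catalog")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    def by_id(self) -> dict[str, RegulatoryRegion]:
        return {e.id: e for e in self.entries}

    def ordered(self) -> list[RegulatoryRegion]:
        """Entries in genomic order (genome chromosome order, then start)."""
        order = {c: i for i, (c, _) in enumerate(self.genome)}
        return sorted(self.entries, key=lambda r: (order.get(r.chrom, len(order)), r.start, r.id))

    def merged_with(self, other: "RegionCatalog") -> "RegionCatalog":
        genome = list(self.genome)
        known = {c for c, _ in genome}
        genome.extend((c, l) for c, l in other.genome if c not in known)
        return RegionCatalog(entries=self.entries + other.entries, genome=genome)


@dataclass
class RunConfig:
    """All tunable thresholds of a run; defaults follow the published method."""

    gwas_p_threshold: float = 5e-6
    grouping_distance: int = 100_000
    grouping_link_p: float = 0.1
    n_score_permutations: int = 10_000
    n_celltype_permutations: int = 10_000  # method default 100,000; reduced for desk scale
    fdr_threshold: float = 0.05
    rng_seed: int = 0
    permutation_mode: str = "post_mapping"  # pre_mapping | post_mapping | both
    min_background_nodes: int = 50
    expression_threshold: float = 0.0  # a region is expressed if any sample exceeds this

    def __post_init__(self) -> None:
        if not 0 < self.gwas_p_threshold < 1:
            raise ValueError("gwas_p_threshold must be in (0,1)")
        if not 0 < self.grouping_link_p <= 1:
            raise ValueError("grouping_link_p must be in (0,1]")
        if self.grouping_distance < 0 or self.n_score_permutations < 1:
            raise ValueError("invalid grouping_distance or n_score_permutations")
        if self.permutation_mode not in ("pre_mapping", "post_mapping", "both"):
            raise ValueError(f"unknown permutation_mode {self.permutation_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def read_gwas(
    path: str | Path,
    column_map: Optional[dict[str, str]] = None,
    provenance: str = "",
    sep: str = "\t",
) -> GwasTable:
    """Read a delimited GWAS summary table with a header line.

    *column_map* maps the internal names snp_id/chrom/pos/pvalue to the file's
    column names.  Rows with unparseable position or p-value (or p outside
    (0, 1]) are skipped with a warning; duplicate SNP ids keep the record with
    the smallest p-value.  A missing mapped column is a hard error.
    """
    cmap = dict(DEFAULT_GWAS_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [v for v in cmap.values() if v not in df.columns]
    if missing:
        raise ValueError(f"GWAS file {path} lacks mapped columns: {missing}")

    pos = pd.to_numeric(df[cmap["pos"]], errors="coerce")
    pval = pd.to_numeric(df[cmap["pvalue"]], errors="coerce")
    ok = pos.notna() & pval.notna() & (pos >= 1) & (pval > 0) & (pval <= 1)
    n_skipped = int((~ok).sum())
    if n_skipped:
        log.warning("read_gwas: skipped %d malformed rows in %s", n_skipped, path)
    sub = pd.DataFrame(
        {
            "snp_id": df.loc[ok, cmap["snp_id"]].astype(str),
            "chrom": df.loc[ok, cmap["chrom"]].astype(str),
            "pos": pos[ok].astype(int),
            "pvalue": pval[ok].astype(float),
        }
    )
    # duplicate ids: keep the smallest p (deterministic, conservative)
    sub = sub.sort_values(["snp_id", "pvalue"], kind="mergesort").drop_duplicates("snp_id", keep="first")
    sub = sub.sort_values(["chrom", "pos", "snp_id"], kind="mergesort")
    records = [
        SnpRecord(snp_id=r.snp_id, chrom=r.chrom, pos=int(r.pos), pvalue=float(r.pvalue))
        for r in sub.itertuples(index=False)
    ]
    return GwasTable(records=records, provenance=provenance or str(path), n_skipped=n_skipped)


def read_genome_table(path: str | Path) -> list[tuple[str, int]]:
    """Two-column chrom/length table (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], dtype={0: str, 1: int})
    return [(str(r.chrom), int(r.length)) for r in df.itertuples(index=False)]


def read_region_catalog(
    path_bed: str | Path,
    kind: str,
    genome: Sequence[tuple[str, int]],
) -> RegionCatalog:
    """Read a BED6 file into a catalog of 1-based inclusive regions.

    Promoter entries are TSS anchors: a BED record of width 1 anchors the TSS
    at its (1-based) end coordinate and is expanded to the -300/+100 window in
    transcription direction; wider promoter records are expanded around their
    5' end.  Enhancer entries are kept as their literal span.  Records with
    start >= end or an unknown chromosome are rejected with a warning.
    """
    if kind not in ("promoter", "enhancer"):
        raise ValueError(f"kind must be promoter or enhancer, got {kind!r}")
    lengths = dict(genome)
    entries: list[RegulatoryRegion] = []
    n_rejected = 0
    with open(path_bed) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                n_rejected += 1
                continue
            chrom, s0, e0 = parts[0], parts[1], parts[2]
            name = parts[3] if len(parts) > 3 else f"{chrom}:{s0}-{e0}"
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
            annotation = parts[6] if len(parts) > 6 else None
            try:
                start0, end0 = int(s0), int(e0)
            except ValueError:
                n_rejected += 1
                continue
            if start0 >= end0 or chrom not in lengths:
                n_rejected += 1
                continue
            start, end = start0 + 1, end0  # BED half-open -> 1-based inclusive
            if kind == "promoter":
                tss = end if strand != "-" else start
                start, end = promoter_window(tss, strand, chrom_length=lengths[chrom])
            else:
                end = min(end, lengths[chrom])
            entries.append(
                RegulatoryRegion(
                    id=name, chrom=chrom, start=start, end=end,
                    strand=strand, kind=kind, annotation=annotation,
                )
            )
    if n_rejected:
        log.warning("read_region_catalog: rejected %d records in %s", n_rejected, path_bed)
    return RegionCatalog(entries=entries, genome=list(genome))


def write_region_bed(catalog: RegionCatalog, path: str | Path) -> None:
    """Write catalog entries as BED6 (converting back to 0-based half-open)."""
    with open(path, "w") as fh:
        for r in catalog.ordered():
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.id}\t0\t{r.strand if r.strand != '.' else '.'}\n")


def read_expression_matrix(
    path: str | Path,
    sample_metadata_path: str | Path,
    catalog: Optional[RegionCatalog] = None,
):
    """Load a regions × samples expression matrix plus sample metadata.

    Technical replicates (shared ``group_id``) are averaged (arithmetic mean
    of raw values) and samples flagged ``exclude`` are dropped before any
    correlation is computed.  Rows absent from the catalog are dropped with a
    warning; duplicate region rows are a hard error; zero overlap with the
    catalog is a hard error.  Returns an :class:`~ndanet.atlas.ExpressionAtlas`
    with all-zero rows flagged non-expressed and removed from the network.
    """
    from .atlas import ExpressionAtlas

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate region rows in expression matrix: {dups[:5]}")
    meta = pd.read_csv(sample_metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "group_id", "cell_type"}
    if not required <= set(meta.columns):
        raise ValueError(f"sample metadata must have columns {sorted(required)}")
    if "exclude" in meta.columns:
        excl = meta["exclude"].fillna("0").isin(("1", "true", "True", "yes"))
        meta = meta[~excl]
    meta = meta[meta["sample_id"].isin(df.columns)]
    if meta.empty:
        raise ValueError("no usable samples after metadata filtering")

    # average technical replicates per group
    groups = meta.groupby("group_id", sort=True)
    cols, sample_ids, cell_types = [], [], []
    for gid, sub in groups:
        cols.append(df[sub["sample_id"].tolist()].mean(axis=1))
        sample_ids.append(str(gid))
        cell_types.append(str(sub["cell_type"].iloc[0]))
    mat = pd.concat(cols, axis=1)
    mat.columns = sample_ids

    if catalog is not None:
        known = set(catalog.ids)
        keep = mat.index.isin(known)
        n_drop = int((~keep).sum())
        if n_drop == len(mat):
            raise ValueError("expression matrix shares no region ids with the catalog")
        if n_drop:
            log.warning("read_expression_matrix: dropped %d rows absent from catalog", n_drop)
        mat = mat.loc[keep]
    values = mat.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression matrix contains negative values")
    return ExpressionAtlas(
        matrix=values,
        region_ids=list(mat.index.astype(str)),
        sample_ids=sample_ids,
        cell_types=cell_types,
    )


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


NDA_COLUMNS = [
    "group_id", "representative_region", "members", "n_snps", "best_gwas_p",
    "score_s", "score_s_iterative", "ccs", "raw_p", "fdr",
]
CELLTYPE_COLUMNS = ["cell_type", "rra_rho", "rra_p", "empirical_p", "fdr", "n_regions_used"]


def write_results(
    nda_results: pd.DataFrame,
    celltype_results: Optional[pd.DataFrame],
    out_dir: str | Path,
    config: Optional[RunConfig] = None,
    input_hashes: Optional[dict[str, str]] = None,
    extra_manifest: Optional[dict] = None,
) -> dict[str, Path]:
    """Write result tables in deterministic order plus a JSON run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    nda = nda_results.reindex(columns=NDA_COLUMNS)
    nda = nda.sort_values(
        ["fdr", "score_s_iterative", "group_id"], ascending=[True, False, True], kind="mergesort"
    )
    p = out / "nda_results.tsv"
    nda.to_csv(p, sep="\t", index=False, float_format="%.6g")
    paths["nda_results"] = p

    if celltype_results is not None:
        ct = celltype_results.reindex(columns=CELLTYPE_COLUMNS)
        ct = ct.sort_values(["fdr", "empirical_p", "cell_type"], kind="mergesort")
        p = out / "celltype_results.tsv"
        ct.to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths["celltype_results"] = p

    manifest = {
        "config": config.to_dict() if config else None,
        "seed": config.rng_seed if config else None,
        "input_hashes": input_hashes or {},
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    p = out / "manifest.json"
    with open(p, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = p
    return paths
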