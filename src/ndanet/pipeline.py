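"""End-to-end orchestration: map -> correlate -> group -> score -> permute -> FDR -> cell types.

Stages communicate through files in the output directory so a run can be
inspected and resumed: the JSON manifest records the configuration, the seed
and content hashes of all inputs, and a rerun with identical inputs and
configuration reuses the existing outputs (recomputing whenever a recorded
output hash no longer matches the file on disk).
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .atlas import CoexpressionNetwork, ExpressionAtlas
from .celltype import celltype_empirical
from .grouping import build_groups, choose_representatives, check_ld_independence
from .io_formats import (
    GwasTable,
    RegionCatalog,
    RunConfig,
    file_sha256,
    read_expression_matrix,
    read_genome_table,
    read_gwas,
    read_region_catalog,
    write_results,
)
from .nda_core import corrected_score, iterative_scores, subset_scores
from .nullmodels import (
    empirical_significance,
    ks_compare,
    post_mapping_null,
    pre_mapping_null,
)
from .regions import enrichment_per_mb, filter_putative_snps, map_snps_to_regions

log = logging.getLogger(__name__)


@dataclass
class RunResult:
    config: RunConfig
    n_snps_k: int
    n_mapped_regions: int
    n_groups: int
    enrichment: float
    nda_table: pd.DataFrame
    celltype_table: Optional[pd.DataFrame]
    ks_statistic: float
    ks_pvalue: float
    qq: pd.DataFrame
    paths: dict = field(default_factory=dict)
    counters: dict = field(default_factory=dict)


def qq_table(observed_scores, permuted_scores) -> pd.DataFrame:
    """Matched quantiles of observed vs permuted-expected scores (for Q-Q plots)."""
    obs = np.sort(np.asarray(observed_scores, dtype=float))
    perm = np.asarray(permuted_scores, dtype=float)
    if len(obs) == 0 or len(perm) == 0:
        raise ValueError("both score sets must be non-empty")
    q = (np.arange(1, len(obs) + 1) - 0.5) / len(obs)
    # inverted-CDF quantiles: identical samples land exactly on the diagonal
    expected = np.quantile(perm, q, method="inverted_cdf")
    return pd.DataFrame({"quantile": q, "expected": expected, "observed": obs})


def run_from_objects(
    config: RunConfig,
    gwas: GwasTable,
    catalog: RegionCatalog,
    atlas: ExpressionAtlas,
    ld_table: Optional[pd.DataFrame] = None,
    out_dir: Optional[str | Path] = None,
    input_hashes: Optional[dict[str, str]] = None,
) -> RunResult:
    """Run the full analysis on in-memory inputs."""
    rng = np.random.default_rng(config.rng_seed)
    t0 = time.time()
    counters: dict = {"snps_read": len(gwas.records)}

    # --- SNP selection and mapping
    K = filter_putative_snps(gwas.records, config.gwas_p_threshold)
    counters["snps_putative"] = len(K)
    mapping = map_snps_to_regions(K, catalog.entries)
    counters["regions_with_snp"] = len(mapping.regions)
    counters["snp_hits"] = mapping.n_hits()
    if len(mapping.regions) == 0:
        raise RuntimeError("stage mapping: no putatively-significant SNP falls in any region")
    enrichment = enrichment_per_mb(K, mapping, catalog.entries, catalog.genome)

    # --- coexpression network over the whole expressed atlas
    network = CoexpressionNetwork(
        atlas,
        min_background=config.min_background_nodes,
        expression_threshold=config.expression_threshold,
    )
    counters["network_nodes"] = network.n_nodes

    node_ids = set(network.region_ids)
    regions_r = [r for r in mapping.regions if r.id in node_ids]
    counters["regions_expressed"] = len(regions_r)
    if len(regions_r) < 2:
        raise RuntimeError("stage network: fewer than 2 expressed trait-associated regions")

    # --- grouping
    groups = build_groups(
        regions_r, network, distance=config.grouping_distance, p_cut=config.grouping_link_p
    )
    by_id = {r.id: r for r in regions_r}
    groups = choose_representatives(groups, network, regions_by_id=by_id)
    n_res = len(groups)
    counters["groups"] = n_res
    ld_report = check_ld_independence(groups, mapping.hits, ld_table)

    # --- observed scores on representatives
    reps = [g.representative for g in groups]
    rep_idx = network.indices_of(reps)
    W = network.weight_matrix(rep_idx)
    s = subset_scores(W)
    s_it = iterative_scores(W, s)
    ccs = corrected_score(s_it, n_res)

    # --- permutation null
    ordered_ids = [r.id for r in _ordered_network_regions(catalog, network)]
    use_pre = config.permutation_mode in ("pre_mapping", "both")
    use_post = config.permutation_mode in ("post_mapping", "both")
    pools = []
    if use_post:
        null_post = post_mapping_null(
            network, ordered_ids, groups, config.n_score_permutations, rng,
            distance=config.grouping_distance, p_cut=config.grouping_link_p,
            regions_by_id={r.id: r for r in catalog.entries},
        )
        pools.append(("post_mapping", null_post))
    if use_pre:
        null_pre = pre_mapping_null(
            network, K, catalog.entries, catalog.genome,
            config.n_score_permutations, rng,
            distance=config.grouping_distance, p_cut=config.grouping_link_p,
        )
        pools.append(("pre_mapping", null_pre))
    primary_pool = pools[0][1].pooled()
    counters["permutations"] = sum(p.n_perms for _, p in pools)

    sig = empirical_significance(reps, s_it, primary_pool, config.fdr_threshold)
    ks_stat, ks_p = ks_compare(s_it, primary_pool)
    qq = qq_table(s_it, primary_pool)

    nda_table = pd.DataFrame(
        {
            "group_id": [g.group_id for g in groups],
            "representative_region": reps,
            "members": [",".join(g.members) for g in groups],
            "n_snps": [sum(len(mapping.hits.get(m, [])) for m in g.members) for g in groups],
            "best_gwas_p": [
                min(min((h.snp.pvalue for h in mapping.hits.get(m, [])), default=1.0) for m in g.members)
                for g in groups
            ],
            "score_s": s,
            "score_s_iterative": s_it,
            "ccs": ccs,
            "raw_p": sig["raw_p"].to_numpy(),
            "fdr": sig["fdr"].to_numpy(),
        }
    )
    counters["significant_groups"] = int((nda_table["fdr"] < config.fdr_threshold).sum())

    # --- cell-type specificity on the significant set
    significant_regions = nda_table.loc[
        nda_table["fdr"] < config.fdr_threshold, "representative_region"
    ].tolist()
    celltype_table = None
    if len(significant_regions) >= 2:
        celltype_table = celltype_empirical(
            significant_regions, network.atlas,
            n_perms=config.n_celltype_permutations, rng=rng,
            fdr_threshold=config.fdr_threshold,
        )
    else:
        log.info("fewer than 2 significant regions: cell-type stage skipped")

    counters["elapsed_s"] = round(time.time() - t0, 2)
    for k, v in counters.items():
        log.info("pipeline %s = %s", k, v)

    result = RunResult(
        config=config,
        n_snps_k=len(K),
        n_mapped_regions=len(mapping.regions),
        n_groups=n_res,
        enrichment=enrichment,
        nda_table=nda_table,
        celltype_table=celltype_table,
        ks_statistic=ks_stat,
        ks_pvalue=ks_p,
        qq=qq,
        counters=counters,
    )
    if out_dir is not None:
        paths = write_results(
            nda_table, celltype_table, out_dir, config=config,
            input_hashes=input_hashes or {},
            extra_manifest={
                "counters": counters,
                "enrichment": enrichment,
                "ks": {"statistic": ks_stat, "pvalue": ks_p},
            },
        )
        qq.to_csv(Path(out_dir) / "qq.tsv", sep="\t", index=False, float_format="%.6g")
        if not ld_report.empty:
            ld_report.to_csv(Path(out_dir) / "ld_report.tsv", sep="\t", index=False)
        _write_groups(groups, Path(out_dir) / "groups.tsv")
        _record_output_hashes(Path(out_dir))
        result.paths = {k: str(v) for k, v in paths.items()}
    return result


def _ordered_network_regions(catalog: RegionCatalog, network: CoexpressionNetwork):
    node_ids = set(network.region_ids)
    return [r for r in catalog.ordered() if r.id in node_ids]


def _write_groups(groups, path: Path) -> None:
    pd.DataFrame(
        {
            "group_id": [g.group_id for g in groups],
            "chrom": [g.chrom for g in groups],
            "span_start": [g.span[0] for g in groups],
            "span_end": [g.span[1] for g in groups],
            "representative": [g.representative for g in groups],
            "members": [",".join(g.members) for g in groups],
        }
    ).to_csv(path, sep="\t", index=False)


def _record_output_hashes(out_dir: Path) -> None:
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    manifest["output_hashes"] = {
        p.name: file_sha256(p)
        for p in sorted(out_dir.iterdir())
        if p.suffix in (".tsv",) and p.is_file()
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _resume_ok(out_dir: Path, config: RunConfig, input_hashes: dict[str, str]) -> bool:
    manifest_path = out_dir / "manifest.json"
    if not manifest_path.exists():
        return False
    try:
        with open(manifest_path) as fh:
            manifest = json.load(fh)
    except json.JSONDecodeError:
        return False
    if manifest.get("config") != config.to_dict() or manifest.get("input_hashes") != input_hashes:
        return False
    for name, digest in manifest.get("output_hashes", {}).items():
        p = out_dir / name
        if not p.exists() or file_sha256(p) != digest:
            log.info("resume: output %s missing or corrupted; recomputing", name)
            return False
    return "output_hashes" in manifest and (out_dir / "nda_results.tsv").exists()


def run_all(
    config: RunConfig,
    gwas_path: str | Path,
    promoters_path: Optional[str | Path],
    enhancers_path: Optional[str | Path],
    expression_path: str | Path,
    samples_path: str | Path,
    genome_path: str | Path,
    out_dir: str | Path,
    gwas_columns: Optional[dict[str, str]] = None,
    ld_path: Optional[str | Path] = None,
) -> RunResult:
    """File-based entry point with resumability.

    If the output directory already holds a manifest whose configuration,
    input hashes and output hashes all match, the stored results are reloaded
    instead of recomputed.
    """
    out = Path(out_dir)
    inputs = {
        "gwas": gwas_path, "promoters": promoters_path, "enhancers": enhancers_path,
        "expression": expression_path, "samples": samples_path, "genome": genome_path,
    }
    input_hashes = {k: file_sha256(v) for k, v in inputs.items() if v is not None}

    if _resume_ok(out, config, input_hashes):
        log.info("resume: all stages up to date in %s; skipping recomputation", out)
        nda_table = pd.read_csv(out / "nda_results.tsv", sep="\t")
        ct_path = out / "celltype_results.tsv"
        celltype_table = pd.read_csv(ct_path, sep="\t") if ct_path.exists() else None
        with open(out / "manifest.json") as fh:
            manifest = json.load(fh)
        qq = pd.read_csv(out / "qq.tsv", sep="\t")
        return RunResult(
            config=config,
            n_snps_k=manifest["counters"]["snps_putative"],
            n_mapped_regions=manifest["counters"]["regions_with_snp"],
            n_groups=manifest["counters"]["groups"],
            enrichment=manifest["enrichment"],
            nda_table=nda_table,
            celltype_table=celltype_table,
            ks_statistic=manifest["ks"]["statistic"],
            ks_pvalue=manifest["ks"]["pvalue"],
            qq=qq,
            counters=manifest["counters"],
            paths={"out_dir": str(out)},
        )

    genome = read_genome_table(genome_path)
    gwas = read_gwas(gwas_path, column_map=gwas_columns)
    catalogs = []
    if promoters_path is not None:
        catalogs.append(read_region_catalog(promoters_path, "promoter", genome))
    if enhancers_path is not None:
        catalogs.append(read_region_catalog(enhancers_path, "enhancer", genome))
    if not catalogs:
        raise ValueError("at least one of promoters/enhancers is required")
    catalog = catalogs[0]
    for extra in catalogs[1:]:
        catalog = catalog.merged_with(extra)
    atlas = read_expression_matrix(expression_path, samples_path, catalog=catalog)
    ld_table = pd.read_csv(ld_path, sep="\t") if ld_path else None
    return run_from_objects(
        config, gwas, catalog, atlas, ld_table=ld_table,
        out_dir=out, input_hashes=input_hashes,
    )
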