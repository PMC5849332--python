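"""Synthetic atlases, catalogs and GWAS tables with planted structure.

The generator emulates the statistical situation the method is built for: an
expression atlas in which most regulatory regions vary independently, a few
planted modules share an activity pattern (tunable pairwise Spearman
correlation, optionally restricted to a subset of cell types), and a GWAS in
which signal SNPs with low p-values fall inside the module regions while
background SNPs are uniform over the genome with uniform p-values.

Module rows are built by a Gaussian latent factor: member i gets
sqrt(a)*z + sqrt(1-a)*eps_i with a = 2*sin(pi*rho_s/6), the Gaussian-copula
loading whose bivariate-normal Spearman correlation equals the target rho_s;
a monotone transform (exp) then makes values non-negative without changing
any rank correlation.  Truth labels are returned so recovery can be scored
without external data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .atlas import ExpressionAtlas
from .io_formats import GwasTable, RegionCatalog, write_region_bed
from .regions import RegulatoryRegion, SnpRecord, promoter_window

DEFAULT_GENOME: list[tuple[str, int]] = [("chr1", 10_000_000), ("chr2", 10_000_000)]


@dataclass
class ModuleSpec:
    size: int
    rho: float  # target pairwise Spearman correlation
    name: str = "module"
    active_celltypes: Optional[list[str]] = None  # None: active in all samples


@dataclass
class SnpBin:
    n: int  # SNPs per region for region placements; total for genome placement
    p_low: float
    p_high: float
    placement: str = "genome"  # genome | module_regions | nonmodule_regions
    log_uniform: bool = True


@dataclass
class SimScenario:
    n_regions: int = 2000
    n_samples: int = 100
    n_celltypes: Optional[int] = None  # None: one cell type per sample
    modules: list[ModuleSpec] = field(default_factory=list)
    snp_bins: Optional[list[SnpBin]] = None  # None: defaults (background + module signal)
    genome: list[tuple[str, int]] = field(default_factory=lambda: list(DEFAULT_GENOME))
    enhancer_fraction: float = 0.2
    min_module_separation: int = 200_000  # keep planted members out of grouping range
    n_background_snps: int = 20_000
    housekeeping_celltype: Optional[str] = None  # globally high-activity cell type
    housekeeping_factor: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for m in self.modules:
            if m.size > self.n_regions:
                raise ValueError("module size exceeds n_regions")
            if not -1.0 <= m.rho <= 1.0:
                raise ValueError(f"infeasible target correlation {m.rho}")

    def default_bins(self) -> list[SnpBin]:
        bins = [SnpBin(n=self.n_background_snps, p_low=0.0, p_high=1.0, placement="genome", log_uniform=False)]
        if self.modules:
            bins.append(SnpBin(n=1, p_low=1e-10, p_high=5e-6, placement="module_regions"))
        return bins

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def copula_loading(rho_s: float) -> float:
    """Latent-normal Pearson loading whose bivariate Spearman equals rho_s."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def simulate_catalog(scenario: SimScenario, rng: Optional[np.random.Generator] = None) -> RegionCatalog:
    """Tile regions over the synthetic genome with jittered spacing.

    Promoters are 401-bp strand-aware TSS windows, enhancers literal spans of
    200-400 bp; jitter keeps spacing irregular so the grouping logic is
    exercised.
    """
    rng = rng or scenario.rng()
    genome = scenario.genome
    total = sum(l for _, l in genome)
    entries: list[RegulatoryRegion] = []
    n_done = 0
    for ci, (chrom, length) in enumerate(genome):
        n_here = round(scenario.n_regions * length / total)
        if ci == len(genome) - 1:
            n_here = scenario.n_regions - n_done
        spacing = length / (n_here + 1)
        for k in range(n_here):
            anchor = int((k + 1) * spacing + rng.uniform(-0.3, 0.3) * spacing)
            anchor = min(max(anchor, 600), length - 600)
            rid = f"reg{len(entries):05d}"
            if rng.random() < scenario.enhancer_fraction:
                width = int(rng.integers(200, 401))
                start = max(1, anchor - width // 2)
                entries.append(
                    RegulatoryRegion(id=rid, chrom=chrom, start=start, end=min(start + width, length),
                                     strand=".", kind="enhancer")
                )
            else:
                strand = "+" if rng.random() < 0.5 else "-"
                s, e = promoter_window(anchor, strand, chrom_length=length)
                entries.append(
                    RegulatoryRegion(id=rid, chrom=chrom, start=s, end=e, strand=strand, kind="promoter")
                )
        n_done += n_here
    return RegionCatalog(entries=entries, genome=list(genome))


def _scattered_members(
    catalog: RegionCatalog, n: int, min_sep: int, rng: np.random.Generator, taken: set[int]
) -> list[int]:
    """Pick n catalog indices pairwise separated by > min_sep bp (and unused)."""
    regs = catalog.entries
    order = rng.permutation(len(regs))
    chosen: list[int] = []
    for i in order:
        if int(i) in taken:
            continue
        ok = all(
            regs[i].chrom != regs[j].chrom or abs(regs[i].start - regs[j].start) > min_sep
            for j in chosen
        )
        if ok:
            chosen.append(int(i))
            if len(chosen) == n:
                break
    if len(chosen) < n:
        raise ValueError("cannot place module members with requested separation")
    return sorted(chosen)


def simulate_atlas(
    scenario: SimScenario,
    catalog: RegionCatalog,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ExpressionAtlas, pd.DataFrame]:
    """Generate the expression atlas plus truth labels for planted modules."""
    rng = rng or scenario.rng()
    n, m = scenario.n_regions, scenario.n_samples
    if len(catalog) != n:
        raise ValueError("catalog size does not match scenario")
    n_ct = scenario.n_celltypes or m
    cell_types = [f"ct{k % n_ct:03d}" for k in range(m)]
    sample_ids = [f"s{k:04d}" for k in range(m)]

    latent = rng.standard_normal((n, m))
    module_of = np.full(n, "", dtype=object)
    taken: set[int] = set()
    for mod in scenario.modules:
        members = _scattered_members(catalog, mod.size, scenario.min_module_separation, rng, taken)
        taken.update(members)
        a = copula_loading(mod.rho)
        z = rng.standard_normal(m)
        eps = rng.standard_normal((mod.size, m))
        latent[members] = np.sqrt(a) * z + np.sqrt(1.0 - a) * eps
        module_of[members] = mod.name
        if mod.active_celltypes is not None:
            inactive = ~np.isin(np.asarray(cell_types), mod.active_celltypes)
            for i in members:
                latent[i, inactive] = -np.inf  # exp -> exactly zero outside active samples

    matrix = np.exp(latent)
    if scenario.housekeeping_celltype is not None:
        cols = np.asarray(cell_types) == scenario.housekeeping_celltype
        matrix[:, cols] *= scenario.housekeeping_factor

    atlas = ExpressionAtlas(
        matrix=matrix, region_ids=catalog.ids, sample_ids=sample_ids, cell_types=cell_types
    )
    truth = pd.DataFrame({"region_id": catalog.ids, "module": module_of.astype(str)})
    return atlas, truth


def simulate_gwas(
    scenario: SimScenario,
    catalog: RegionCatalog,
    truth: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
    bins: Optional[Sequence[SnpBin]] = None,
) -> GwasTable:
    """Place background and signal SNPs according to the scenario's bins."""
    rng = rng or scenario.rng()
    bins = list(bins if bins is not None else (scenario.snp_bins or scenario.default_bins()))
    genome = scenario.genome
    lengths = np.array([l for _, l in genome], dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    chroms = [c for c, _ in genome]
    total = int(lengths.sum())
    is_module = truth["module"].to_numpy() != ""
    records: list[SnpRecord] = []

    def draw_p(bin_: SnpBin, size: int) -> np.ndarray:
        lo, hi = max(bin_.p_low, 1e-300), bin_.p_high
        if bin_.log_uniform:
            return 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=size)
        return rng.uniform(bin_.p_low, bin_.p_high, size=size)

    for bin_ in bins:
        if bin_.placement == "genome":
            coords = rng.integers(0, total, size=bin_.n)
            pvals = np.clip(draw_p(bin_, bin_.n), 1e-300, 1.0)
            for c, p in zip(coords, pvals):
                ci = int(np.searchsorted(starts, c, side="right") - 1)
                records.append(
                    SnpRecord(f"rs{len(records):07d}", chroms[ci], int(c - starts[ci]) + 1, float(p))
                )
        else:
            want_module = bin_.placement == "module_regions"
            idx = np.flatnonzero(is_module == want_module)
            if len(idx) == 0:
                raise ValueError(f"no regions available for placement {bin_.placement!r}")
            if want_module:
                targets, per_region = idx, bin_.n  # n SNPs in every module region
            else:
                targets = rng.choice(idx, size=min(len(idx), bin_.n), replace=False)
                per_region = 1
            for i in targets:
                r = catalog.entries[int(i)]
                if r.width < per_region:
                    raise ValueError(f"region {r.id} too small for {per_region} SNPs")
                pos = rng.integers(r.start, r.end + 1, size=per_region)
                pvals = np.clip(draw_p(bin_, per_region), 1e-300, 1.0)
                for pp, p in zip(pos, pvals):
                    records.append(SnpRecord(f"rs{len(records):07d}", r.chrom, int(pp), float(p)))
    records.sort(key=lambda s: (s.chrom, s.pos, s.snp_id))
    return GwasTable(records=records, provenance="synthetic")


def write_bundle(
    out_dir: str | Path,
    catalog: RegionCatalog,
    atlas: ExpressionAtlas,
    gwas: GwasTable,
    truth: pd.DataFrame,
) -> dict[str, Path]:
    """Write a simulated dataset in the external formats (BED/TSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    promoters = [e for e in catalog.entries if e.kind == "promoter"]
    enhancers = [e for e in catalog.entries if e.kind == "enhancer"]
    for kind, entries in (("promoters", promoters), ("enhancers", enhancers)):
        p = out / f"{kind}.bed"
        cat = RegionCatalog(entries=entries, genome=catalog.genome) if entries else None
        with open(p, "w") as fh:
            if cat:
                for r in cat.ordered():
                    if r.kind == "promoter":
                        # emit the TSS anchor so the catalog round-trips through the
                        # promoter-window expansion on load
                        tss = r.end - 100 if r.strand != "-" else r.start + 100
                        fh.write(f"{r.chrom}\t{tss - 1}\t{tss}\t{r.id}\t0\t{r.strand}\n")
                    else:
                        fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.id}\t0\t.\n")
        paths[kind] = p

    p = out / "genome.tsv"
    with open(p, "w") as fh:
        for c, l in catalog.genome:
            fh.write(f"{c}\t{l}\n")
    paths["genome"] = p

    p = out / "expression.tsv"
    df = pd.DataFrame(atlas.matrix, index=atlas.region_ids, columns=atlas.sample_ids)
    df.index.name = "region_id"
    df.to_csv(p, sep="\t", float_format="%.6g")
    paths["expression"] = p

    p = out / "samples.tsv"
    pd.DataFrame(
        {
            "sample_id": atlas.sample_ids,
            "group_id": atlas.sample_ids,
            "cell_type": atlas.cell_types,
            "exclude": 0,
        }
    ).to_csv(p, sep="\t", index=False)
    paths["samples"] = p

    p = out / "gwas.tsv"
    gwas.to_frame().to_csv(p, sep="\t", index=False, float_format="%.10g")
    paths["gwas"] = p

    p = out / "truth.tsv"
    truth.to_csv(p, sep="\t", index=False)
    paths["truth"] = p
    return paths


# ---------------------------------------------------------------------------
# Named fixtures


def _grouping_chain_bundle(seed: int):
    """Engineered catalog exercising transitive 100 kb / p<0.1 grouping.

    R consists of eight engineered enhancers on chr1: A-B and B-C are within
    100 kb and strongly correlated (one planted module), while A-C exceeds
    100 kb, so {A,B,C} merge only through the transitive chain.  D-E are
    within range but anti-correlated by construction (E is a decreasing
    transform of D), so they stay apart deterministically.  F is isolated;
    G-H are correlated but 150 kb apart.  Expected partition:
    {A,B,C} {D} {E} {F} {G} {H}.
    """
    rng = np.random.default_rng(seed)
    genome = [("chr1", 5_000_000), ("chr2", 5_000_000)]
    spans = {
        "A": 1_000_000, "B": 1_050_001, "C": 1_100_500,
        "D": 2_000_000, "E": 2_050_000, "F": 3_000_000,
        "G": 4_000_000, "H": 4_150_000,
    }
    entries = [
        RegulatoryRegion(id=name, chrom="chr1", start=s, end=s + 400, strand=".", kind="enhancer")
        for name, s in spans.items()
    ]
    n_bg = 192
    for k in range(n_bg):
        s = 20_000 + k * 25_000
        entries.append(
            RegulatoryRegion(id=f"bg{k:03d}", chrom="chr2", start=s, end=s + 400, strand=".", kind="enhancer")
        )
    order = {c: i for i, (c, _) in enumerate(genome)}
    entries.sort(key=lambda r: (order[r.chrom], r.start, r.id))
    catalog = RegionCatalog(entries=entries, genome=genome)

    n, m = len(entries), 50
    latent = rng.standard_normal((n, m))
    pos_of = {e.id: i for i, e in enumerate(entries)}
    a = copula_loading(0.9)
    z1 = rng.standard_normal(m)
    for name in "ABC":
        latent[pos_of[name]] = np.sqrt(a) * z1 + np.sqrt(1 - a) * rng.standard_normal(m)
    z2 = rng.standard_normal(m)
    for name in "GH":
        latent[pos_of[name]] = np.sqrt(a) * z2 + np.sqrt(1 - a) * rng.standard_normal(m)
    w = rng.standard_normal(m)
    latent[pos_of["D"]] = np.sqrt(a) * w + np.sqrt(1 - a) * rng.standard_normal(m)
    latent[pos_of["E"]] = -np.sqrt(a) * w + np.sqrt(1 - a) * rng.standard_normal(m)

    atlas = ExpressionAtlas(
        matrix=np.exp(latent),
        region_ids=[e.id for e in entries],
        sample_ids=[f"s{k:04d}" for k in range(m)],
        cell_types=[f"ct{k:03d}" for k in range(m)],
    )
    module_of = ["" for _ in entries]
    for name in "ABC":
        module_of[pos_of[name]] = "chainABC"
    for name in "GH":
        module_of[pos_of[name]] = "pairGH"
    truth = pd.DataFrame({"region_id": [e.id for e in entries], "module": module_of})

    records = [
        SnpRecord(f"sig_{name}", "chr1", spans[name] + 200, 1e-8) for name in spans
    ]
    bg_pos = rng.integers(1, 5_000_000, size=500)
    for k, p in enumerate(bg_pos):
        records.append(SnpRecord(f"rsbg{k:05d}", "chr2", int(p), float(rng.uniform(1e-3, 1.0))))
    records.sort(key=lambda s: (s.chrom, s.pos, s.snp_id))
    gwas = GwasTable(records=records, provenance="grouping_chain")
    return catalog, atlas, gwas, truth


GROUPING_CHAIN_PARTITION = [["A", "B", "C"], ["D"], ["E"], ["F"], ["G"], ["H"]]

FIXTURES = ("null_small", "planted_module", "two_hubs", "grouping_chain")


def make_fixture(name: str, out_dir: Optional[str | Path] = None, seed: int = 0):
    """Deterministic named fixtures; optionally written to *out_dir* as files.

    Returns (scenario_or_None, catalog, atlas, gwas, truth).
    """
    if name == "grouping_chain":
        catalog, atlas, gwas, truth = _grouping_chain_bundle(seed)
        scenario = None
    else:
        if name == "null_small":
            scenario = SimScenario(n_regions=200, n_samples=50, seed=seed)
        elif name == "planted_module":
            scenario = SimScenario(
                n_regions=2000, n_samples=100,
                modules=[ModuleSpec(size=15, rho=0.8, name="planted")], seed=seed,
            )
        elif name == "two_hubs":
            scenario = SimScenario(
                n_regions=2000, n_samples=100,
                modules=[
                    ModuleSpec(size=10, rho=0.8, name="hub1"),
                    ModuleSpec(size=10, rho=0.8, name="hub2"),
                ],
                seed=seed,
            )
        else:
            raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURES}")
        rng = scenario.rng()
        catalog = simulate_catalog(scenario, rng)
        atlas, truth = simulate_atlas(scenario, catalog, rng)
        gwas = simulate_gwas(scenario, catalog, truth, rng)
    if out_dir is not None:
        write_bundle(out_dir, catalog, atlas, gwas, truth)
    return scenario, catalog, atlas, gwas, truth
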