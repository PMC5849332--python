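# Methods

## The model

`ndanet` asks whether the regulatory regions genetically associated with a
trait share transcriptional activity patterns more than chance predicts.  The
inputs are (1) full GWAS summary statistics (every genotyped/imputed SNP with
its association p-value), (2) a catalog of promoter TSS and enhancer spans,
and (3) an expression atlas quantifying each region's activity (e.g. CAGE tag
counts or TPM) across many samples.

The analysis proceeds in six steps.

**1. SNP selection and mapping.**  The putatively-significant SNP set K is
every variant with association p < 5×10⁻⁶ — a deliberately permissive
threshold, chosen so regions just below genome-wide significance can be
rescued by coexpression evidence.  Promoter windows extend −300 bp upstream
to +100 bp downstream of the TSS in transcription direction (this covers the
core transcription-factor binding footprint); unstranded TSS are treated as
'+'; windows are clipped at contig ends.  Enhancers are their catalogued eRNA
span.  The trait-associated set R = P ∪ E contains every region holding at
least one K-SNP; a SNP inside overlapping regions hits all of them.

**2. Link probabilities.**  Pairwise similarity is Spearman rank correlation
(midranks for ties), robust to the heavy-tailed, zero-inflated distributions
of expression data.  A raw correlation is not comparable across nodes — a
broadly co-varying "hub" profile correlates with everything — so each
correlation x between index node i and partner j is converted into the
node-specific, directional empirical probability

    p(i→j) = (#{r > x} + 1) / (N + 1),

where r runs over the N = n_A − 1 correlations of node i with every other
node in the whole network A.  The add-one pseudo-count keeps p ∈ (0, 1] (the
plain count can reach zero, which would make the log-weight below infinite);
it upper-bounds the difference between "strictly stronger" and "at least as
strong" counting by 1/(N+1).  Anti-correlated pairs (x ≤ 0) carry zero weight
in scores — inverse regulatory relationships exist but are too rare to
outweigh the noise they admit — yet they remain inside each node's background
distribution.

**3. Grouping (n_res).**  SNPs travel in linkage blocks and neighbouring
regions share local regulation, so regions within 100 kb (inner gap between
intervals) whose correlation p-value in either direction is below 0.1 are
merged, transitively (single linkage).  Each group is represented by the
member with the largest NDA score against all other groups.  That definition
is circular, so representatives are initialised to the earliest member,
scored against the union of other groups' members, then refined against the
current representatives; two refinement rounds reach a fixed point in
practice and the result is then frozen.  Ties break to the smaller start
coordinate, then the lexicographically smaller id.  The group count n_res is
the number of independent units tested.

**4. NDA scores.**  For the set of representatives, each node's score is
s = Σ_j −log10 p(node→j) over the other members; within-group links never
contribute.  Because one very strong node inflates all its partners, an
iterative correction recomputes each node's score after removing every node
with a strictly larger initial score (ranking taken once from the initial
scores; exact ties stay in together, and the top node keeps its full score).
The corrected coexpression score ccs = s_iterative / n_res puts analyses of
different sizes on one scale.  Both s and s_iterative are reported.

**5. Significance.**  The null must preserve positional structure.
Post-mapping permutations (the default) rotate the observed nodes' indices on
the genomically-ordered list of all network nodes by a random offset (drawn
without replacement, never zero), regroup the rotated set by the same rules,
and demand the same group-size multiset as the observed grouping; a mismatch
triggers up to 8 fresh rotations, after which groups are padded with
consecutive neighbouring regions (oversized ones trimmed, surplus dropped)
until the multiset matches exactly.  Pre-mapping permutations instead rotate
the SNP set K on the concatenated circular genome and re-map; they measure
the composite of coexpression and the enrichment of trait SNPs in regulatory
sequence, and are available via `permutation_mode`.  Iterative scores from
all permuted networks form one pooled null (permuted nodes differ from run to
run, so per-node nulls are undefined); raw_p = (1 + #{permuted ≥ observed}) /
(1 + n_permuted), followed by Benjamini–Hochberg step-up FDR across nodes,
significant at FDR < 0.05.  A two-sample Kolmogorov–Smirnov statistic
comparing observed and permuted score distributions summarises the aggregate
signal, and matched quantiles are written for Q–Q plots.

**6. Cell-type specificity.**  For the significant set, each region's
replicate-averaged samples are aggregated per cell type (arithmetic mean) and
cell types are ranked by the region's activity.  Cell types in which a region
is inactive (expression ≤ 0 by default) all share the *worst* rank, so the
normalized rank is 1 and the Beta order statistic below treats inactivity as
carrying no evidence.  (The alternative — a shared tail midrank — makes a
cell type that is inactive in every selected region look "unusually
consistent": with 15 lists a constant normalized rank of 0.56 scores
0.56¹⁵ ≈ 1.7×10⁻⁴, and the permutation control cannot reproduce that tie
pattern, so every silent cell type would be called significant.)  The lists
are combined by robust rank aggregation: for each cell type with sorted
normalized ranks r₍₁₎ ≤ … ≤ r₍ₙ₎ across n lists,

    ρ = min_k P(Beta(k, n−k+1) ≤ r₍ₖ₎),      rra_p = min(1, ρ·n),

the Bonferroni-corrected minimum order-statistic p-value.  Because sample
composition biases raw RRA (a broadly active "housekeeping" profile ranks
high for any region set), ρ is compared against ρ values from random draws of
n expressed regions (10,000 by default; raise `n_celltype_permutations` to
the method's reference 100,000 when runtime allows), giving an add-one
empirical p and BH FDR across cell types.

## Synthetic data

The generator reproduces the statistical situation the method assumes, not
the biology of any particular atlas.  A default genome of 2 × 10 Mb carries
regions tiled with ±30% jittered spacing (~10 kb at 2000 regions), 80%
promoters (401-bp strand-aware windows) and 20% enhancers (200–400 bp
spans).  Background expression rows are i.i.d. log-normal.  A planted module
of target pairwise Spearman ρ_S is built from a shared Gaussian latent factor
with loading a = 2·sin(π·ρ_S/6) — the Gaussian-copula inversion of the
bivariate-normal Spearman formula — then transformed by exp, which preserves
all rank correlations exactly; realized module correlations land within
±0.05 of target at ≥100 samples.  Module members are placed ≥200 kb apart so
the LD-grouping step does not collapse them.  A module may be restricted to
named cell types (expression exactly zero elsewhere), and one cell type may
be marked "housekeeping" (all regions' activity multiplied by 5 in its
samples) to exercise the composition-bias control.  GWAS tables mix uniform
background SNPs (p ~ U(0,1), uniform positions; 20,000 by default) with
signal SNPs placed inside chosen regions, p log-uniform below 5×10⁻⁶ (or any
configured bin, e.g. weak SNPs with 10⁻⁴ < p < 10⁻² for the p-value-dependence
check).  Truth labels accompany every atlas so recovery can be scored without
external data.

What passing tests on this generator do *not* show: robustness to
sample-size imbalance across cell types, to mappability or GC artefacts in
real CAGE counts, to population-specific LD (the generator plants no LD; the
grouping rule is exercised geometrically), or to modules whose coexpression
is weaker or partial.  The named fixtures are `null_small` (200×50, no
structure), `planted_module` (2000×100, one 15-region ρ=0.8 module),
`two_hubs` (two 10-region modules) and `grouping_chain` (an engineered
catalog whose mapped regions A–H reproduce, deterministically, a transitive
merge chain {A,B,C}, a distance-gated correlated pair {G},{H}, an
anti-correlated close pair {D},{E} and an isolated singleton {F}).

## Numerical choices

- Correlations are computed by rank-transforming rows and block-multiplying
  z-scored ranks; results are independent of the block size.  Values are
  quantized at 10⁻⁹ before any counting: Spearman values are rationals on a
  far coarser grid, and strict-inequality counts must not depend on
  floating-point summation order.
- Zero-variance rows are excluded from the network with a warning; a network
  needs ≥50 comparison nodes per empirical distribution (configurable).
- Exact score ties share a rank in the iterative exclusion; near-ties at
  machine precision are not treated as ties.
- Permutation offsets are drawn without replacement so no two permutations
  coincide; retry rotations (after a group-multiset mismatch) are fresh
  uniform draws.
- Empirical p-values use the add-one rule throughout, so no p is ever zero;
  the raw-p floor is 1/(n_permuted_scores + 1).
- BH FDR uses the standard step-up with monotone enforcement
  (statsmodels `multipletests`).
- Duplicate SNP ids keep the record with the smallest p-value; "expressed"
  means activity > 0 in at least one sample (threshold configurable).

## Known limitations

- Iterative scoring gives the weakest node of every subset a score of exactly
  0; the empirical p-value distribution therefore has a conservative atom at
  p = 1 (≈9% for 30-node subsets).  Calls are unaffected — the atom sits at
  the non-significant boundary — but raw p is super-uniform near 1.
- Power for the bottom-ranked members of a genuine module is intrinsically
  limited under iterative scoring: a member ranked k-th from the top retains
  only its links to lower-ranked module members, so the last few members of
  even a strong module are statistically exchangeable with null nodes.  On
  the 2000-region planted-module benchmark this recovers ~10–11 of 15 members
  at FDR < 0.05 with zero decoys; raw (non-iterative) scoring recovers all 15
  but admits decoy regions that happen to correlate with the module's latent
  profile.  The package scores significance on the iterative statistic —
  specificity over sensitivity — and reports both columns.
- The LD check is diagnostic only: it flags representative pairs whose SNPs
  exceed r² ≥ 0.8 in a user-supplied table, and never filters.
- Desk-scale problem sizes (2000-region atlases, 1000-permutation nulls,
  10,000 cell-type permutations) are the package defaults for simulation
  studies; production atlases and the reference permutation counts (10,000 /
  100,000) are reached through `RunConfig`.
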