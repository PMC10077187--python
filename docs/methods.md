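# Methods

This note documents the models, conventions and numerical choices behind
`mebnet`, and what the synthetic benchmarks do and do not demonstrate.

## Input preparation

OTU tables are OTU × sample integer count matrices, one per kingdom, over a
shared sample set. Preparation applies, in order (configurable):

- **Rarefaction** to a fixed depth per sample by multivariate hypergeometric
  subsampling (without replacement), so column sums equal the depth exactly.
  Typical depths for paired 18S/16S pond surveys are ~31,800 and ~49,700
  reads per sample, which are the defaults carried by
  `SyntheticSpec.study_scale()`.
- **Prevalence filter**: an OTU is kept when it is detected (count > 0) in
  at least ⌈f·n⌉ samples; the default f = 0.5 with 48 samples keeps OTUs
  present in ≥ 24. The filter is idempotent and never touches the sample set.

Whether rarefaction precedes or follows the filter is a free choice in the
pipeline (`rarefy_first`, default true). The default order mirrors the usual
amplicon workflow in which depth normalization happens at the sequence
processing stage, before any network-specific filtering.

## SparCC correlation model

Counts are compositional; Pearson correlations on relative abundances are
biased by closure. The estimator works from log-ratio variances
t_ij = Var[log(x_i/x_j)], which are closure-invariant, and approximates
basis (latent absolute-abundance) log-variances ω² through the sparse linear
system t_i ≈ (p−2)ω_i² + Σ_j ω_j², then
ρ_ij = (ω_i² + ω_j² − t_ij)/(2ω_iω_j), clipped to [−1, 1].

Parameters (all exposed in `fit()` and the pipeline config):

| parameter | default | meaning |
|---|---|---|
| pseudocount | 1 | Dirichlet prior count added before forming fractions |
| n_draws | 20 | Dirichlet posterior draws; ρ is the element-wise median |
| exclusion_threshold | 0.1 | \|ρ\| above which the strongest pair leaves the basis system |
| max_exclusion_rounds | 10 | one pair removed per round |
| n_boot | 100 | permutation bootstrap replicates for P values |
| r_threshold, p_threshold | 0.6, 0.05 | edge retention: \|ρ\| > 0.6 **and** P < 0.05, both strict |

P values are the plain proportion of null replicates with |ρ| at least the
observed value, the null being independent per-OTU permutation of counts
across samples (association destroyed, per-OTU abundance distributions
preserved). No +1 continuity correction is applied, so with 100 replicates
the smallest attainable P is 0; at the 0.05 threshold this behaves like
"fewer than 5 of 100 nulls as extreme". Basis variances solved from the
linear system are floored at 1e−10 before taking square roots.

Both kingdoms are pooled into a single SparCC run (cross-kingdom log-ratios
carry the signal); only inter-kingdom edges proceed to network construction.

## Bipartite networks and node statistics

Edges are split by sign into two networks with weight |ρ|; isolated nodes
are pruned, and a node with links of both signs appears in both networks.
Downstream metrics use the quantitative weights; NODF and the z–c role
statistics use the binarized matrix, and where integer interaction counts
are required (d′ bounds, Patefield marginals) weights are scaled ×100 and
rounded — with |ρ| ∈ (0.6, 1] the relative rounding error is below 1%.

- **NODF**: mean over all row pairs and column pairs of the paired overlap
  percentage (100·overlap/fill of the smaller set) when fills strictly
  decrease, else 0. Binary by definition.
- **d′ (Blüthgen)**: d_i = Σ_j p′_ij ln(p′_ij/q_j) against partner marginal
  availability q, standardized to [0, 1] by d′ = (d − d_min)/(d_max − d_min)
  with d_max = ln(m/A_i) — the tight upper bound, attained exactly by a node
  whose single partner nobody else uses — and d_min evaluated on the most
  availability-proportional integer allocation of the node's A_i
  interactions (largest-remainder apportionment, ties broken by column
  order). A node whose bounds collapse (one possible partner) gets d′ = 0.
- **Interaction evenness** uses the ln(rows·cols) denominator (the "product"
  convention); Shannon diversity uses natural logs over interaction weights.
- **Quantitative linkage density**: marginal-weighted mean of 2^H (effective
  partner counts, base-2 entropy per node), averaged over the two guilds.
- **Clustering coefficient** per guild: mean local clustering of the
  one-mode projection (two members linked iff they share ≥ 1 partner; nodes
  with < 2 projection neighbours contribute 0). Several two-mode variants
  exist; the projection-based one is used because it is the common default
  in general-purpose graph software.
- **Compartments** are connected components counting only linked nodes.

Core taxa are nodes present in both signed networks; their degree symmetry
is summarized by a = (d⁺ − d⁻)/(d⁺ + d⁻) ∈ [−1, 1], an index introduced here
to quantify biased positive/negative linkage, and by the fraction of all
degrees incident to core nodes.

## Nestedness significance

Null matrices preserve the integer row and column totals of the observed
(×100-scaled) weight matrix. They are drawn from the fixed-margin
hypergeometric ensemble by cross-tabulating a random pairing of row and
column labels, which is distribution-identical to Patefield's r2dtable
sequential scheme. Each null table is binarized at > 0 before NODF, since
NODF is a binary index. p_higher and p_lower are plain proportions of nulls
at or beyond the observed value over n_rand = 100 randomizations by default;
ties count toward both, so p_higher + p_lower ≥ 1. Matrices with fewer than
two occupied rows or columns are rejected (the null is degenerate there).

## Modularity and roles

Barber's Q is computed module-wise as Σ_m [e_m/m − K_m D_m/m²] over shared
row/column labels. The optimizer is weighted label propagation: rows start
as singletons (or k random labels on restarts), columns adopt their
strongest partner's label, then guilds are swept alternately, each node
taking the candidate label with the best marginal score
(w_i→module − k_i·D_module/m), keeping its current label on ties; sweeps
stop when Q stops increasing (tolerance 1e−12, cap 200 sweeps). The
multi-restart wrapper (default 10 restarts, seeds spawned from one
SeedSequence so results are reproducible and Q is non-decreasing in the
number of restarts) varies the initial module count — the same idea as the
DIRT variant of the algorithm.

z and c are computed on binary degrees. z is the z-score of a node's links
into its own module, standardized over all nodes (both guilds) of that
module with the population standard deviation; modules in which every member
has equal within-module degree give z = 0. c = 1 − Σ_t (k_it/k_i)². Role
thresholds: z > 2.5 distinguishes hubs; c > 0.62 distinguishes
connectors/network hubs.

## Robustness

One guild is removed cumulatively; an opposite-guild node goes secondarily
extinct when its last surviving partner disappears. The survivor fraction
y_k (y_0 = 1, y_N = 0) is integrated by trapezoid over the fraction removed:
R = (1/N)·Σ (y_{k−1}+y_k)/2. Removal orders are uniformly random (default
100 replicates) or generalists-first by **initial** degree — degrees are not
recomputed during the cascade, which keeps the scheme deterministic up to
tie-breaking; ties are shuffled per replicate. Directions (which guild is
removed) are reported separately, not averaged.

## Synthetic communities

`generate_community` draws per-sample basis log-abundances from a
multivariate normal whose correlation matrix is the identity plus the
planted signed inter-kingdom entries (log-sd 1.0 per OTU by default, a
typical amplicon-scale overdispersion), exponentiates, closes to fractions
per kingdom, and draws multinomial counts at the kingdom's sequencing depth.
Planting correlations on the latent basis scale makes "planted edge" mean
exactly the quantity SparCC estimates. Positive-definiteness of the planted
covariance is checked by Cholesky and violations are reported with advice to
lower magnitudes; the edge-planting helper keeps pairs node-disjoint so any
magnitude < 1 is safe. Phylum labels are sampled from representative coastal
aquaculture pond frequencies (Proteobacteria-dominated bacteria;
Chlorophyta/Ciliophora/Fungi-dominated microeukaryotes) so phylum summaries
look realistic.

Two named parameterizations:

- `study_scale()`: 48 samples, 1210 bacterial and 406 microeukaryotic OTUs,
  depths 49,706/31,781 — the scale of a filtered paired pond survey. Used
  for generator-level checks.
- `benchmark()`: 200 samples, 40 + 20 OTUs, depth 3000 (50 reads per OTU),
  12 node-disjoint planted edges at |r| = 0.9 (8 positive, 4 negative).
  This is the edge-recovery benchmark: the pipeline must recover ≥ 80% of
  planted edges with matching sign while ≤ 5% of reported inter-kingdom
  edges are unplanted. The OTU count is kept modest so the full
  SparCC-plus-bootstrap fit runs in seconds; recovery rates are driven by
  sample size, depth per OTU and magnitude, which are held at the benchmark
  conditions, not by community richness.

What the generator does **not** emulate: sequencing error and chimeras,
intra-kingdom association structure, habitat covariates, taxon-abundance
mean–variance coupling, and dense overlapping association motifs (planted
edges are node-disjoint). Passing the recovery benchmark therefore shows the
estimator chain is correctly implemented and well calibrated under its own
model assumptions — not that real pond networks are recovered at those
rates.

## Degenerate inputs and tie-breaking

- Empty networks: metric functions raise; the pipeline reports link counts
  only. 1×1 networks: evenness is undefined (NaN in reports), NODF needs
  ≥ 2 rows and columns.
- Rarefaction refuses depths exceeding any sample total, naming the sample.
- All randomness flows through `numpy.random.Generator`; the pipeline fans a
  single master seed out to stage seeds via `SeedSequence.spawn`, and every
  derived seed is recorded in the run manifest.
- Label propagation keeps the current module label on score ties; largest
  remainder apportionment (d_min) breaks remainder ties by column index.

## Known limitations

- The bootstrap P resolution is 1/n_boot; with the default 100 replicates,
  P < 0.05 effectively means ≤ 4 exceedances. Increase `n_boot` for finer
  control of the threshold.
- The basis-variance system is solved by least squares after pair exclusion;
  with very few OTUs (p = 3) it reduces to the exact closed form, below that
  it raises.
- d′ depends on the ×100 integer scaling; alternative scalings shift d_min
  slightly for weakly supported nodes.
- `generate_nested_incidence` guarantees strictly decreasing row fills;
  column fills are strictly decreasing (and NODF = 100) only for
  staircase-compatible shapes such as the canonical square maximal case —
  strict column fills require consecutive row fill values.
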