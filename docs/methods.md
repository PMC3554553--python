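# Methods

## The weight-update model

All algorithms in this package estimate, for each SNP, a weight in [−1, 1]
that is large when genotype mismatches at that SNP co-occur with class
mismatches among neighbouring samples. The shared update is

    ΔWᵢ[a] = Σ_{j≠i} c(sᵢ,sⱼ) · diff(a,sᵢ,sⱼ) · f(dist_ij) / Σ_{j≠i} |f(dist_ij)|,
    W[a]   = mean over visited samples i of ΔWᵢ[a],

with `c = +1` for a miss and `−1` for a hit, `diff ∈ {0,1}` the local
attribute mismatch, `dist_ij` a global sample distance and `f` a neighbour
weighting kernel with range [−1, 1].

**Normaliser.** The denominator uses the *absolute* kernel mass
`Σ|f|` rather than the signed sum `Σf`. For the signed ("star") kernels the
signed sum can vanish or go negative, which would make the update unbounded
or flip its sign; the absolute mass is the smallest normaliser that
guarantees `|ΔWᵢ[a]| ≤ 1` for every kernel, and coincides with `Σf` for the
non-negative kernels (ReliefF, SURF). A sample whose kernel mass is zero
contributes a neutral update of 0. The self-pair `j = i` is always excluded.

**Kernels.**

- *ReliefF*: per-sample steps at the k-th nearest hit and k-th nearest miss
  radii, default `k = 10`. Ties at the k-th neighbour are inclusive (every
  sample at distance ≤ the k-th radius counts), which makes the output
  invariant to sample order. If fewer than `k` hits or misses exist, all
  available neighbours of that category are used (with a warning).
- *SURF*: global step `f = 1` iff `dist ≤ t`. The boundary is inclusive,
  matching the signed step below.
- *SURF\**: signed step, `+1` iff `dist ≤ t`, else `−1`.
- *SWRF\**: sigmoid `f(d) = 2/(1 + exp(−(t−d)/(u/scale))) − 1`, strictly
  decreasing, `f(t) = 0`, saturating to ±1 for near/far pairs.

`t` defaults to the mean and `u` to the population standard deviation of
the pairwise distances, computed over the n(n−1)/2 unordered distinct pairs
(diagonal excluded). Distances are exact integers (Hamming or taxicab)
computed via indicator matrix products rather than floating-point `pdist`,
so threshold comparisons and tie policies are exact.

**Scale factor.** At the default `scale = 4`, `|f| > 0.95` ("full weight")
requires `|d − t| > (u/4)·ln 39 ≈ 0.916·u` — full weight begins roughly one
standard deviation from the mean distance. Because the pairwise-distance
distribution of high-dimensional SNP data is approximately normal, this
puts roughly a third of all pairs in the saturated regions (the normal
value is P(|Z| > 0.916) ≈ 36%; the acceptance script measures ≈ 35–36% on
simulated data). At `scale = 1` the onset moves to ≈ 3.66 standard
deviations and far fewer than 1% of pairs reach full weight: the kernel
degrades into a ramp. At very large scales the sigmoid hardens into the
SURF* step; the package verifies numerical equality at `scale = 10⁶` on
tie-free data.

**Original Relief** is kept as a separate routine: one nearest hit and one
nearest miss per sample, update `diff(a,sᵢ,s_miss) − diff(a,sᵢ,s_hit)`,
divided by the number of visited samples. Nearest-neighbour ties are broken
by lowest sample index. Note that the framework run with a k=1 ReliefF
kernel produces exactly *half* of Relief's weights: the framework
normalises by the kernel mass of both neighbours (2), Relief by the sample
count only. The ranking is identical; the tests pin the factor.

**Engine contracts.** Binary classes only; genotypes in {0,1,2}; default
pass visits every sample (deterministic), subsampling requires an explicit
seed. The per-sample ReliefF thresholds are computed once from the full
distance matrix (O(n²) memory).

## Synthetic epistasis generator

The generator emulates the style of two-locus benchmark collections used
for Relief-family evaluations: a 3×3 penetrance table `f_gh = P(disease |
g, h minor alleles at loci A, B)` with Hardy–Weinberg genotypes, linkage
equilibrium between the loci, balanced case-control sampling, and
class-independent noise SNPs appended afterwards.

- **Prevalence** `K = Σ P(g)P(h) f_gh`; **heritability** is variance
  explained on the observed scale, `h² = Σ P(g)P(h)(f_gh − K)² / (K(1−K))`
  — the standard convention in this synthetic-epistasis literature.
- **Main-effect score** is the larger of the two marginal-penetrance ranges;
  purely epistatic models have score ≈ 0.
- **Model search** (`find_model`): a uniform random table is projected onto
  the zero-marginal-effect subspace (`f → f − m_A(g) − m_B(h) + 2K`, which
  keeps the P-weighted mean at K and flattens both marginals exactly), then
  rescaled about K by `α = √(h²·K(1−K)/Var)` so the recomputed heritability
  hits the target to floating-point accuracy; candidates with cells outside
  [0, 1] are rejected. Plain rejection on the main-effect tolerance without
  the projection step would essentially never terminate — random tables
  carry main effects orders of magnitude above the 0.01 tolerance.
  All-or-none (0/1) candidate tables, whose heritability is identically 1,
  are interleaved so near-unity targets stay reachable (the fully penetrant
  XOR table is the classic witness).
- **Sampling**: genotype pairs are drawn unconditioned and disease assigned
  with probability `f_gh`; rejection sampling fills equal case and control
  quotas. Noise SNPs default to Hardy–Weinberg genotypes with per-SNP MAF ~
  Uniform(0.05, 0.5); a uniform-over-{0,1,2} mode is available since "random
  genotypes" admits either reading. Functional SNPs occupy the first two
  columns and are recorded in the dataset metadata and the study manifest.
- **Designs**: `SimulationDesign` defaults to the benchmark factorial —
  heritabilities (0.01, 0.025, 0.05, 0.1, 0.2, 0.3, 0.4), MAFs (0.2, 0.4),
  5 models per setting, 100 replicates per model, sizes (200, 400, 800,
  1600), 998 noise SNPs — 28,000 datasets in all. Per-dataset seeds are
  spawned deterministically from the design seed and recorded in the
  manifest, so a design is reproducible byte-for-byte.

What the generator does **not** emulate: linkage disequilibrium structure,
genotyping error, missing genotypes, covariates, population stratification,
or main-effect loci. Passing power results therefore speak to the
algorithms' ability to find *pure, noise-embedded* two-locus interactions
under idealised genotype sampling — not to performance on real GWAS data.

## Evaluation protocol

A run *succeeds* at percentile cutoff `p` if both functional SNPs rank
inside the top `round(a·(100−p)/100)` attributes (half away from zero; the
95th percentile of 1000 SNPs examines exactly 50). Power is the success
proportion over replicates; curves run from the 100th to the 50th
percentile and are monotone by construction. Ranking ties are broken by
ascending attribute index, making every reported rank deterministic.

Success counts of two algorithms are compared with the two-sided Fisher
exact test (probability-mass convention with a 1e−7 relative tie tolerance,
delegated to `scipy.stats.fisher_exact` and validated in the tests against
exhaustive integer-combinatorics enumeration for all tables with margins
≤ 30), with Bonferroni correction over the number of comparisons performed.

## Problem sizes used in the shipped checks

The shipped scaled-down power study uses 100 datasets (5 models × 20
replicates) at heritability 0.2, MAF 0.4, 400 samples and 100 noise SNPs,
checking the ordering power(SWRF*) ≥ power(SURF*) ≥ power(ReliefF) at the
95th-percentile cutoff. The sigmoid geometry checks use 400 samples × 1000
class-independent SNPs (79,800 pairs; the acceptance script averages 5
replicate datasets). These sizes give sampling errors of a few percentage
points on power estimates, small enough to resolve the ordering observed at
full benchmark scale.

## Known limitations

- Binary phenotypes and complete genotypes only; no multi-class or
  missing-data handling.
- No iterative re-weighting wrappers (e.g. repeated runs with attribute
  removal), and no dimension-weighted global distances.
- The O(n²) distance matrix limits practical sample sizes to a few
  thousand on desktop memory.
- The model search targets *purely* epistatic tables; models with
  deliberate small main effects require relaxing `main_effect_tol`.
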