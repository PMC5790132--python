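# Methods

Model definitions, priors and numerical choices, module by module.
Time is measured in units of 100 Myr; rates in substitutions per
nucleotide site per 100 Myr.

## Species timetree (`clockpart.trees`)

A fixed 9-taxon ultrametric tree: a caterpillar of internal nodes
1–7 with ages (1.00, 0.95, 0.55, 0.40, 0.25, 0.15, 0.10) plus a
two-taxon clade (node 8, age 0.50) attached at the root.
`SpeciesTimeTree` stores parent/child arrays, node ages and the
branch↔child mapping; `rooted_to_unrooted_lengths` folds the 16 rooted
branches to the 15 branches of the unrooted topology (the two root
branches merge into edge 0).

## Clock-violation simulation (`clockpart.clock_sim`)

Per gene g: locus rate μ_g ~ Gamma(10, rate 10/0.5) (mean 0.5, 95%
interval (0.24, 0.85)). Per branch b: independent log-normal rates
log μ_gb ~ N(log μ_g − σ²/2, σ²); the −σ²/2 offset keeps
E[μ_gb] = μ_g, and σ² = 0 is the strict clock. Nucleotide branch
lengths are rate × duration; codon lengths are exactly 3× the
nucleotide lengths.

## Codon simulation (`clockpart.codon_sim`)

GY94-style M3 discrete mixture over the 61 sense codons (universal
code), κ = 2 on transitions, ω on nonsynonymous changes, uniform codon
frequencies. Site classes ω = (0.01, 0.5, 0.9) with class
probabilities (0.8, 0.19, 0.01) for conserved genes (mean ω 0.112) and
(0.5, 0.3, 0.2) for less-conserved genes (0.335). The mixture is
normalized *globally* so the expected number of substitutions per codon
site is 1 per unit branch length, preserving the relative rates of the
classes. Transition matrices come from a symmetric eigendecomposition
(uniform frequencies make Q symmetrizable trivially); rows are clipped
at 0 and renormalized against eigen-round-off. Alignments are emitted
as codon or nucleotide matrices with per-column gene and codon-position
annotations, and can be written as FASTA, PHYLIP or RAxML-style
partition files.

## Partition schemes (`clockpart.partitioning`)

Data blocks are (gene, position-class) pairs, position classes
{1+2, 3}. Fixed schemes: C (everything), CP (two position pools),
G (per gene), GCP (per block).

**PF** (`bic_greedy_merge`): greedy bottom-up merging under a linked
proportional-branch-length model — one shared branch-length set fitted
once on the full alignment and held fixed, with a free rate multiplier,
κ, α and empirical base frequencies per partition (6 parameters).
BIC uses N = total columns and counts the shared branch lengths once.
Merging stops when no pairwise merge lowers BIC.

**CS** (`gap_statistic_cluster`): per-block branch-length vectors are
compared with the scale-free sBSD distance
d(a, b) = max of the two directed values min_{s≥0} ‖a − s·b‖ / ‖a‖
(closed form at s = ⟨a,b⟩/‖b‖²). Blocks are embedded by classical MDS,
clustered by deterministic k-medoids (build + swap), and k is chosen by
a bounding-box gap statistic (uniform reference sets, default 500
bootstraps), preferring k = 1 when no gap is significant.

## Likelihood surfaces (`clockpart.ml`)

HKY85 with 4-category discrete-gamma rate heterogeneity (mean-preserving
quantile discretization). Felsenstein pruning over site patterns with
per-category (patterns × 4) matrix products; the branch-length gradient
is computed analytically in one postorder/preorder pass and verified
against central differences. `fit_branch_lengths` maximizes over
(branch lengths, log κ, log α) with L-BFGS-B; alignments over 20 000
columns are fitted in two stages (κ/α profiled on a deterministic
column stride, then branch lengths refitted on the full data).
`ApproxLikelihoodSurface` keeps (b̂, ∇ℓ, H, ℓ̂, κ̂, α̂);
`taylor_approx_loglik` evaluates the second-order expansion with
negative proposals truncated at 0. Surfaces serialize to JSON.

## Dating MCMC (`clockpart.mcmc`)

**Time prior.** Calibrated nodes carry soft-bound densities: 95% mass
uniform on (lower, upper), 2.5% in a power tail toward 0 and 2.5% in an
exponential right tail, density-continuous at the bounds. Given the
calibrated ages, the free node ages are jointly uniform on their order
polytope; the joint prior is (∏ soft bounds) / V(calibrated ages),
where the polytope volume V is computed exactly by recursive polynomial
integration. This construction makes the prior-only marginals of
calibrated nodes equal their calibration densities. The root must be
calibrated.

**Rate priors.** Locus mean rates μ_1..L follow a gamma-Dirichlet
prior: the average rate is Gamma(shape, rate) (G(2,4) in the reference
configuration) and the rates partition it via a symmetric Dirichlet.
σ̄² ~ G(2, 20) analogously.

**Clocks.** IR: branch rates iid log-normal LN(log μ − σ²/2, σ²).
AR: geometric-Brownian node rates with variance σ²·duration and
midpoint branch rates.

**Sampler.** Metropolis-within-Gibbs sweeps: sliding-window age moves
with reflection; a whole-tree scale move (ages × c, rates / c) that
leaves branch lengths invariant and mixes the time–rate confounding;
multiplicative branch-rate moves vectorized across partitions;
locus-rate and σ² moves. Step sizes adapt to 20–40% acceptance during
burn-in only. Dated chains initialize from the data (ages proportional
to mean fitted molecular depths, root at its calibration midpoint;
rates at fitted length / duration), which keeps the short scaled-down
burn-in safely past convergence; prior-only chains initialize from a
prior-style draw. Summaries: posterior means, shortest-interval 95%
HPDs, autocorrelation-based ESS, acceptance rates;
`convergence_check` compares two independent chains.

**Chain profiles.** `McmcSettings` defaults mirror the full reference
protocol (burn-in 10⁶, 10⁴ samples every 500). The scaled-down profile
used by the experiment driver and the results script (burn-in 3000,
2000 samples every 3) was chosen from acceptance-rate and ESS
diagnostics under the runtime budget.

## Evaluation (`clockpart.evaluate`)

Per node and replicate, with true age t, posterior mean t̂ and 95% HPD
width w: relative error d = |t̂ − t|/t; relative width w/t;
√MSE = √((w/3.92)² + (t̂ − t)²) (the interval-implied variance plus
squared error); coverage with closed intervals (boundary counts).
Aggregation averages over replicates per node, then over nodes, so the
overall value is the unweighted mean of per-node means.

## Orchestration (`clockpart.experiment`)

`ExperimentConfig` crosses rate priors (G(2,4) correct, G(2,40) slow,
G(2,0.4) fast), calibration strategies (root B(0.8,1.2); plus node-3
B(0.525,0.575); or the deliberately wrong B(0.575,0.625)), clock models
and schemes over shared replicates. Surfaces are cached by column set,
so schemes that induce the same partitions never refit. Artifacts per
replicate: gene trees (Newick), rate tables (TSV), alignment (PHYLIP),
partition file, scheme JSONs, surface JSONs, trace TSVs and a `.done`
marker carrying the config hash. Per-cell seeds derive from the master
seed via SHA-256 → `SeedSequence` and stay below 2³¹.

## Known limitations

- The species topology is fixed; no topology inference.
- The birth–death time-prior kernel is implemented in its uniform
  (λ = μ, ρ = 0) limit only; other settings raise `NotImplementedError`.
- The approximate likelihood is quadratic in unrooted branch lengths;
  very short chains far from the MLE can exploit surface curvature
  error, as with any Taylor-surface dating method.
- `bic_greedy_merge` ranks merges under fixed shared branch lengths;
  it cannot distinguish blocks that differ only by a branch-length
  *pattern* at equal overall rate (a scalar multiplier per partition is
  the only linked degree of freedom).
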