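# Methods

## The measurement being modelled

A pooled loss-of-function screen for regulators of T cell migration into
the CNS reads out, per sgRNA and tissue, how many knockout cells reached
that tissue. The transduced pool (about 1,000 cells per guide) is injected
into the blood; spleen and blood samples are neutral subsamples of that
pool, while entry into spinal-cord meninges and parenchyma passes a
selective bottleneck: a cell carrying a knockout of a migration
*facilitator* enters with reduced probability, a knockout of a *brake*
with increased probability. Sequencing the guide cassette afterwards gives
an sgRNA × sample count matrix; everything downstream is count statistics.

## Statistical chain

### Filtering and normalization

sgRNAs with fewer than 50 raw counts in more than two replicates of the
same tissue are discarded globally ("fewer than" and "more than" are
strict, so (50, 0, 0) survives and (49, 49, 49) does not). Size factors
are median-of-ratios: the pseudo-reference for sgRNA *i* is the geometric
mean of its counts across samples, and sample *j*'s factor is the median
of c_ij / g_i over reference sgRNAs, the reference set being sgRNAs with
all counts ≥ 50 (configurable, and restrictable to NT guides). Size
factors are defined only up to one overall scale convention; the
equivariance that matters — scaling one sample by λ scales its factor
*relative to every other sample* by λ and leaves normalized count ratios
unchanged — holds exactly and is property-tested at 1e-10. Zeros are
retained; the pseudocount (default 1) keeps lfcs finite.

### Per-sgRNA negative-binomial test

For comparison B vs A the statistic is the sum S_B of B's normalized
counts. Its null distribution is a negative binomial centred on
n_B · μ̂_A with variance

    Var(S_B − n_B μ̂_A) = n_B σ²(μ)(1 + n_B / n_A),

where σ²(μ) comes from a least-squares fit of log(variance) on log(mean)
across the NT guides' per-sample normalized counts (fallback: all guides
when fewer than 30 NT guides are present; Poisson tail when the fitted
variance does not exceed the mean). The (1 + n_B/n_A) term propagates the
sampling error of the reference mean; without it the one-sided p-values
are visibly anticonservative at 3 + 3 replicates. sgRNAs whose reference
group is all-zero after normalization are flagged and assigned p = 1.
Depletion and enrichment p-values are converted to mid-rank percentiles
in (0, 1], ties broken by mid-rank and residual ties by index order.

### Gene aggregation (modified robust rank aggregation)

A gene's sorted member percentiles r₍₁₎ ≤ … ≤ r₍ₙ₎ enter
βₖ = P[Binomial(n, r₍ₖ₎) ≥ k]; members with percentile > α (default 0.25)
are non-informative, the score is ρ = min over informative k of βₖ (ρ = 1
when no member is informative) and `goodsgrna` counts the informative
members. The permutation p-value draws, independently for each gene,
n_perm (default 1,000) same-size percentile sets with replacement from
the full pool (NT guides included in the pool, excluded from the gene
table). Two deliberate choices:

- **Independent nulls per gene.** Sharing one null sample across genes
  correlates every gene's p-value through the common null ECDF and
  inflates the Kolmogorov–Smirnov distance of the null p-value
  distribution; independent draws (vectorised, chunked) keep the
  end-to-end calibration test meaningful.
- **Smoothed tie handling.** ρ has an atom at 1 (probability 0.75⁴ ≈ 0.32
  for a 4-guide gene under the null), so the plain formula
  (1 + #{ρ′ ≤ ρ})/(n_perm + 1) stacks ~32 % of null genes at p = 1. The
  default p-value is the standard smoothed permutation form
  (1 + #{ρ′ < ρ} + U·#{ρ′ = ρ})/(n_perm + 1) with U ~ Uniform[0, 1) drawn
  per gene from the same seeded generator: identical to the plain formula
  whenever ρ is untied, exactly uniform under the null, floor
  1/(n_perm + 1) respected. `tie_break='conservative'` restores the plain
  formula.

The gene-level lfc is the median (configurable to mean) of member sgRNA
lfcs and is reported identically in the neg and pos columns, matching the
MAGeCK-style gene-summary format.

### Non-targeting resampling null

800 pseudo-genes are built by averaging 4 NT sgRNA lfcs drawn with
replacement; their standard deviation σ_NT is the empirical noise scale
of a "gene" and feeds the effect-size threshold. For iid NT lfcs the
ratio σ_NT/σ_guide concentrates near 1/√4, which the tests verify.

### Candidate tiers and essentiality calls

The genome-wide → validation funnel and the facilitator/brake rules are
table-driven with every inequality as printed: CNS-vs-blood |lfc| > 0.5;
other comparisons (|lfc| > 1 ∧ directional goodsgrna ≥ 2) ∨ (|lfc| > 0.6
∧ goodsgrna > 2 in either direction — a `directional_weak_tier` switch
restricts this to the lfc's own direction); expression filter with the
|lfc| > 0.85 CNS rescue; external GO-derived lists unioned verbatim.
Facilitator: lfc < −3σ_NT ∧ goodsgrna ≥ 3 ∧ p < 0.05; brake mirrored; the
aggregate "essential" flag needs the same directional call in ≥ 3
comparisons (configurable). GO-term membership itself and the
expressed-in-T-cells list are inputs, not computed.

### Flow co-transfer statistics

The migration ratio is (KO/control)_tissue ÷ (KO/control)_blood within
one animal, so inter-animal transfer efficiency cancels; any of the four
referenced populations below 100 cells excludes the record, with the
reason kept. Location tests against 1 are gated by Shapiro–Wilk at
α = 0.05 (unstated in the source protocol; exposed as a parameter):
normal → one-sample t, otherwise Wilcoxon signed-rank (exact null for
n ≤ 25 without ties, normal approximation with continuity correction
above). Summary-statistic input forces the t route. Multiplicity is
handled by the Benjamini–Krieger–Yekutieli two-stage step-up: stage 1 runs
BH at q′ = q/(1+q) to estimate m₀ = m − r₁, stage 2 re-runs the step-up
with critical values i·q′/m₀; adjusted values are defined so that
adjusted ≤ q exactly reproduces the flags.

### Clonal overlap

After restricting to cells with exactly one β chain and a non-empty CDR3
(exclusions counted, never silent), the clonotype key is
(participant, CDR3β-aa) — V/J calls can be appended via `clonotype_cols`.
Overlapping = key present in both compartments of the same participant;
expanded = overlapping with ≥ 3 total cells. The per-cluster propensity is
100 · overlapping/blood cells within the cluster and group (the group's
blood cells are the denominator; clusters with none are flagged
undefined). Expression enters as the mean (configurable to median)
log-normalized value over those same cells; correlations are Pearson with
a t-transform p-value on n − 2 degrees of freedom.

## The synthetic-data generator

`simulate_screen` draws, per replicate, one shared blood pool
(multinomial over guides at the configured coverage), then subsamples it
per tissue: multivariate hypergeometric for peripheral tissues, and for
CNS tissues probability-proportional-to-weight Poisson sampling
(per-guide binomial thinning with inclusion probabilities iteratively
capped at 1 and renormalised to the bottleneck size) with cell weights
2^(effect_lfc · efficacy) — an approximation to exact weighted sampling
without replacement that preserves the weighted marginals and the
per-guide cap, so bottleneck overdispersion emerges at the cell level.
Reads are gamma-Poisson (NB) around the cell counts scaled to the target
depth. Guide efficacies are Beta(8, 2) (mean 0.8) by default. All
randomness descends from one integer seed via `SeedSequence` spawning.

Default conditions are the desk-scale screen used throughout the tests:
2,000 genes × 4 sgRNAs + 800 NT guides, 1,000× pool coverage, 300×
per-tissue bottlenecks, 3 replicates, ~500 reads per guide, NB dispersion
0.01. Genome-wide scale (21,410 genes, 396 miRNAs) is reachable by
parameter. What the generator does *not* emulate: guide-design biases (GC
content, off-target), PCR jackpotting beyond the NB dispersion,
animal-to-animal pooling structure, or clonal T cell expansion between
injection and sampling — so passing recovery tests demonstrate the
statistics, not robustness to those real-data artefacts. Note that with
sequencing depth fixed, planting many depleted guides redistributes reads
to the remainder (compositional shift); recovery tests therefore measure
planted effects against the null guides.

`simulate_flow` splits a fixed gate binomially at the tissue's true
KO/control ratio (blood pinned at 1), so the normalized ratio estimates
that truth directly. `simulate_clones` partitions blood cells into clones
with geometric sizes (mean 2 cells), seeds each clone into CSF with
probability equal to its cluster's propensity (1 + Poisson(0.5) CSF
cells), and gives configured genes per-cluster mean expression
intercept + slope · propensity with Gaussian cell noise; CDR3β strings
are random and unique per clone within a participant, not V(D)J-realistic.

## Numerical and design notes

- Seeds: every stochastic routine takes an explicit integer seed;
  identical seeds give byte-identical outputs.
- The NB tail uses the integer-rounded count sum; when the modelled
  variance does not exceed the mean the Poisson tail is used instead.
- The α-RRA permutation chunk size (256 genes) only bounds memory.
- FASTQ guide counting searches the first occurrence of the vector anchor
  (default `CACCG`) and matches the following 20 nt exactly; Hamming
  mismatch tolerance is opt-in and linear-scans the manifest, acceptable
  for validation-scale libraries.
- Degenerate inputs raise typed errors (zero-variance test input,
  empty normalization reference, missing NT null) rather than returning
  NaNs; the CLI maps error classes to distinct exit codes.
- Library manifests take explicit per-class guide counts plus an optional
  exact-total trim, because published library totals are ambiguous about
  whether control guides are included; both readings are constructible.

## Limitations

The screen statistics assume guides of a gene are exchangeable evidence;
guide-specific off-target effects are not modelled. The NB variance model
is a single log-log line — adequate for the simulated dispersion range,
cruder than shrinkage estimators on real data. The aggregate essential
flag treats tissue comparisons as independent votes although they share
the blood reference. Clonal-overlap propensity inherits the usual
single-cell caveats (cluster-label quality, sampling depth of CSF).
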