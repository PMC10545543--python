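# cnscreen

Analysis toolkit for pooled **in vivo CRISPR migration screens**, built
around the screen design in which autoreactive CD4⁺ T cells carrying a
genome-wide knockout library are transferred into an animal and later
recovered from blood, spleen, spinal-cord meninges and parenchyma. Guides
whose knockout impairs entry into the CNS (*facilitators*) are depleted in
CNS tissues relative to blood; guides whose knockout enhances entry
(*brakes*) are enriched. The package is for computational biologists who
need the full desk-side statistics of such a screen — plus the two
companion readouts, flow-cytometry co-transfer ratios and blood↔CSF TCR
clonal overlap — with a synthetic-data generator that plants known effects
for end-to-end validation.

## What it computes

For each tissue comparison *B vs A* (e.g. meninges vs blood):

- **Filtering / normalization** — sgRNAs with < 50 counts in more than two
  replicates of a tissue are discarded; size factors are median-of-ratios
  against a per-sgRNA geometric-mean pseudo-reference restricted to sgRNAs
  with all counts ≥ 50.
- **Per-sgRNA test** — lfc = log₂((mean_B + 1)/(mean_A + 1)); one-sided
  depletion/enrichment p-values from a negative-binomial tail whose
  variance comes from a log-log mean–variance fit on the non-targeting
  (NT) guides.
- **Gene aggregation (α-RRA)** — for a gene with sorted member rank
  percentiles r₍₁₎ ≤ … ≤ r₍ₙ₎, members with percentile > α = 0.25 are
  non-informative; βₖ = P[Binomial(n, r₍ₖ₎) ≥ k]; the gene score
  ρ = minₖ βₖ over informative k, with a permutation p-value against
  random same-size sgRNA sets and a `goodsgrna` count of supporting
  guides.
- **NT resampling null** — 800 pseudo-genes of 4 NT guides drawn with
  replacement; the pseudo-gene lfc standard deviation σ_NT calibrates the
  effect-size threshold.
- **Essentiality calls** — facilitator iff lfc < −3·σ_NT, goodsgrna ≥ 3
  and p < 0.05 (brakes mirrored), with an aggregate flag requiring support
  in ≥ 3 tissue comparisons.
- **Flow co-transfer statistics** — per-animal (KO/control)_tissue ÷
  (KO/control)_blood ratios, < 100-cell exclusions, Shapiro–Wilk-gated
  one-sample t / Wilcoxon tests against 1, and two-stage
  Benjamini–Krieger–Yekutieli FDR adjustment.
- **TCR clonal overlap** — cells whose CDR3β clonotype appears in both
  blood and CSF of the same participant are *overlapping*; per-cluster
  overlap percentage (CNS migration propensity) is Pearson-correlated with
  regulator expression.

## Worked example

`examples/simulate_and_call.py` simulates a 400-gene screen with 15
planted facilitators and 10 brakes, then runs the full chain:

```
simulated 1800 sgRNAs x 12 samples
low-count filter dropped 0 sgRNAs
meninges:blood: NT pseudo-gene null sd = 0.074 (effect threshold |lfc| > 0.222)
parenchyma:blood: NT pseudo-gene null sd = 0.069 (effect threshold |lfc| > 0.208)
called 15 facilitators (15 of 15 planted recovered)
called 10 brakes (10 of 10 planted recovered)
```

The NT null sd lines give the empirical noise scale of a "gene" made of
four control guides; a real gene must move more than three of those
standard deviations (and pass the goodsgrna and p-value criteria in both
CNS-versus-blood comparisons) to be called. The other example scripts
cover design arithmetic (`plan_screen.py`), flow ratios
(`flow_ratios.py`) and clonal overlap (`tcr_overlap.py`).

A thin CLI wraps the same functions:

```bash
cns-screen plan-coverage --library-size 12000 --coverage 1000
cns-screen simulate screen --seed 3 --out sim/
cns-screen run --counts sim/counts.tsv --meta sim/meta.tsv --seed 4 --out run/
```

## Layout

- `src/cnscreen/library.py` — sgRNA manifests, coverage/MOI arithmetic
- `src/cnscreen/counts_io.py` — count/metadata TSV I/O, FASTQ guide counting
- `src/cnscreen/screen_stats.py` — filtering, normalization, NB test, α-RRA, NT null
- `src/cnscreen/hit_selection.py` — candidate tiers, facilitator/brake calls
- `src/cnscreen/migration_stats.py` — flow ratios, location tests, BKY FDR
- `src/cnscreen/clonal_overlap.py` — TCR overlap, propensity correlations
- `src/cnscreen/simulate.py` — screen/flow/clone generators with ground truth
- `src/cnscreen/pipeline.py`, `cli.py` — orchestration and the `cns-screen` CLI

See `docs/methods.md` for the statistical model, its assumptions and the
numerical choices.
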