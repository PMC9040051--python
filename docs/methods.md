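# Methods

## Substitution model

All codon-level machinery uses an MG94-style model on the 61 sense codons
of the standard genetic code.  Only single-nucleotide changes have nonzero
rate; a change is weighted by κ when it is a transition (A↔G, C↔T), by the
branch-specific ω when it is nonsynonymous, and by the stationary
frequency of the target nucleotide at the changed codon position.  Codon
frequencies are the F3x4 product form (per-position nucleotide frequencies
multiplied and renormalized over sense codons), which makes the chain
time-reversible; transition matrices are computed by a symmetric
eigendecomposition of the π-similarity transform.  Each branch's generator
is scaled so that branch length t is the expected number of codon
substitutions per codon site *under that branch's ω*.

Per-branch dN and dS follow the flow-decomposition convention:
dN = t·ρN/(3 fN) and dS = t·ρS/(3 fS), where ρN, ρS are the proportions of
stationary substitution flow through nonsynonymous and synonymous changes
under the branch ω, and fN, fS the same proportions at ω = 1 (mutational
opportunity).  Under this convention dN/dS equals the branch ω exactly, so
simulated "truth" and fitted estimates are directly comparable.

There is no among-site rate variation (the analysis the pipeline
reproduces fixed the gamma shape machinery off), no site or branch-site
models, and no model selection.

Codons containing `-` or `N` are missing data everywhere: they contribute
a vector of ones to the pruning likelihood, are skipped in NG86 counting
and in autapomorphy scanning.  Terminal stop codons are stripped on load;
internal stops are errors.

## Likelihood engine and optimizer

The quintet topology is fixed:
(((poly_pat, dip_pat), (poly_mat, dip_mat)), outgroup), seven branches,
each with its own (t, ω), plus a shared κ — the free-ratio branch model.
Site patterns are compressed; the five-taxon pruning reduces to two 61×61
matrix products per likelihood evaluation, and the conditional likelihood
of a single branch (others fixed) reduces to a per-pattern contraction
that is much cheaper for terminal branches than full evaluations.

Optimization is coordinate-wise: repeated sweeps over branches, each
branch maximized by alternating bounded Brent line searches in log t and
log ω (the t-phase reuses one eigendecomposition; ω is quantized to four
significant digits for eigendecomposition caching), followed by a bounded
Brent search in log κ.  Starts are κ = 2, ω = 0.4 (with seeded lognormal
jitter for additional starts); the best log-likelihood wins, ties within
1e-6 going to the earliest start.  Bounds: t ∈ [1e-9, 30],
ω ∈ [1e-4, 50]; a branch fitted at the ω cap is flagged `at_cap`, and a
branch with t below 1e-7 is reported as zero length with ω undefined
(`undefined` flag), as is any branch whose synonymous length is
numerically zero.  Convergence tolerance is 1e-4 log-likelihood units per
round, up to four rounds; on 2,000-codon simulated quintets this recovers
κ and per-branch ω with no measurable optimizer noise (independent starts
agree to ~3 decimal places in log ω).

Initial branch lengths come from per-tip codon mismatch fractions — a
cheap distance heuristic that only serves as a starting point.

Marginal ancestral reconstruction computes, under the fitted model, the
posterior codon distribution at the three internal nodes by the standard
rerooting messages; the maximum-posterior codon is reported with its
probability, ties broken toward the lexicographically smallest codon.

The NG86-style pairwise counter (equal-path averaging over mutational
paths, stop-avoiding, Jukes–Cantor corrected, saturation flagged at
p ≥ 3/4) is deliberately independent of the ML engine and serves as its
cross-check oracle in the tests.

## Bootstrap machinery

Category concatenations record gene-block boundaries.  The gene bootstrap
resamples whole gene blocks with replacement — implemented as reweighting
of the shared site-pattern table, which is exactly equivalent to refitting
the resampled alignment (verified in tests) — and refits the model per
replicate.  Two replicate-refit modes exist:

- `refit`: full warm-started optimizer runs (κ fixed at the point
  estimate, one sweep), repeated `optimizer_replicates` times with
  jittered starts and summarized by per-branch lower medians;
- `profile`: because per-pattern site likelihoods do not depend on the
  bootstrap weights, each terminal branch's conditional log-likelihood
  (other branches at the point estimate) is precomputed on a 33×17
  log-spaced (ω, t) grid; a replicate then reduces to weighted sums over
  the grid plus parabolic refinement of log ω.  This approximates one warm
  coordinate update and matches `refit` replicate-for-replicate
  (correlation > 0.99, no detectable bias in the log-ratio) at a small
  fraction of the cost; the large simulation studies use it.

The codon bootstrap resamples codon columns instead and exists for
categories with too few genes for block resampling.

Two-tailed p-values are read directly from the bootstrap distribution:
p = 2·min(frac ≤ ref, frac ≥ ref), capped at 1 and floored at 2/B, the
resolution of a B-replicate bootstrap.  Percentile 95% intervals
accompany every distribution.  All resampling is reproducible
bit-for-bit from (inputs, seed, B).

### Background normalization

Category ω_PAT/ω_MAT ratios are normalized by the NOT (non-organelle-
targeted) background ratio.  Two forms are provided:

- **point normalization** (default in the staged pipeline): every
  replicate is divided by the NOT point estimate.  This matches the
  source workflow and is appropriate when the background concatenation is
  genome-scale, so its own uncertainty is negligible;
- **paired normalization**: category replicate i is divided by background
  replicate i, propagating the background's uncertainty into the
  normalized distribution.  At desk-scale background sizes (tens of
  genes) point normalization measurably inflates the type-I error of the
  two-tailed test, so the simulation studies and calibration experiments
  use the paired form.

Medians are lower medians throughout, for determinism.

## Synthetic data

The generator produces data with the statistical structure the analysis
assumes, under the same model family the engine fits, so parameter
recovery is well-posed:

- **Quintet alignments**: root codon from the stationary distribution,
  each branch evolved by its transition matrix.  Defaults — t = 0.2
  substitutions/codon per branch, κ = 2, ω = 0.2, uniform position
  frequencies, 500 codons — reflect moderately diverged angiosperm
  quintets (tree-wide dS ≈ 1, genome-wide ω near 0.2) while staying well
  below synonymous saturation.
- **Gene-tree sets**: species topology with, at stated rates, one diploid
  tip swapped with the opposite-subgenome polyploid tip (mimicking
  homoeologous exchange), paralog tips, and bootstrap supports ≤ 50 on one
  internal split; supports are otherwise 80–100.
- **Classification tables**: per-gene true tier drawn from supplied
  proportions; each focal gene shares an orthogroup with one reference
  gene annotated to match, predictor votes consistent with targeting
  (wiped with the stated predictor error rate), dual targeting at the
  stated rate.  With zero predictor error the classification rule recovers
  every tier exactly, by construction.
- **Gene content**: each ancestral gene loses each homoeolog
  independently with per-subgenome, per-category probabilities; diploid
  models retain everything.

What the generator does **not** emulate: indels and alignment error
(inputs are assumed aligned and trimmed), among-site rate variation,
selection heterogeneity along genes, synteny-block structure (syntenic
quintet lists are generated directly as tables), GC/codon-usage skew
beyond F3x4, and misannotation.  Passing tests therefore demonstrate
correctness and calibration of the statistical machinery under the
model's assumptions, not robustness to real-data artifacts such as
misalignment — which, in the real workflow, the dS filter and manual
trimming address.

## Simulation-study settings

Validation experiments run at desk scale, sized for a single CPU:

- **Parameter recovery**: 40 genes × 1,000 codons (t = 0.2, ω = 0.2,
  κ = 2); median fitted per-branch ω within 25% of truth and κ ∈
  [1.5, 2.6] for ≥ 90% of genes.
- **Null calibration**: 100 datasets, each 50 category + 50 background
  genes × 40 codons, all branches ω = 0.3, B = 100 gene-block bootstrap,
  paired normalization; rejection at α = 0.05 expected in 5% ± 3% of
  datasets.  Block sizes below ~30 codons make the block bootstrap
  underestimate the sampling variance of the ω ratio (observed directly
  in development), so 40-codon blocks and ≥ 50 blocks per side are the
  smallest configuration at which the percentile test is calibrated.
- **Directional power**: 25 datasets with ω_PAT = 0.6 vs ω_MAT = 0.2 in
  the category against an unbiased ω = 0.2 background; detection
  (normalized ratio > 1, p < 0.05) expected in ≥ 80% of datasets.

`scripts/acceptance.py` re-runs the same experiments at slightly reduced
replicate counts and also recomputes the exact content-bias statistics
from published per-subgenome gene counts.

## Statistical conventions

- Exact binomial tests and Clopper–Pearson intervals via scipy
  (`binomtest`, `proportion_ci(method="exact")`); content-bias delta
  Δ = (n_PAT − n_MAT)/(n_PAT + n_MAT) with the CI transformed from the
  paternal proportion by 2p − 1.
- Fisher's exact test (two-sided, conditional odds ratio) for
  autapomorphy bias and for the exact two-proportion comparison of a
  category's content bias against the background; a zero margin makes the
  test undefined rather than an error.
- Pearson χ² without continuity correction for retention contrasts
  (sample sizes in the intended use are large); expected cells below 1
  are flagged.
- Sign tests exclude ties and undefined values from the binomial count
  but report them; proportions p_PAT, p_MAT use all genes in the
  denominator.
- Divergence binning splits genes at the median diploid–diploid dN,
  median gene to the low bin.

## Design choices in open territory

- The dS quality cutoff is inclusive (a quintet exactly at the cutoff is
  kept), and is a per-dataset setting.
- Missing bootstrap supports are treated as support 100: only measured
  low support is evidence against a split.
- Topology concordance is assessed on the tree rooted at the outgroup
  with a three-way verdict: concordant (both species-tree cherries
  resolved), discordant (any conflicting resolved clade), unresolved
  (polytomies prevent both).  Unresolved quintets are excluded along with
  discordant ones.
- Quintet identity for merging phylogenetic and syntenic sets is the
  unordered five-member id set.
- The autapomorphy rule takes derived polarity from the reconstructed
  parent node and requires the parent state to equal the residue shared
  by the other four tips — the stricter reading; sites with any gap or
  ambiguity are skipped entirely.
- The default exchange matrix is a synthetic physicochemical-class matrix
  (replacements crossing charge/polarity/special classes score 1, within
  class 0) intended for tests and examples; curated indices load from a
  20×20 TSV.
- Curvature-based standard errors are not computed; inference rests on
  the bootstrap.

## Known limitations

- The ML engine is specialized to the 5-taxon quintet topology; it is not
  a general phylogenetic likelihood library.
- The profile bootstrap conditions non-focal branches on the point
  estimate; with strongly correlated branch parameters (e.g. saturated
  data) the refit mode is the safer choice.
- ω on near-zero-dS branches is intrinsically unstable; such branches are
  flagged rather than silently dropped, and the ω cap (50) bounds runaway
  estimates.
- Exact binomial CIs are conservative by construction; coverage slightly
  above 95% is expected and tested for.
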