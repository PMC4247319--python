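# Methods

## Model and procedure

The pipeline treats differential expression between two tumor grades as a
supervised projection problem. The predictor block is the samples ×
features matrix of quantile-normalized log2 intensities; the response is
the grade label coded 0/1 (lexicographically first level → 0) and
mean-centered. VIP scores are invariant to any affine recoding of this
choice, which the tests assert, so the coding carries no arbitrary
influence on results.

**Quantile normalization.** Every sample column is replaced by the
cross-sample means of the order statistics at its ranks, so all columns
share one empirical distribution afterwards and within-column ranks are
preserved. Within-column ties receive the mean of the reference values at
the tied rank positions — a deliberate trade: tied values stay tied, at the
cost of the "identical sorted columns" property holding exactly only for
tie-free columns. Missing values are rejected at load rather than imputed,
because silent imputation would perturb VIP ranks invisibly. Probe-level
summarization and background correction are upstream of this package; a
provenance flag records whether the input was declared background-corrected
but never changes computation.

**NIPALS PLS.** With a univariate response the NIPALS inner iteration
converges in a single pass, so each component is computed in closed form
(weights ∝ deflated-X-response covariance, normalized; scores, loadings and
deflation as usual). A component whose covariance norm falls below
`tol × ‖X₁ᵀy₁‖` (tol = 1e-12) terminates extraction; the effective number
of components is recorded and may be smaller than requested. Features are
centered but not variance-scaled by default: the matrix is already
quantile-normalized onto a common scale, and scaling is exposed as an
option rather than silently applied. The default of **2 components** keeps
the dominant class-separation axis plus one correction axis while keeping
the permutation loop cheap; it is configurable, and the early-termination
rule protects degenerate designs.

**Pooled permutation FDR.** The null model shuffles class labels over
samples — targeting exactly "no association between expression and grade"
— refits the PLS model with the same requested component count, and pools
all p VIP values from each of B permutations into a single empirical null.
Pooling gives B·p-value resolution at modest B. The plug-in estimate
`FDR(v) = [#null ≥ v / B] / max(1, #obs ≥ v)` (ties counted with ≥) is
capped at 1 and monotonized step-up so FDR is non-increasing in VIP, which
makes thresholding coherent. Permutations in which no component survives
(zero explained response variance) contribute zero VIPs and are counted in
diagnostics rather than dropped, keeping the null size at exactly B·p.

Two properties of this estimator matter for interpretation. First, it
*controls* rather than unbiasedly estimates the FDR: under a global null
the observed and null VIPs are exchangeable, the estimate hovers near 1,
and essentially nothing is called significant — conservative, as a
screening rule should be. Second, when a large fraction of features carries
true signal, those features inflate the pooled null (their permuted
covariances are larger), costing power. This dilution is why the synthetic
study keeps true signals sparse (~4% of features, below).

**Survival screen.** Per selected feature, samples split into low/high
strata by k-means with k = 2 in one dimension. The optimum of 1-D 2-means
is always a contiguous split of the sorted values, so it is found exactly
by scanning the n − 1 thresholds — removing the initialization randomness
of iterative k-means entirely; boundary ties go to the lower cluster.
Strata are compared with the standard two-group log-rank chi-square (1 df,
chi-square approximation; lifelines implementation, validated in tests
against a hand-tabulated O−E computation). Raw p < 0.05 flags significance,
matching the screen design; an informational Benjamini–Hochberg column is
emitted because the per-feature screens are multiple tests, but it does not
drive the flag. Per-feature failures (constant expression, degenerate
statistic) are recorded in the output table, never fatal.

**Target network.** Prediction lists from multiple algorithms are consumed
as input files (the algorithms themselves are out of scope). Pairs
supported by ≥ 2 distinct methods survive; their genes are then filtered
against the gene-level differential-expression call, which reuses the
identical PLS/VIP/permutation machinery on the gene matrix rather than
substituting a t-test — the same selection procedure applied to a second
data shape. Identifier matching is exact string after case normalization;
alias resolution is dataset plumbing out of scope. Gene–gene interaction
edges may be supplied in an optional file; they carry a distinct relation
attribute and are excluded from bipartite degree bookkeeping.

**Enrichment.** Hypergeometric upper tail via scipy's log-space survival
function. The universe defaults to the annotation universe intersected with
the assayed gene matrix — the least surprising choice, and logged, since
p-values depend on it. Raw p-values at 0.05 mirror the screening style of
the analysis; BH-adjusted values ride along informationally. Terms are
tested only at overlap ≥ 1 (k = 0 rows carry p = 1 and are noise). Flat
sets only: no ontology-graph propagation.

## Synthetic study conditions

The generator emulates the cohort structure the analysis assumes, with one
RNG sub-stream per stage (master seed + stage name), so stages regenerate
independently and a fixed configuration yields byte-identical files.

| parameter | default | rationale |
|---|---|---|
| cohort | 24 + 50 samples | the two-grade design the pipeline targets |
| miRNA features / spiked | 500 / 20 | sparse signal (4%), desk-scale p |
| effect size | 1.5 × noise_sd | detectable but not trivial at n = 74 (two-sample z ≈ 6) |
| noise_sd, baseline | 1.0, 8.0 log2 units | typical microarray intensity scale |
| baseline hazard / ratio | 0.05 / 4.0 | median survival ≈ 14 time units in the low stratum, clear but finite separation |
| censor rate | 0.01 | light independent censoring (~10% censored) |
| gene features | 300 | smaller second matrix exercising the same machinery |
| targets per miRNA / shared fraction | 5 / 0.5 | keeps the supported target set, and hence true gene-level signal, sparse |
| gene DE fraction | 0.3 of supported targets | ≈ 13 true DE genes (~4% of the gene universe) |
| planted term | 12 members, 10 from DE targets | strongly enriched against N = 300 |

Spike signs alternate (+, −, +, ...) so both over- and under-expression
occur. Expression is generated directly on the log2 scale (Gaussian), not
as lognormal raw intensities — the analysis consumes log2 values, so the
extra layer would add nothing testable. The gene-layer sparsity numbers
follow from the pooled-null dilution noted above: with the gene universe
fixed at 300, a dense DE fraction (tens of percent) inflates the permuted
VIP null enough that a calibrated screen correctly reports near-zero
discoveries; ~4% true signal is both the realistic regime for this
estimator and consistent with the miRNA layer. Survival hazard follows the
high/low stratum of the *first* spiked feature only; all other features are
prognostically null.

What the generator does **not** emulate: correlated gene blocks, batch or
array effects, intensity-dependent variance, probe-level effects, and
informative censoring. Passing tests therefore demonstrate correctness of
the machinery under the stated model, not robustness to those real-data
phenomena.

## Numerical and design choices

- Permutation and pipeline stage seeds derive deterministically from one
  master seed (SeedSequence keyed by stage name, CRC32 of the name); all
  derived integer seeds stay below 2³¹.
- Tail counts in the FDR use `searchsorted` on sorted arrays: O((B·p) log)
  and exactly reproducible.
- The default study size (B = 500, p = 500 + 300, 74 samples) runs the full
  pipeline in a few seconds on one CPU; B = 10,000 remains the
  production-scale default of the standalone `select` command.
- `significant` is the strict rule FDR < threshold everywhere, so a
  threshold of 1.0 excludes features pinned at the cap — the flag and the
  filter can never disagree.
- The 2-means scan breaks WCSS ties toward the smaller low-cluster;
  equal-valued samples never straddle the boundary.
- Stage resume compares a SHA-1 hash of the analysis-relevant configuration
  (output directory excluded); any config change invalidates downstream
  stage markers.

## Known limitations

- No cross-validated choice of the component count; sensitivity to A is
  exposed as an option, not automated.
- The pooled null assumes features are comparable after normalization; a
  per-feature null would be B times more expensive at the same resolution.
- The log-rank p uses the chi-square approximation; small-stratum exact
  permutation p-values are not implemented.
- Quantile normalization's exact common-distribution guarantee degrades
  (by design) in the presence of within-column ties.
- No quality-control filter is applied before normalization; inputs are
  assumed already curated.
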