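# Methods

This note documents the models, estimation procedures, numerical choices
and known limitations of `pregmeth`. Everything quantitative stated here is
computed by the test suite (`tests/`) or by `scripts/acceptance.py`.

## Synthetic data model

The generator emulates the statistical structure of a 450K-style
methylation study of sorted CD4+ T cells.

**Cell-type methylomes.** Each probe's baseline beta is drawn from a
3-state mixture — unmethylated `Beta(5, 45)`, hemimethylated `Beta(10, 10)`,
methylated `Beta(45, 5)` with weights (0.45, 0.10, 0.45) — reproducing the
bimodal marginal distribution of real beta values. A configurable fraction
(default 0.30) of probes is cell-type specific: the non-reference cell
types are shifted by 0.3–0.9 (clipped to [0.01, 0.99], realized gap always
≥ 0.2, bookkept in the ground truth). The large shifts mirror the fact that
cell-type-discriminating CpGs often switch nearly fully between states;
they are also what makes the factorization identifiable (below).

**Samples.** Sample `j` in group `g` draws mixing proportions
`ω_j ~ Dirichlet(c · π_g)` with concentration `c = 6` and group means
`π` = (0.60, 0.40) / (0.55, 0.45) / (0.45, 0.55) for the non-pregnant /
first- / second-trimester groups of the default 12/11/12 design — the
memory-cell fraction rises through pregnancy, and individual variation is
wide (inter-individual memory fractions spanning roughly 0.1–0.9). The
observed beta is `Beta(μν, (1−μ)ν)` around the mixture mean `μ = Mu ω_j`,
with concentration `ν = 100` (SD ≈ 0.05 at mid-range betas, a few percent
near the boundaries — the order of within-group variability of normalized
array betas). `ν = ∞` is the exact noiseless limit. The paper-style cohort
does not state these variances; both are documented calibrations, fixed
before the verification studies and not revisited.

**Planted effects.** Group effects (default: 100 probes in the
second-trimester group, |Δβ| ~ U(0.05, 0.15), two-thirds hypermethylated)
are planted only on probes whose baseline is *shared* across cell types;
on cell-type-specific probes the group shift in mixing proportions would
add its own mean difference and the recorded Δβ would no longer equal the
generating-mean difference (a ground-truth invariant). The shift is applied
on the logit scale with the offset that moves the reference-group mean by
exactly the planted Δβ; probes without headroom get the opposite sign.
Effect probes concentrate on a designated set of effect genes (default 40)
so the network stage has a recoverable target.

**QC artifacts** are planted as disjoint probe sets per filter at
configurable rates (defaults between 0.1% and 2%, echoing the relative
magnitudes of real 450K filtering), so the filter report can be checked
against the generator's bookkeeping exactly.

**Network.** A scale-free background is grown by preferential attachment
from an (m+1)-clique seed (m = 2), giving exactly `m(n−m−1) + m(m+1)/2`
edges; node identities are a random permutation of the gene universe so
attachment order and gene identity are decoupled. The planted module is a
clique (default 8 genes) placed on effect genes, its edges scored 990 over
a 900–960 background. The 8-gene default puts the module's CpG overlap with
a disease's DMPs at roughly 10–25 CpGs, proportionally comparable to the
overlaps a full-size study reports.

**Disease cohorts** (default 15 cases / 10 controls) share the pregnancy
cohort's methylomes. Case effects sit on the pregnancy effect probes with
generating-mean differences exactly `effect_sign × scale` times the
pregnancy differences; `floor(overlap_fraction · n_controls)` controls
(default 3) receive case-like profiles and are listed in the ground truth.

What the generator does **not** emulate: batch/chip-position effects, probe
cross-reactivity beyond a flag, spatial correlation along the genome,
age/sex covariates, and realistic LD between SNP-affected probes. Passing
tests therefore demonstrate correctness of the inference machinery under
the stated generative assumptions, not robustness to these real-data
complications.

## Preprocessing

Filters run in a fixed order (detection p, bead count, CpG presence, SNP
proximity, multi-mapping); each filter's removal count is taken among
probes surviving the earlier filters, so counts are disjoint and conserve
the input probe count. A probe fails the detection rule when its worst-case
detection p exceeds 0.01 (per-sample fraction configurable). X-chromosome
probes are retained by default (all-female designs); a switch drops them.
"CpG presence" is carried as a plain annotation flag.

BMIQ-style normalization fits the 3-state beta mixture by EM per sample.
Two stabilizations matter at desk scale (a few thousand probes per sample):
the EM is initialized from a hard state assignment at 0.25/0.75 with
method-of-moments parameters, and each state's mean is projected into its
canonical band (≤ 0.30 / 0.30–0.70 / ≥ 0.70) at every M-step so components
cannot drift into each other's roles. Because the moment-based M-step is
not likelihood-monotone, convergence is judged on state means and weights
(tolerance 1e-4, ≤ 500 iterations); non-convergence warns and uses the last
iterate. The mixture is fitted once on the pooled sample and the per-design-
type parameters are derived from shared state responsibilities, so fits of
type I and type II probes cannot land in different local modes; the
residual same-distribution distortion of the map is below ±0.02. The type
II map quantile-matches the U and M states through the fitted beta CDFs and
linearly dilates the intermediate state into the remaining gap; it is built
on a 2001-point grid with a running maximum, guaranteeing monotonicity and
range [0, 1]. M-values use the base-2 logit with clipping constant
ε = 1e-3; the inverse is exact on [ε, 1−ε].

## Deconvolution

`B ≈ Mu Ωᵀ` is fitted by alternating exactly solved constrained least
squares: Mu rows by active-set enumeration over the 3^K bound patterns of
[0,1]^K (each pattern solved for all probes at once), Ω rows by support
enumeration over the 2^K−1 nonempty supports of the simplex (equality-
constrained KKT systems, batched over samples). Exactness makes the
deviance (residual sum of squares) provably non-increasing; the trace is
recorded and asserted. Five random restarts by default; restart seeds
derive from the master seed; the lowest deviance wins, first-found on ties.

The product `Mu Ωᵀ` only identifies the factors up to an affine
re-parameterization of the mixing simplex (stretching Ω and compressing the
profile contrast leaves the fit unchanged). The returned representation is
therefore canonicalized by pushing each profile vertex away from the
centroid of the others until the [0,1] bounds on Mu bind — the maximum-
volume simplex inscribed in the feasible box, which is the biologically
meaningful representation when cell-type-specific CpGs approach full
methylation contrast. The reconstruction is preserved exactly. With the
default generator this recovers planted proportions to MAE ≈ 0.02 (and to
±0.02 per entry in the noiseless limit).

K is selected by the variance (optionally mean) of the bootstrapped
deviance: samples are resampled with replacement (probes fixed) and the
model is refitted cold from a random start per bootstrap. Under- and
over-parameterized models are unstable across resamples; the true K gives
the most stable deviance. On pure two-type cohorts the procedure selects
K = 2 in ≥ 9/10 seeds. A caveat observed at desk scale: when planted group
effects occupy a non-negligible probe fraction (5% of 2 000 probes in the
analysis drivers) they form a weak genuine third component and K = 3 may
win; the adjustment columns remain valid covariates either way, and at
realistic probe counts (hundreds of effect probes among 450 000) the effect
block is invisible to K selection.

## Differential methylation

Ordinary least squares per probe on M-values with intercept, group
indicators (reference group absorbed) and K−1 omega columns (the full
simplex block plus intercept is collinear; the dropped column is
configurable). Despite the mixed-model vocabulary sometimes attached to
this formula, it contains no random effects and is fitted as fixed-effects
OLS, with a plain-OLS switch. Residual variances are moderated following
the standard empirical-Bayes scheme: `post s² = (d₀s₀² + d·s²)/(d₀+d)`,
with d₀ from inverting the trigamma identity on `var(log s²)` and s₀² from
the corrected mean of `log s²`; moderated t on d₀+d degrees of freedom.
When the dispersion of `log s²` does not exceed sampling noise, d₀ = ∞ and
s₀² is taken as the geometric mean of the s², which makes moderation an
exact no-op for a constant variance vector (a deliberate deviation from
the textbook bias-corrected intercept, chosen so the degenerate case
collapses to the ordinary t). Zero residual variance with a nonzero effect
yields t = ±∞, p = 0.

Δβ is the difference of raw group-mean betas on the normalized matrix,
deliberately unadjusted. DMP: `q < 0.05` and `|Δβ| > 0.05`, both strict.
DMG: majority direction of member DMPs, ties broken by the smallest-q DMP
(the source description of the tie-break is self-contradictory;
smallest-q is this package's documented rule); multi-gene probes count for
every mapped gene. MDS is classical Torgerson scaling on the 1 000 most
variable probes; variance explained is the eigenvalue share among positive
eigenvalues.

Calibration (asserted): on null cohorts raw p-values are KS-uniform and
the joint criterion calls ~0 DMPs; planted |Δβ| = 0.10 effects are
recovered at ≈ 90% sensitivity at n = 12/group through the full
filter→BMIQ→deconvolution→model chain.

## Network module

Distance between genes is shortest-path length in edges (adjacent genes
d = 1, so a clique attains the harmonic-average minimum H = 1); the
intermediate-node reading would shift every distance by one and is not
used. Unreachable pairs contribute 0 to the reciprocal sum. The
co-localization null resamples uniformly random node sets of equal size
(not degree-matched), and the permutation p uses the plus-one rule. The
permutation machinery precomputes one BFS per node and reuses the table.

MCODE follows the vertex-weighting/complex-growth scheme: weight = (max
core number of the open neighbourhood) × (density of that k-core); growth
admits neighbours with weight ≥ (1−vwp)·seed-vertex weight (vwp = 0.2);
haircut on (iterative 2-core), fluff off; complexes scored density × size;
the module is the union of seed-containing complexes passing the cutoff.
DIAMOnD adds, per round, the candidate with the smallest hypergeometric
tail P(X ≥ k_s); p-values equal up to 1e-9 relative are treated as ties and
resolved by more member links, then lower degree, then id — so the ranking
does not depend on which evaluation route produced the p. Clique Sum keeps
maximal cliques (size ≥ 3) whose seed content passes a one-sided Fisher
test at Bonferroni-corrected α = 0.05 over the tested cliques.
Correlation Clique is a documented reconstruction (its published internals
are not restated in the source material): per iteration each edge survives
with probability `(score/1000) × mean(endpoint factors)` (seed factors from
supplied weights, non-seeds at a configurable baseline of 1.0), seed-
enriched maximal cliques of the sampled graph mark their genes present, and
the module is the genes present in ≥ 50% of iterations. All four detectors
run on the full network with seed genes by default (an induced-subgraph
mode exists). Consensus: membership in ≥ 3 of the 4.

The harmonic distance, DIAMOnD ranking, maximal-clique enumeration and
Fisher FE/p are each verified against independent brute-force oracles
(queue BFS, log-factorial hypergeometric recomputation, bitmask subset
checking, log-factorial tail enumeration) with exact agreement.

## Disease relevance

The divisive subgroup selection is a greedy surrogate for the published
divisive shuffling approach, whose internals the source material does not
restate: repeatedly evaluate removing each removable sample (controls only
by default, matching a design in which only control counts shrank) and
accept the removal that most increases the separation score between the
retained groups. Two choices make the greedy search reliable: (i) the
score is the sum of −log10 q over probes passing the joint DMP criterion
(the plain DMP count is available) — removing a contaminated control
strengthens every true DMP multiplicatively while removing a clean sample
costs degrees of freedom, so chance improvements are penalized; and (ii) a
removal must beat the current score by 10% (selection over many candidates
inflates small chance gains). The score is cell-composition adjusted: the
cohort is deconvolved once up front and the omega columns enter every
candidate fit; without this, chance composition imbalance dominates the
count in roughly one cohort in ten. Planted case-like controls are removed
exactly (no more, no fewer) in ≥ 95% of seeds, and cohorts without planted
overlap see near-zero removals.

Enrichment is Fisher's exact test on an explicit background universe
(all measured CpGs, resp. all annotated genes), with fold enrichment
`FE = (a/(a+b)) / ((a+c)/N)`; the background is always carried in the
result because FE depends on it. A vectorized margin-scan route computes
all overlaps of one margin configuration at once. Directionality is the
Pearson (t-based p) and Spearman correlation of the paired pregnancy and
disease effect vectors on the overlapping CpGs; the verdict is the sign of
the Pearson r. End-to-end, planted disease signs (−1, −1, +1) are recovered
with p < 0.05 in ≥ 95% of seeds — the synthetic analogue of two diseases
that improve and one that worsens during pregnancy.

## Orchestration and determinism

All randomness flows from one master seed through numpy seed spawning;
stage seeds are derived, and two runs of the pipeline with the same config
produce byte-identical summary JSON. Every threshold lives in
`PipelineConfig` (YAML-loadable); the run directory contains every
intermediate table, a manifest (version, seed, parameter hash) and a
summary JSON. The CLI (`pregmeth simulate/preprocess/deconvolve/dmp/module/
disease/run-all`) is a thin layer over the library; the numbered
`analysis/` drivers are the narrative equivalent.

## Problem sizes

The verification studies run at desk scale: cohorts of 700–4 000 probes and
the 12/11/12 (or 12/12) sample design, networks of 120–300 nodes, 20-seed
replication for the stochastic recovery claims, and exhaustive Fisher
verification over all ~6.3×10⁵ tables with N ≤ 60. These sizes were chosen
so each study isolates one inferential property cleanly; none of the
full-size study's real-data numbers (module sizes, fold enrichments,
correlations) are targets, since they depend on cohorts this package does
not ship.

## Known limitations

- The Correlation Clique scoring is a parameterized reconstruction; its
  constants are config, not literature values.
- The subgroup-selection surrogate is greedy and one-sample-at-a-time; it
  cannot undo a removal, and its guarantees are empirical, not worst-case.
- BMIQ at a few thousand probes per sample carries sampling noise of the
  mixture fits into the normalized betas (~0.01–0.02 typical shift);
  at full array scale this vanishes.
- The deconvolution's simplex anchoring assumes some cell-type-specific
  CpGs approach full contrast; with uniformly weak contrast the affine
  ridge re-appears and proportions are recovered only up to that
  re-parameterization.
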