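# Methods

## Model

A simple lattice accommodates t = k² lines in incomplete blocks of size k
with r = 2 replications whose blockings are mutually orthogonal, so any
two lines share a block at most once.  The plot-level model is

    y_ijk = μ + α_i + γ_j(i) + g_k + ε_ijk ,

with fixed replication effects α, random block-within-replication effects
γ ~ N(0, σ_b²) and residuals ε ~ N(0, σ²).  For QTL testing the line value
g_k is decomposed into the tested locus b*x*ₖ plus p background covariate
markers (composite interval mapping).  Writing δ = σ_b²/σ², the residual
covariance is σ²Σ with Σ = I + δZZ′, block-diagonal over field blocks, and

    (I_k + δJ_k)^(−1/2) = I_k + [(1+kδ)^(−1/2) − 1]/k · J_k

whitens each block in O(k) per column.  After whitening, every genome
position is tested by ordinary least squares and scored with
LOD = (n/2)log₁₀(RSS₀/RSS₁), n = t·r.  The two mean-based comparators use
the same scan on t line values: arithmetic means (`rcbd`) and GLS-adjusted
lattice means (`amld`; minimum-norm solve of the whitened replication+line
model, which recovers inter-block information and reduces to arithmetic
means at δ̂ = 0).

### Variance components

σ̂² is the intra-block residual mean square of the fixed
replication+line+block fit.  σ̂_b² equates the treatment-adjusted block sum
of squares to its expectation: with X the fixed design and P the relevant
projectors, E[SS_block|lines] = df_b σ² + tr(Z′(P_full − P_X)Z) σ_b²; the
moment estimate is truncated at zero, where the whitening degrades
gracefully to the identity.  Both are exact-projection computations (QR),
no iterative fitting.

### Genotype imputation

Scan positions between markers have unobserved genotypes.  A RIL genome is
a two-state Markov chain along each chromosome with switch probability
R = 2r/(1+2r), r = Haldane(d); D complete imputations are drawn per line by
forward filtering / backward sampling conditional on all observed markers
(missing marker genotypes are handled by the same pass).  Per-position LOD
scores are averaged over the D draws; with fully observed markers every
draw reproduces the data at marker columns.  Defaults D = 16 and a 2 cM
grid balance Monte-Carlo error in the averaged LOD (< 0.2 LOD at peaks
versus D = 64 on the study scenario) against runtime; both are exposed.

### Covariate selection, window, and two-pass calling

Covariates are chosen per method on its own response representation by
forward stepwise least squares (p = 3 by default, genome-order
tie-breaking); during the scan, covariates within 10 cM of the test
position are dropped from both null and alternative models so the contrast
isolates the tested locus.

Single-pass CIM profiles carry two well-known artifacts: a selected
covariate sitting 10–15 cM off a QTL absorbs its signal and the exclusion
window re-exposes it clipped at the window edge, and a covariate selected
midway between two linked same-sign QTLs produces a plateau "ghost" peak.
Both displace peaks by 10–20 cM.  Calling is therefore two-pass: pass 1
scans with stepwise covariates and extracts greedy peaks (LOD > 2.5); pass
2 re-scans with covariates placed at the markers nearest those peaks and
re-extracts calls — one iteration of standard multiple-QTL refinement.
Candidate peaks must additionally be local maxima of the profile within
±min_sep (10 cM) on their chromosome, so monotone shoulders of a taller
peak are never reported as separate QTLs.  Support intervals are the
contiguous region within 1.5 LOD of the peak.

### Thresholds

Fixed rule: LOD > 2.5.  Permutation rule: the scan (including covariate
re-selection) is repeated over shuffled data and the threshold is the
⌈(1−α)(N+1)⌉-th order statistic of the genome-wide maxima.  For the
mean-response methods the shuffle acts on lines.  For the plot-level scan
the default exchanges raw plot phenotypes over all plots (the classical
complete-null permutation); `unit="line"` instead shuffles genotype rows
against intact line phenotypes, which preserves any line-level polygenic
background in the null and yields conservative (higher) thresholds — the
principled choice when a strong unmodelled polygenic term is expected, at
a cost in power.  δ̂ is not re-estimated per permutation.

### Multi-environment extension

With s environments as fixed covariates the full model adds the QTL main
effect and its environment interaction; three nested LODs are reported per
position (joint, additive-only, interaction-only; the joint LOD dominates
both by the RSS ordering).  Whitening is applied per environment with that
environment's δ̂.  The interaction columns are implemented for s = 2.

## Simulation design

The generator reproduces the study conditions: 196 RILs on five 150 cM
chromosomes with 16 evenly spaced markers (10 cM); ten QTLs in Zeng's
classic layout (three on each of chromosomes 1–3, one on chromosome 4,
none on 5; effects from +1.61 down to −0.46); 100 polygenes with effects
U(0, 0.1); 14×14 simple lattice, two replications, replication effect 2;
residual variance Var(g)(1/h²−1) with h² = 0.7 computed from the realized
sample variance of the simulated genetic values; block variance σ²δ with
δ ∈ {0.5, 1, 5, 10}; 100 replicates per cell at full scale.

Two generator choices were genuinely open and are fixed as follows.
Polygene placement: all polygene effects are positive, so scattering 100
of them over the five mapped chromosomes turns every chromosome into one
diffuse directional pseudo-QTL — scans then show chromosome-wide gradients,
power collapses and the false-discovery rate explodes for every method,
none of which matches the behaviour the method is known to have on this
design.  Polygenes therefore segregate independently of the mapped genome
by default (independent Bernoulli(1/2) loci, as genes on unmapped
chromosomes would), making the trait polygenic without contaminating the
map; on-map placement remains available (`polygene_placement="genome"`).
Truth matching: a call counts as detecting a QTL (and a QTL as covering a
call) when they are within 10 cM of each other on the same chromosome;
with a 10 cM marker spacing a detected QTL's peak regularly sits at the
neighbouring marker, which a 5 cM radius would misclassify as a false
positive.

What the generator does **not** emulate: genotyping errors, missing
plots, segregation distortion, crossover interference, epistasis, spatial
(row-column or AR1) field trends beyond the block effect, or unequal
line replication (the soybean-style 184-lines-in-196-cells layout).
Passing tests therefore demonstrate correctness of the estimators and the
power ordering under the stated model, not robustness to those features.

## Numerical choices

Positions merge within 1e-9 cM; LOD is clamped at 0 and RSS ratios floored
at 1e-12 of RSS₀; collinear test columns (residual sum of squares below
1e-10 after projection) score LOD 0; stepwise ties break to genome order;
the σ̂_b² moment estimate truncates at 0; adjusted means use the
minimum-norm least-squares solution, whose replication/line indeterminacy
cancels in the reported means.  All randomness flows through
`numpy.random.Generator`; study replicate `rep` of cell `cell` is seeded
`SeedSequence([master, cell, rep])`, making every cell reproducible and
parallel-safe.

## Reduced study scale

The bundled reproduction (`scripts/acceptance.py`, `tests/test_acceptance.py`)
runs 30 replicates per fixed-threshold cell and 25 replicates × 100
permutations per permutation cell, with D = 16 draws on a 2 cM grid.  At
this scale the Monte-Carlo standard error of an overall power estimate is
about 3 percentage points; power checks use ±3 SE bands.

## Known limitations

- The pooled false discovery rate under a fixed LOD 2.5 threshold is a few
  percent, not below 1%: the genome-wide null maximum of the scan exceeds
  2.5 in a sizeable fraction of replicates (the α = 0.05 permutation
  threshold itself is ≈3.1–3.3), so occasional false calls at that
  threshold are a property of the threshold, and are most visible where
  power (hence the call denominator) is low, e.g. the arithmetic-mean
  strategy at δ = 10.  The permutation rule keeps the plot-level scan's
  FDR at ≈1%.
- The plot-level LOD uses n = t·r observations; with a strong unmodelled
  polygenic background the within-line residual correlation makes the
  fixed-threshold scan more liberal than its mean-based counterparts
  (see the permutation-unit discussion above for the conservative
  alternative).
- Missing plots are not supported (complete lattices only); the
  multi-environment interaction scan supports two environments.
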