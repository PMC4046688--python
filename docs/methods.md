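# Methods

## Design and scope

`crossqtl` analyses a two-line backcross: founders from a divergent sire
line ("Iberian") and a dam line ("Landrace"), F1 boars mated back to
Landrace sows, and phenotypes recorded on the backcross (BC) generation
only.  Every BC animal carries one guaranteed Landrace gamete, so the
only hidden genetic quantity is the line origin of the F1-transmitted
gamete along each chromosome.  The package covers the full analysis
chain — line-origin inference, SNP QC, single- and multi-trait mixed
models, linkage and association scans, pleiotropy decision trees,
TAS-region calling, and a targeted eQTL stage — together with a
generator that simulates data under exactly the model the analysis
assumes.

## Line-origin probabilities (`lineorigin`)

The F1 gamete's origin is a two-state Markov process along the
chromosome with transition probabilities from the Haldane map function
`r(d) = (1 − e^(−2d/100))/2` (no crossover interference).  Emissions at
each SNP use line-specific allele frequencies estimated by ML counts
from the F0 genotypes — fixation between lines is *not* assumed, since
causal and marker alleles in real line crosses are rarely fully
divergent.  A small emission slack (default 1e-3, mixed uniformly over
the three genotype states) absorbs genotyping errors.  A
forward–backward pass yields posteriors at the markers; posteriors at
arbitrary grid positions (default 1 cM spacing) combine the flanking
forward and backward messages through the Haldane transitions.  The
additive coefficient is `P_a = Pr(QQ) − Pr(qq)`; for BC animals
`Pr(QQ) = 0`, hence `P_a ∈ [−1, 0]`.

The smoother treats each BC gamete independently; it does not phase the
F1 sires jointly across their half-sib families.  On dense informative
maps the difference is negligible (posterior–truth agreement > 99% in
the recovery suite); on sparse or weakly divergent maps the per-gamete
treatment loses some information.

## Relationship matrices (`pedkin`)

`A` is built by the tabular method in pedigree order; records exist
only for BC animals, and the analyses use the principal submatrix of
`A` over the phenotyped cohort (the exact marginal covariance of their
breeding values).  Multi-trait covariances are `A ⊗ G0` with
individual-major ordering; log-determinants and quadratic forms use the
eigenstructure of the two factors.  A trait covariance that fails PSD
by more than 1e-8 is projected onto the PSD cone with a warning.
Storage is dense throughout — the target scale is a few hundred
animals.

## Mixed-model engine (`mixedlm`)

All fits are full maximum likelihood, not REML.  The scans compare
models that differ in *fixed* effects (QTL and SNP coefficients), and
only ML log-likelihoods are comparable across fixed-effect structures;
the cost is the usual downward bias in variance components at n ≈ 157,
which cancels in the LR differences the pipeline actually interprets.

*Single trait.*  One spectral decomposition of the phenotyped submatrix
of `A` per cohort turns the covariance `σ²_e(λ A + I)` diagonal for
every variance ratio `λ = σ²_u/σ²_e`; fixed effects and `σ²_e` are
profiled in closed form and the fit is a bounded one-dimensional search
over `log λ` (Brent, `xatol` 1e-8, explicit comparison with the λ = 0
boundary).  A vectorized variant runs hundreds of responses sharing one
design in lock-step golden-section iterations; the eQTL stage uses it
to scan all probes simultaneously (agreement with the scalar path is
~1e-13 in log-likelihood).

*Multi trait.*  With complete records the same rotation makes the
covariance block diagonal with k×k blocks `d_i G0 + R0`; `G0` and `R0`
are parameterized by log-Cholesky factors (diagonal bounds e^−8 to e^5)
and optimized by L-BFGS-B with fixed effects profiled by GLS at each
evaluation (closed-form 2×2 inverses on the bivariate path).  Warm
starts propagate along scan positions.  The residual cross-trait
covariance `R0` is estimated, not fixed: both depots are measured on
the same animal, and omitting residual correlation would inflate
pleiotropy evidence.  Records missing one trait of a pair contribute
their observed trait through a dense marginal likelihood over the
observed entries (slower path, verified against
`scipy.stats.multivariate_normal`).

Variance components are re-estimated at every tested position or SNP
(exact scans).  The only fast-mode use — variance components held at
the pleiotropic-peak estimates — is the two-QTL position profiling over
the coarse product grid, and the selected pair is refitted by full ML
before any LR is reported.

## Scans and decisions (`qtlscan`)

Storey q-values use the λ-grid 0.05…0.95 with a cubic-spline smoother
for π₀ evaluated at λ = 0.95; below 100 p-values the conservative
π₀ = 1 fallback applies (every decision-tree gate in the test suite
operates in this regime, where the procedure coincides with the plain
step-up).

Confidence intervals invert the LR profile: the interval covers every
grid position with `LR ≥ LR_max − χ²(level, df)` and places its
endpoints at the first position *below* that threshold on each side
(clipped to the scanned range).  The extension is deliberate: the true
crossing lies between grid points, and this is the standard
conservative convention for profile-LOD support intervals on a discrete
grid.  Naive drop intervals are known to undercover at moderate QTL
effects, which bounds how often an eQTL interval can bracket its target
gene (see "Acceptance behaviour" below).

TAS regions cluster significant SNPs (q < 0.05) with consecutive gaps
below 1.5 cM; a cluster needs at least 3 members and is rejected if
every member pair is in complete LD (dosage r² = 1 within 1e-9, the
strictest reading of "not fully linked").  The decision trees follow
the staged logic: scan gate with multiplicity control, then nominal
0.05 for the within-region contrasts (multiplicity is controlled once,
at the scan step).  The two-QTL versus pleiotropic contrast uses df = 1
(the shared-position constraint); the df = 3 contrast of the two-QTL
model against the no-QTL null is recorded alongside for transparency.

## Targeted eQTL stage (`eqtlscan`)

Probe expression enters the same animal model as the fat traits
(sex, batch, carcass weight, polygenic term).  Scans are restricted to
windows from the pleiotropy stage: cM intervals from pleiotropic QTL
confidence intervals (linkage mode) or SNP sets from pleiotropic TAS
regions (association mode).  Per window and probe the best test is
retained, and discoveries are flagged by the Benjamini–Yekutieli
step-up at FDR 0.20 with thresholds `k·q/(M_eff·c)`,
`c = Σ_{i≤⌈M_eff⌉} 1/i`.

Multiplicity is counted at the effective number of tests on *both*
axes: `M_eff = N_eff(probes) × M_eff(window tests)`, with the
eigenvalue-variance formula `M_eff = 1 + (M−1)(1 − Var(λ)/M)` applied
to the probe correlation matrix and to the window's P_a position
columns (linkage) or SNP dosage columns (association).  Counting grid
positions 1 cM apart at face value would treat ~98%-correlated tests as
independent; the effective count is the principled choice and the one
under which a study-scale discovery (nominal p ≈ 3×10⁻⁵ over a
30-position window and ~207 effective probes) can reach the FDR-0.20
threshold at all.  The probe filter keeps probes with strictly more
than 20% of samples beyond ±1.5-fold of the probe median
(|value − median| > log₂ 1.5 on log₂ data, auto-detected), then
collapses duplicate probes per gene to the highest-mean probe.

## The generator (`simpop`)

The generator realizes exactly the analysis model, so parameter
recovery is a meaningful end-to-end test.  Defaults mirror the
reference design: 3 sire-line boars × 30 dam-line sows, 5 F1 boars ×
25 dam-line sows, 157 BC animals; sex alternates and slaughter batch
rotates over 3 levels (balanced nuisance structure); carcass weight is
standard normal and genetically independent.  Meioses place crossovers
as a Poisson process (intensity 1 per 100 cM, no interference),
matching the Haldane map function used in analysis.  Founder allele
frequencies default to divergent Betas (means 0.8/0.2) — real line
crosses are divergent but not fixed — and can be pinned per SNP;
line-fixed frequencies reproduce the fully informative map the linkage
machinery assumes at full power.  Phenotypes have unit base variance
per trait (`σ²_u = h²`, `σ²_e = 1 − h²`), cross-trait genetic and
residual correlations, and QTL effects in those base-SD units added
through the true line-origin coefficient.  Genotype missingness (1%)
and Mendelian errors (0.2%) are injected only after the truth record is
stored.

Expression values are `baseline + effect × P_a(regulating locus) +
noise` on a log₂-like scale, with a per-sample co-expression factor
(variance share 0.75, independent between tissues) shared by all
probes.  The factor emulates the dominant principal component of
normalized expression arrays; it is what brings the effective number of
probe tests for a ~470-probe set down to ~207 rather than ~470, the
regime a real targeted study operates in.  Tissue 2 reuses the first
`n` tissue-1 samples (default 40 of 102) and scales the genetic effect
by the probe's sharing coefficient.

What the generator does *not* emulate: compositional (sum-to-100%)
constraints among fatty acids, gas-chromatography measurement error,
probe-level microarray noise or normalization artifacts, selection or
non-random mating, and X-chromosome inheritance.  Passing tests
demonstrate correctness of the statistical machinery under its own
assumptions, not robustness to these real-data features.

Randomness: one global seed; each stage (pedigree, genomes, phenotypes,
expression) draws from its own SeedSequence substream with a fixed
stage key, so stages are reproducible independently of call order.

## Problem sizes in the test suite

The statistical acceptance tests run at study scale but modest
replicate counts chosen for a desktop run: 200 null replicates (n=157)
for type-I error, 50 replicates (n=400) for position/effect recovery,
3×50 replicates (n=300, 2 cM decision-tree grid, coarse two-QTL
profiling at 4 cM with 2 cM refinement) for architecture recovery, and
25 replicates (102 arrays, 471 probes) for the targeted eQTL stage.
Oracle checks (dense multivariate-normal likelihoods, gene-dropping
relationship estimates, brute-force step-ups) use small instances where
exactness, not power, is at stake.

## Acceptance behaviour and known limitations

- The targeted-eQTL recovery check is the one acceptance property that
  does not clear its bar: at a 1 base-SD cis effect over 102 arrays the
  discovery power under BY-control at the effective multiplicity is
  ≈ 0.70, and the 95% LR-drop interval covers the regulating gene in
  only ≈ 85% of discoveries, so the joint event runs at ≈ 0.6.  Both
  factors are properties of the published procedure (naive drop
  intervals undercover; BY at ~2000 effective tests needs LR ≳ 19), not
  of this implementation — the same run controls the null side cleanly
  (zero false eQTL discoveries in ≥ 90% of replicates).
- Nyholt's eigenvalue-variance M_eff is insensitive for strongly
  blocked correlation structures and tends to overestimate the
  effective test count; it is used because it is the field-standard
  choice this pipeline models, with the equivalent alternative formula
  intentionally not duplicated.
- ML variance components at n ≈ 157 are biased low; heritability point
  estimates from single cohorts should be read with that in mind.
- The per-gamete line-origin smoother ignores F1-sire phase information
  shared across half-sib families.
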