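# Methods

## The models

All analyses are linear mixed models of plot-level phenotypes
`y = Xb + Σ_t Z_t u_t + ε`.

**Multi-environment model** (the workhorse): fixed overall mean and
replicate effect; random SE main effect, trial, replicate nested in
SE-and-trial, and incomplete block nested in replicate — each iid with its
own variance — plus the line-by-SE genetic effect

    u_gxe ~ N(0, (ΛΛ' + diag(Ψ)) ⊗ K)

where `Λ` (k SEs × m factors) and `Ψ` (k specific variances) give the
factor-analytic between-SE genetic covariance `Go`, and `K` is the line
kinship: genomic `G` (VanRaden method 1, `WW'/2Σp_j(1−p_j)` with dosages
centered by twice the allele frequency — observed panel frequencies by
default, base-population frequencies optionally) or pedigree `A` (tabular
numerator relationship). For cohorts pooled with ungenotyped historical
lines, `K` becomes block-diagonal with an identity block for the lines
without markers. The residual is independent between SEs with per-SE
variance `σ²_k`, optionally correlated within an SE as the separable
`AR1(ρ_col) ⊗ AR1(ρ_row)` process over field columns and rows.

**Multi-year variant**: historical SEs are relabeled as distinct
environments (`B5IR*` style) so they enter the FA structure as additional
correlated SEs, and the replicate/block nesting keys gain the year label.
**Single-SE variant**: the genetic term is a line main effect
`u ~ N(0, σ²_g K)`; trial, replicate-in-trial and block terms as above.

**BLUEs** come from the same machinery with the line(-by-SE) effects moved
into the fixed part. Random terms whose design columns then lie inside the
span of the line effects (the SE main effect always; the trial effect
whenever no line appears in more than one trial within an SE) are dropped:
their variances have no error-contrast information. Reported BLUEs are the
cell effect plus the average replicate effect, so the mean BLUE matches
the overall mean; standard errors come from the fixed-block inverse of the
mixed-model equations.

### Identifiability and scale conventions

* FA loadings are identified by zeroing the upper triangle of `Λ` and
  making each factor's leading loading positive (an LQ rotation applied
  after convergence; with m=1 only the sign matters). The default order is
  m=1; anything up to k−1 is accepted.
* Genetic variances are expressed per unit kinship. Because VanRaden `G`
  of an inbred panel has mean diagonal ≈ 1+F (≈1.75 for three selfing
  generations), the line-scale genetic variance is `Go_kk · mean(diag K)`;
  that product enters the plot heritability
  `h²_k = σ²_g(k)/(σ²_g(k)+σ²_k)`. With a unit-diagonal kinship the two
  conventions coincide.
* Kinships are stabilized before factorization by adding 1e−6 to the
  diagonal; an optional `0.99·G + 0.01·I` blend is available but off by
  default.

## REML estimation

One Cholesky factorization of the mixed-model-equation matrix
`C = W'R⁻¹W + diag(0, Σ⁻¹)` per objective evaluation gives the restricted
log-likelihood through
`−2l = (n−p)·log 2π + log|R| + log|Σ| + log|C| + y'Py`. The optimizer
runs three expectation–maximization (EM) iterations for stable start-up,
then average-information (AI) Newton steps on transformed parameters (log
variances, log specific variances, raw loadings) with step halving
against the likelihood; a variance that collapses below 1e−8 of the
phenotypic variance is pinned to the boundary and flagged. On small
systems (MME dimension ≤ 100) a derivative-free Nelder–Mead/Powell polish
tightens the optimum — this is what the brute-force-oracle agreement
tests exercise at 1e−4/1e−3. Spatial correlations are profiled rather
than Newton-updated: a −0.9…0.9 grid in steps of 0.1 followed by
golden-section refinement, per SE and axis, every few iterations; this
avoids boundary instability of joint ρ steps. Convergence requires
relative log-likelihood change below `tol` (default 1e−6) and transformed
parameter change below 100·tol; non-convergence yields a warning-carrying
result, never an exception.

Only observed (line, SE) cells of the genetic term carry equations; the
predictions for unobserved cells are the conditional means
`Cov(all, obs) Σ_obs⁻¹ û_obs` under the fitted covariance, which is
algebraically identical to carrying zero-incidence columns and much
cheaper for sparse-testing fits. When every line is observed in every SE
the prior precision factorizes as `K⁻¹ ⊗ Go⁻¹` and the Kronecker shortcut
is used throughout.

A deliberately independent reference path (`sparsegp.reference`) builds
the dense phenotypic covariance and maximizes the error-contrast
likelihood with generic derivative-free optimizers over an unstructured
2×2 genetic covariance; the test suite checks both the objective identity
(to 1e−8 at arbitrary parameters) and the maximizer agreement (1e−4 in
log-likelihood, 1e−3 in components) against it.

## Sparse-testing designs

The overlap count for fraction f of n lines over k SEs is the smallest
`x ≥ f·n` with `(n−x)` divisible by k, which makes the per-SE unique sets
exactly equal and reproduces the published counts 28/58/88/112/142 for
n=280, k=6 (calibration sets 70/95/120/140/165, prediction sets
210/185/160/140/115). The non-overlapping scheme partitions lines into
sets differing by at most one (46/47 for 280 over 6); which SEs receive
the larger sets is randomized per repeat, as is everything else —
allocation is simple random sampling of lines (a family-stratified option
exists but is off by default). Checks are phenotyped everywhere, excluded
from accuracy sets.

## Accuracy metrics

* **Predictive ability**: Pearson correlation, per SE, between the
  predicted genetic effects of that SE's prediction set and the reference
  BLUEs computed once from the full data.
* **Smith–Hazel intersection accuracy**: index weights `b = P⁻¹ G w` with
  `G = Go` from the fit, `P = Go + diag(σ²_ε / n_reps)` (per-line-mean
  phenotypic covariance; configurable) and economic weights
  `(0.25, 0.1, 0.3, 0.2, 0.1, 0.05)` bound positionally to the sorted SE
  order. The top `⌈0.2·n⌉` lines by index score from the prediction model
  are intersected with the same selection from the full-data fit. Ties at
  the cutoff break by line id, and each model's own fitted covariance
  builds its index.

## The synthetic-data generator

The generator emulates the data architecture of an elite spring-wheat
stage-2 cohort, not any real dataset: inbred founders (allele frequencies
uniform on the configured MAF range), ~56 biparental crosses with family
sizes uniform on 1–9, three generations of selfing at unlinked loci
(linkage is deliberately not modelled: relationship-based prediction needs
relatedness, not linkage disequilibrium), six SEs with five trials of
56 entries + 4 checks in two replicates, blocks of ~8 consecutive plots
within an 8×15 per-trial grid, and plot values built as mean + SE + trial
+ replicate + block + genetic + spatial AR1⊗AR1 noise (ρ = 0.3 each way
by default).

Genetic values are marker-mechanistic: each latent factor and each
SE-specific deviation is a linear score of ~300 randomly chosen marker
effects, standardized and successively orthogonalized in-sample (the
projection of a marker score is still a marker score), so the realized
between-SE covariance of the true values equals `ΛΛ' + Ψ` and genomic
prediction has a real marker target. A direct matrix-normal draw
(`mvn` mechanism) is available for oracle checks. The default six-SE
architecture sets pairwise genetic correlations from ≈−0.06 to ≈0.77 with
one near-uncorrelated low-heritability SE (plot h² 0.18, the
early-heat-stress pattern) and heritabilities up to 0.6.

What the generator does not emulate: linkage maps and LD decay,
genotyping-error/imputation artefacts, selection during line development,
non-rectangular fields, and year effects beyond a label. Passing tests
therefore demonstrate correctness of the machinery and qualitative
behaviour under the assumed covariance structure, not calibration to any
particular field dataset.

## Validation studies and problem sizes

The canned studies (in `sparsegp.experiments` and the validation suite)
use sizes chosen to make one-core runs practical while keeping the
cohort architecture: parameter recovery uses ten cohorts of 300 lines ×
six SEs × two replicates (~3,900 plots, MME dimension ≈ 2,300; blocks of
~14 plots for this study) and recovers genetic correlations with mean
absolute error ≈ 0.06 and heritabilities ≈ 0.04; the sparse-testing
comparison uses the full 280-line architecture with three allocation
repeats at 0% and 50% overlap; the stage-advancement study uses 150
stage-1 lines of which 80 advance to three correlated SEs. Spatial
residual fitting is exercised on a single-SE instance; the larger studies
simulate spatial noise but fit independent residuals per SE, which leaves
marginal variances (and so heritabilities) unbiased while keeping the
fits fast.

## Known limitations

* The reduced-rank sparse-algebra formulation of high-dimensional FA
  models is not implemented; all linear algebra is dense, sized for
  cohorts up to a few thousand plots.
* Pedigrees record only the biparental cross; selfing generations are
  applied to genotypes but not expanded into pedigree individuals, so `A`
  carries unit diagonals while `G` reflects realized inbreeding. Their
  off-diagonals agree in expectation, which is what PBLUP uses.
* Historical-data augmentation treats prior-year lines as unrelated
  (identity kinship block); any realized relatedness through shared
  founders is ignored, matching the combined-dataset convention when
  markers are unavailable.
* The BLUE model estimates one fixed effect per observed cell; with very
  sparse cells its standard errors grow accordingly, and confounded lines
  would be flagged missing rather than estimated.
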