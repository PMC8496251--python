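# Methods

`kinscan` measures how relatedness (kinship) inflates three families of
genome-scan test statistics — single-locus main effects, pairwise
interaction (epistasis) coefficients, and directed-influence coefficients
obtained by combining two traits — across the mouse mapping designs in
common use, and how linear-mixed-model (LMM) kinship corrections change
that inflation. Everything below is implemented in the package and
exercised by the test suite; no empirical claim is made here that the tests
or `scripts/acceptance.py` do not themselves compute.

## Kinship matrices

The realized genomic relationship matrix is `K = G·Gᵀ/n` for the
individuals × markers dosage matrix `G` (dosages in [0, 1]: 0/0.5/1 =
hom-ref/het/hom-alt) and `n` markers. Dosages enter as-is — no column
centering or standardization — so `K` is positive semidefinite by
construction. For single-locus tests the kinship is recomputed leaving out
the tested marker's chromosome (LOCO); for pair tests, both tested
chromosomes (LTCO), collapsing to LOCO when the two markers share a
chromosome. By default reduced matrices are divided by the number of
markers actually used; `denominator="total"` divides by the full marker
count instead (the two conventions differ by a constant factor per matrix
and the choice is not settled usage; both are provided).

Eigenvalues in (−1e−8, 0) are clipped to zero; anything more negative is
treated as upstream corruption and is fatal.

### Normalization scale

Dosage kinship is uncentered and therefore carries a large component along
the all-ones vector (every pair of individuals shares the population-mean
dosage profile). That component is absorbed by the intercept of any model
and contributes nothing to between-individual variance. `normalized()`
therefore rescales `K` by the mean diagonal of the *centered* matrix, so
that a random effect drawn with covariance `K_norm` has unit expected
between-individual (deviation) variance. With this convention the trait
simulator's `polygenic_variance` and the mixed model's fitted mixing
parameter are both on the familiar `h² = Vg/(Vg+Ve)` scale, and the two
agree: simulating `h² = 0.5` and fitting recovers `ĥ ≈ 0.5`.

## Mixed-model correction

The polygenic model puts residual covariance `σ²(h·K + (1−h)·I)` on each
trait, `h ∈ [0, 1)`. `K = VΛVᵀ` is factored once; in the rotated basis
`Vᵀ` the generalized least-squares problem becomes weighted least squares
with weights `1/(h·λᵢ + 1−h)`, so the fixed effects and `σ²` have closed
forms at each `h` and `h` is profiled on a grid (default step 0.01,
configurable; the grid-search optimum is within one step of a 0.001-step
rerun). Full maximum likelihood is the default; REML is a flag. Ties are
broken toward smaller `h`. Covariates enter the null model used to profile
`h`, so covariate signal cannot load onto the variance component.

Scans then run ordinary least squares on `y* = W^{1/2}Vᵀy` and the
likewise-rotated design columns. At `h = 0` the rotation is orthonormal and
every OLS statistic is unchanged — a convenient exactness check that the
tests exploit. One fit is made per trait × kinship matrix;
eigendecompositions are cached per omitted-chromosome set, which bounds the
cost of LTCO pair scans at `C(n_chrom, 2) + n_chrom` decompositions.

## Scan models

Single-locus, per trait `j` and marker:

    U_ij = β0j + Σ_c x_c,i β_cj + x_1,i β_1j + ε_ij

Pairwise, adding the second marker and the product term:

    U_ij = … + x_1,i β_1j + x_2,i β_2j + x_1,i x_2,i β_12j + ε_ij

P-values default to a t distribution with `n−1` degrees of freedom
(`df_rule="n_minus_1"`); the conventional residual degrees of freedom are a
flag. At survey sample sizes the two are indistinguishable. Monomorphic
markers yield missing statistics and are counted, not dropped silently.

Markers enter pair tests through an LD-aware greedy selection: candidates
are ranked by their best main-effect p-value across the two traits and
taken from the top, skipping any marker whose dosage correlation with an
already selected marker exceeds `collinearity_r_max` (default 0.5). In
high-LD designs the strongest markers all sit on one linkage block, so
selection without this pruning leaves no testable pairs; the threshold also
protects the CAPE matrix inversion. Any surviving pair above the threshold
is excluded as a final guard.

Empirical p-values come from a pooled permutation null: phenotype rows are
permuted jointly across traits (preserving trait–trait correlation, which
the two-trait reparametrization depends on), covariates stay with the
genotypes, and all statistics from successive permutations are pooled until
a target size is reached (desk-scale default 15,000; any size, including
millions, is a config value). `p = (1 + #{null ≥ |stat|})/(1 + N)`, never
exactly zero.

## Directed influences (CAPE-style reparametrization)

For one marker pair fitted on two traits, the main-effect matrix
`B = [[β1¹, β2¹], [β1², β2²]]` and interaction vector `b = (β12¹, β12²)`
define `δ = B⁻¹·b`, and the marker-to-marker influences solve
`δ1 = m12(1+δ2)`, `δ2 = m21(1+δ1)`. Pairs with `cond(B) > 1e8` or
`|1+δ| < 1e−8` are flagged degenerate and reported, never silently
dropped. Because the inversion can amplify noise, the variance of each `m`
is propagated from the two regressions' coefficient covariance blocks
(treated as independent between traits — they share genotypes but have
separate residuals) through a second-order Taylor expansion:
`Var[f] ≈ gᵀΣg + ½·tr((HΣ)²)`. Gradients and Hessians are computed by
central finite differences on the exact map with per-coordinate steps;
against a 200,000-draw Monte-Carlo resampling of the coefficients the
result agrees to a few percent in the moderate-noise regime.

Two properties of this statistic matter for interpretation. First, the
exact `m` distribution is heavy-tailed (no finite variance) once `B` is
noisy, so the standardized `m/SE` statistic is far from normal;
significance therefore uses permutation p-values, not a normal
approximation. Second, the reparametrization is only informative in the
regime marker selection produces — main effects large relative to the
interaction — where `δ` is small and the linearization benign.

## Inflation evaluation

λ maps each p to the χ²₁ quantile of `1−p` and divides the median of those
quantiles by the χ²₁ null median (exact 0.45494 by default; the rounded
0.456 common in print, and a mean-based numerator, are flags). λ = 1 is
calibrated; λ > 1 inflated. QQ exports pair sorted observed `−log10 p`
with uniform plotting positions `i/(N+1)`.

Variability is estimated by Monte-Carlo cross-validation: 10 trials
(default) each draw an 80% subsample of individuals without replacement and
run the full pipeline — main scan, marker selection, pair scan,
reparametrization — for each correction regime (`none`, `reduced` =
LOCO/LTCO, `overall`), recording λ per statistic class. Main-effect and
interaction λ use the analytic t p-values; the directed-influence λ uses
empirical p against one pooled permutation null per population ×
correction, built on the full sample and shared across trials (one pooled
null per run mirrors standard practice and keeps the CV loop tractable).
A normal-approximation option exists but, per the heavy-tail point above,
deflates the directed-influence λ and is not the default.

`run_survey` orchestrates structure metrics plus the CV evaluation over any
set of population bundles, writes delimited λ/structure/QQ tables with a
provenance log, marks failed populations and continues. Reruns with the
same config and seed are byte-identical.

## Population structure metrics

The kinship matrix becomes a weighted network (off-diagonal entries as edge
weights; self-loops removed; negative weights clipped to zero, since
modularity clustering assumes nonnegative weights) and subpopulations are
greedy-modularity communities with a fixed node-order tie-break. F_ST =
(π_T − π_S)/π_T with π the sum over loci of expected heterozygosity
2p(1−p) from dosage allele frequencies — expected rather than observed
heterozygosity because inbred-line individuals have near-zero observed
heterozygosity, which would make the index degenerate (an
observed-fraction variant is a flag). π_S weights subpopulations by size
(unweighted mean is a flag). Trait screening reports each trait's Pearson
correlation with the leading eigenvector of the centered kinship matrix
(sign fixed by making the largest-magnitude loading positive), and the LD
summary pools within-chromosome pairwise dosage correlations.

## The population simulator

Breeding schemes are simulated on founder-label haplotypes with Haldane
meiosis: per chromosome, a Poisson(length/100) crossover count, uniform
crossover positions, no interference, starting strand by fair coin. This is
the simplest model that produces the LD gradient the survey needs — F2 and
backcross high, AIL generation 50 and outbred stock low.

- **F2**: two meioses of the F1 per individual; dosage frequencies 1:2:1.
- **Backcross**: F1 gamete plus an intact recurrent-parent haplotype;
  dosages in {0, 0.5}.
- **RIL**: per line, an F1×F1 sibling pair followed by 20 (default)
  generations of sib mating; residual heterozygous calls (<1% at default
  depth) are kept as 0.5 dosages, with a flag to force homozygosity.
  Genomic replicates are exact row copies; averaging rows within line
  reproduces the RIL-without-replicates population exactly.
- **AIL**: F2 followed by random-pair mating to filial generation 50
  (default), giving per-marker heterozygosity ≈ 0.5 and adjacent-marker
  correlation that shrinks with every generation (map expansion).
- **outbred8**: eight founders funneled round-robin (2-way, 4-way, 8-way)
  per individual, then random mating, optionally sampling the last few
  generations with generation labels — a structural emulation of an
  8-founder outbred stock, not a calibrated model of any particular colony.
  Founder labels are converted to dosages through a random biallelic
  founder-allele matrix.

Traits are `y = Σ a·dosage + Σ w·dosage_i·dosage_j + polygenic + line +
residual`. The polygenic term is multivariate normal with covariance
`polygenic_variance × K_norm` for the realized overall kinship — exactly
the random effect the LMM fits, which is what makes parameter-recovery
tests clean; a many-small-QTL architecture can be emulated directly with
the additive-QTL list. The line effect is shared within RIL line
(covariance `line_variance × ZZᵀ`). Additive QTL accept per-trait weight
multipliers: partial pleiotropy (distinct per-trait effects) is required by
the two-trait reparametrization, whose trait matrix is exactly rank one —
degenerate for every pair — when two traits share one genetic component up
to scale. All draws are recorded in a truth record sufficient for
true/false-positive scoring.

What the simulator does *not* emulate: X-chromosome dosage compensation,
sex-specific maps, crossover interference, mutation, real founder haplotype
panels, genotyping error. Passing tests therefore demonstrate the
statistical machinery under idealized Mendelian inheritance, not
performance on array data artifacts.

## Study conditions and known limitations

Two properties of LOCO are worth stating plainly, because they set what the
desk-scale checks can and cannot show:

- A strain effect that is *not* mediated by genotype (a pure line-level
  random effect) is corrected by the overall kinship — which contains the
  tested marker and absorbs marker-aligned variance, the familiar proximal
  contamination — but not by LOCO, which deliberately leaves the tested
  marker's direction unshrunk. Verified directly: with such a trait the
  LOCO-corrected λ is essentially unchanged while the overall-corrected λ
  is ≈ 1.
- For a kinship-drawn polygenic trait, LOCO retains the tested
  chromosome's share of polygenic signal *by design* (that is its power
  advantage). With C chromosomes this leaves λ above 1 by an amount that
  grows with `n·h²/C`; at strong heritability (h² = 0.5) no desk-scale map
  brings the LOCO λ near 1. With no own-chromosome signal the LOCO-rotated
  scan is exactly calibrated (λ = 1.01 measured), so this is retained
  signal, not miscalibration.

The replicate-structured RIL evaluation therefore uses a weakly polygenic
trait (polygenic variance 0.15 against residual 1 on the deviation scale),
emulating survey traits screened for low correlation with kinship PC1 —
screening that is itself part of the workflow this package implements. At
those conditions (20 chromosomes × 80 cM × 40 markers, 55 lines × 8
replicates) the uncorrected λ ≈ 2.4 and the LOCO-corrected λ ≈ 1.2. The F2
evaluation uses n = 1000 on 2 × 100 cM × 50 markers with h² = 0.5, where
uncorrected λ is in the tens and the overall correction returns it to ≈ 1.
Problem sizes throughout (n of a few hundred, tens of markers per
chromosome, 3–10 CV trials, nulls of 10³–10⁴ values) are the package's
desk-scale defaults; every one of them is a config value that scales up.

Numerical conventions collected in one place: PSD clip tolerance 1e−8;
mixing-parameter grid step 0.01 with ties toward smaller h; β-matrix
condition bound 1e8; |1+δ| tolerance 1e−8; finite-difference steps
`1e−4·max(|β|, 0.05)` per coordinate; empirical p with the +1 correction;
λ denominator 0.4549 (exact χ²₁ median); collinearity bound r = 0.5;
missing genotypes mean-imputed per marker before kinship or scans;
individuals with a missing trait dropped per-analysis.
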