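# Methods

`alugs` re-implements, as a tested reusable pipeline, the genomic-selection
analysis of a two-condition upland-rice trial: a panel of partially inbred
S0 families evaluated under natural aluminum-toxic acid soil (ALU) and a
limed control (LIM), genotyped by GBS, and selected with multi-trait
indices. Because no real dataset ships with the package, a first-class
synthetic-data generator reproduces the statistical structure every stage
assumes; all tests and the acceptance script run against it.

## Synthetic data generator

### Genotypes

Dosages (0/1/2 copies of the minor allele) for `n_lines` x `n_snps`
biallelic SNPs on `n_chromosomes` chromosomes, evenly spaced at
`marker_spacing_bp` (40 kb default, ~1 SNP / 40 kb as in a typical GBS
panel).

* **MAF spectrum.** Target minor-allele frequencies are marginally uniform
  on `maf_range` (default (0.025, 0.5]), drawn along each chromosome
  through an AR(1) Gaussian copula with coefficient `ld_rho`, so linked
  loci have similar frequencies. This keeps the marginal exactly uniform
  while making the LD chain (below) feasible.
* **Linkage disequilibrium.** Each gamete is a first-order Markov chain of
  alleles: the conditional P(a_j | a_{j-1}) is chosen so marker j keeps
  its target frequency while corr(a_{j-1}, a_j) = `ld_rho` (clipped to
  [0,1] where the joint law would be infeasible). One parameter produces
  the slow, monotone r² decay such panels show. Realized adjacent-marker
  *dosage* correlation is mildly attenuated below `ld_rho` (≈0.86 at 0.9
  with no inbreeding, ≈0.78 with the default inbreeding) by clipping and
  by heterozygote thinning; tests account for this.
* **Inbreeding.** S0 plants carry residual heterozygosity. Heterozygous
  calls are thinned per marker to frequency 2p(1-p)(1-f) with
  `inbreeding_f` (default 0.1, "relatively low fixation"): each het
  becomes a random homozygote with probability f. This preserves allele
  frequencies and is applied independently per marker.
* **Missingness** (`missing_rate`, default 0) masks calls uniformly for
  exercising the QC/imputation path.

### True genetic values

For each trait t and condition e, per-SNP effects are drawn from a
multivariate normal whose covariance is the Kronecker product of a
trait-correlation matrix (identity by default; a matrix option induces
e.g. the FL-YLD antagonism) and the 2x2 condition correlation with
off-diagonal `rho_g`. `rho_g` (default 0.6, inside the observed 0.51-0.64
between-condition range) is the single knob that creates
genotype-by-environment interaction: at 1 there is none; at 0 conditions
are genetically unrelated.

The marker-borne part of the true value is `W @ alpha` (W = centered
dosages). A line-level polygenic remainder with the same correlation
structure carries the fraction `1 - marker_share` of genetic variance
(default `marker_share = 0.75`). Real GBS panels do not tag all causal
variation — main-effect GBLUP fits on such panels attribute roughly a 3:1
split between kernel-structured and residual line-level genetic variance,
which is what the fitted model's line intercept exists to absorb. Without
this component, single-environment prediction is unrealistically accurate
and the multi-environment advantage the pipeline is designed to
demonstrate disappears. Both parts are rescaled so the realized genetic SD
per (trait, condition) equals `genetic_sd` exactly (defaults: FL 3.5 d, PH
7 cm, YLD 500 kg/ha, ZN 2 ppm — chosen so phenotypic CVs match a
well-run upland trial: a few percent for FL/PH, ~25-30% for YLD).

### Field trial

Per condition, a p-rep layout of `n_blocks` x `plots_per_block` plots
(default 36 x 14 = 504). `round_half_up(prep_fraction * n_lines)` test
entries (84 of 334 at defaults) are sown twice, every check
`check_reps` times, and remaining plots are padded with extra check
replicates round-robin — the stated percentages are satisfied and the
total plot count is treated as derived, not fixed, since entries +
replicates + checks need not close exactly on the grid. Blocks are laid
side by side, so `col` is the block index and `row` the within-block plot.

Phenotype per plot: condition mean + genetic value + row effect + column
effect + smooth surface + iid residual. The smooth surface is a random
cubic Chebyshev polynomial in (row, col), standardized and scaled.
`spatial_sd`, `row_sd`, `col_sd` are *fractions of each trait's residual
SD* (defaults 0.5/0.3/0.3) rather than raw trait units — one scalar could
not be simultaneously sensible for days and kg/ha. The residual SD comes
from the heritability budget: sd_e = genetic_sd * sqrt((1-h2)/h2), so the
plot-level ratio Vg/(Vg+Ve) equals the configured `h2` (Table-2-like
defaults, 0.56-0.75). Checks receive fixed genetic values drawn from the
same trait-condition covariance.

Every stage draws from its own `SeedSequence` stream derived from the
global seed; identical config + seed is bit-identical at every stage.

**What the generator does not emulate:** selfing-generation drift between
genotyped S0 plants and phenotyped S0:4 bulks, population structure (the
real panel showed none), non-Gaussian trait distributions, spatially
correlated residuals beyond the smooth+row/col decomposition, and
genotype-dependent missingness. Passing tests demonstrate internal
consistency of the methods under this model, not field performance.

## SNP QC and kinship

Filters run sequentially — depth, missingness, biallelic status, MAF — so
removal counts are deterministic and sum to the input count. Boundaries
are strict as conventionally printed: keep depth > 10 (shallower calls are
set missing first), site missingness < 20%, MAF > 2.5% (a site at exactly
0.025 is removed; the boundary behavior is documented rather than
guessed). Missing calls after filtering are imputed per marker by mean
(default) or mode; observed calls are never altered.

The genomic relationship matrix uses the VanRaden-scaled linear kernel
K = WW'/c, W column-centered by twice the panel allele frequency and
c = sum 2p(1-p) — the de-facto standard behind "linear kernel" GBLUP.
Frequencies come from the analyzed panel itself. A correlation-scaled
alternative is exposed. Partial inbreeding inflates the mean diagonal
above 1 (≈1.05-1.1 at defaults); variance components therefore live on
the kernel's own scale (see parameter recovery below).

## Spatial single-trial model

Per condition and trait:

    y = X beta + Z_r u_r + Z_c u_c + Z_s u_s + e

with genotype (families and checks) fixed for BLUEs or random for
variance components, iid random row and column effects, and an optional
smooth surface. The surface is a tensor-product cubic B-spline on the
plot coordinates (8 x 8 basis) with a second-order difference penalty:
its penalty null space (the bilinear trend r, c, r·c) is carried as fixed
covariates and the penalized part enters the mixed model as an iid random
effect through the spectral decomposition of the penalty. This captures
the same smooth + discontinuous decomposition as a PS-ANOVA fit with
standard REML machinery; effective dimensions of that decomposition are
not replicated.

REML profiles out the residual variance and minimizes the deviance over
log variance ratios with an adaptive Nelder-Mead simplex (tolerance 1e-6
relative deviance, iteration cap 200 per component; non-convergence is an
error carrying the optimizer trace). Variance ratios are clipped to
e^[-30, 30], which enforces non-negativity at the boundary. BLUEs use
cell-means coding (one coefficient per entry, no intercept), so the BLUE
is the estimated entry mean; SEs come from the GLS covariance. Missing
plots are dropped listwise per trait.

Broad-sense heritability is H² = σ_G²/(σ_G² + σ_ε²) from the
genotype-random fit — spatial components are deliberately excluded from
the denominator, matching the estimator's definition; whether a
generalized (effective-dimension) heritability would differ is noted but
not implemented. Checks are fitted in the genotype factor but excluded
from all downstream training, validation and selection sets.

## Multi-environment GBLUP

Responses are BLUEs stacked over conditions with one fixed intercept per
condition and a single homogeneous residual. Random effects are
kernel-structured at the line level:

| model | components |
|-------|------------|
| SM    | g (kernel K), l (identity) — one condition |
| MM    | g, l shared across conditions (no GxE) |
| MDs   | MM + per-condition K-deviations sharing one variance σ_ge² |
| MDe   | MM + per-condition K-deviations with own variances σ_ALU², σ_LIM² |

The line intercept l captures line-level genetic variance the markers do
not tag. Sampling is conjugate Gibbs in the spectral basis of each
kernel: with u = U b, K = U diag(d) U', the coefficients b_j are updated
scalar-wise from their normal full conditionals with running-residual
bookkeeping (O(records) per coefficient), variances from
scaled-inverse-chi-square full conditionals, intercepts from normal full
conditionals under a flat prior. The sweep is numba-compiled; seeded
chains are exactly reproducible. Eigenvalues below 1e-10 of the largest
are trimmed.

Priors: every variance gets a scaled-inverse-chi-square with df = 5 and
scale set so the prior mode is an equal split of the phenotypic variance
across the components plus residual. Production chain defaults are
burn-in 5000, 70000 iterations, thinning 5 (13000 retained samples);
tests and cross-validation default to a shortened burn-in 500 / 5000 / 5
chain, which the oracle checks show is adequate at these problem sizes.
Any variance group can be pinned (`fix_variances`) — used for the
BLUP-oracle equivalence check and the nesting degeneracies (MDs with its
deviation variance pinned at ~0 reproduces MM; MDe with equal pinned
deviation variances reproduces MDs with the same pin).

GEBV(entry, condition) = posterior mean of g + l + the condition's
deviation effect(s); the condition intercept is excluded (predictive
ability is correlation-based). Including l is the default because it is
genetic by construction; a flag gives the kernel-only alternative.
`predict_value` adds the intercept back for quantities that need the
observation scale (the ratio stability index). Because effects are
line-indexed, predictions exist for entries unobserved in a condition —
the sparse-testing case — with no data augmentation.

Variance proportions are posterior-mean variances normalized over
{residual, g, l, deviations}. On parameter recovery: σ_g² and σ_I² are
only jointly well identified (the identity and genomic kernels compete
for line-level signal), and σ_g² lives on the realized-kernel scale, so
recovery checks compare σ_g² · mean(diag K) against the marker-borne
generating variance and σ_g²·mean(diag K) + σ_I² against the total — both
recover within a few percent to ~15% at n = 300.

## Cross-validation

Folds partition the test families (checks excluded) into k groups whose
sizes differ by at most one, uniformly at random per repetition,
deterministic per seed. Scenario `single_env` trains SM on k-1 folds of
the target condition; scenario `multi_env` trains on the entire
secondary-condition population plus k-1 target folds — held-out entries
keep their secondary-condition records in training *by design* (sparse
testing). A leakage audit asserts on every fold that no held-out
target-condition record reached the training stack. PA is the Pearson
correlation of GEBVs with held-out BLUEs; degenerate folds are recorded
as missing with a warning.

Model comparison pools the k x repetitions fold values per model (50 at
the default 5 x 10; pooling vs averaging repetitions first is switchable
in the summary, which reports both SDs), runs one-way ANOVA plus Tukey's
HSD at alpha 0.05, and renders a compact letter display via maximal
cliques of mutually non-different models.

## Stability and selection indices

iYLD = (YLD_ALU − YLD_LIM)/YLD_LIM × 100 (positive = aluminum-tolerant);
e_iYLD applies the same formula to SM-predicted yields on the observation
scale. Families with non-positive control yield make the ratio undefined:
the contract default raises; pipeline-level callers use the drop-with-
warning policy.

Smith–Hazel coefficients solve P β = G w (linear solve; singular or
ill-conditioned P errors with a ridge suggestion). P and G are unbiased
(n−1) empirical covariances of family-level values. The genomic index GSi
uses stress-condition BLUEs for P (the GSi targets stress performance;
switchable) and multi-environment MM GEBVs for G, scoring families on
their GEBVs. The phenotypic index PSi uses control-condition BLUEs plus
iYLD as a fifth trait in both matrices, scoring on phenotypes; when no
genomic prediction of iYLD is supplied its observed value stands in for
the genetic column — its marker signal is precisely what the pipeline
shows to be weak. Default weights: FL 0, PH −0.2, YLD 1, ZN 0.8, iYLD 0.5
(program defaults from prior selection cycles).

The top round-half-up(fraction · n) families are selected (33 of 334 at
10%; ties broken by stable family-id order). The selection differential is
S = mean(selected) − mean(population), positive for improvement — the
sign convention that makes a gain read as a positive number.
`bi_condition_top` intersects the per-condition top fractions (the
"high-yielding in both conditions" set).

## Orchestration

`run_pipeline` composes simulate/ingest → QC → BLUEs (+H², correlations)
→ model fits (variance partitions) → CV (+Tukey letters) → selection into
one run with a YAML config, per-stage seeds derived from the global seed,
a machine-readable `summary.json` (bit-reproducible: wall times go to the
log only) and a human-readable `report.md` whose every number traces to a
stage artifact. The thin `alugs` CLI exposes each stage
(`simulate|qc|blues|fit|cv|select|run`).

## Problem sizes

Tests and the acceptance script run the study at reduced scale — 300
lines x 1000 SNPs for cross-validation blocks, 120-line trials for
heritability/spatial checks, 50-80 lines for oracle and nesting checks,
with the shortened chains above — sizes at which the Monte-Carlo
assertions were verified to be stable. The full 334 x ~10⁴ configuration
is the generator default and runs unchanged, only longer.

## Known limitations

* The REML spline is a generic tensor-product P-spline, not a full
  PS-ANOVA decomposition; its variance attribution between "smooth" and
  row/col components can differ from dedicated field-trial spline
  packages even when the BLUEs agree.
* Single homogeneous residual across conditions in the GBLUP stage.
* The Gibbs sampler's scalar updates mix slowly when two components are
  nearly collinear (g vs l); the oracle tests quantify the residual MCMC
  error at the chain lengths used.
* iYLD inherits ratio-noise amplification: its predictive ability is
  structurally lower than that of yield itself, which is the point the
  pipeline demonstrates, but absolute iYLD PAs are sensitive to the
  control-yield mean/SD ratio.
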