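# Methods

`microscca` detects collective associations between host genetic
variants and gut-microbiome features (KEGG-ortholog gene families or
species) from paired genotype and shotgun-metagenomic data. This note
describes the statistical model, the choices behind each stage, and
what the synthetic-cohort validation does and does not establish.

## Model overview

The working hypothesis is that a set of host variants and a set of
microbial features share a common latent factor: neither causes the
other directly, but both load on an unobserved axis (host physiology,
immune tone, diet response, ...). The method therefore looks for paired
sparse weight vectors — β over coded variant columns, α over microbial
features — minimizing

    ‖Xβ − Yα‖₂² + λ₁·pen₁(β) + λ₂·pen₂(α),   s.t. ‖Xβ‖₂ = ‖Yα‖₂ = 1,

where `pen₁` is a group lasso over the two coded columns of each
variant (a variant enters or leaves whole) and `pen₂` is an elastic net
(correlated features enter together). Weight magnitudes are biased
unevenly by the penalties and are deliberately interpreted only as zero
vs nonzero; the reported canonical correlation comes from a classical
CCA refit on the selected columns.

## Abundance normalization and the Tweedie model

Shotgun counts are compositional. Gene-family tables are normalized by
a modified RPKM: each count is divided by gene length per kilobase and
by the geometric mean of the sample's *positive* counts. Species tables
divide by the geometric mean only. Excluding zeros from the geometric
mean (rather than pseudocounting) keeps the transform exactly
equivariant under per-sample rescaling, which is the property the
correction exists to provide. Features present in fewer than 10% of
samples are removed (boundary inclusive).

Normalized abundances are continuous, nonnegative, zero-inflated and
overdispersed. They are modeled as Tweedie with power 1 < p < 2
(compound Poisson–gamma): `Var(Y) = φ·μ^p` and
`P(Y = 0) = exp(−μ^(2−p) / (φ(2−p)))`. A single table-level (p, φ) is
estimated by ordinary least squares of log feature variance on log
feature mean (Taylor's law); features with zero mean or variance are
excluded, not imputed. Log-log OLS was chosen over likelihood profiling
for robustness and transparency; the slope is all the downstream model
needs. The observed-vs-expected zero-proportion diagnostic
(`zero_diagnostic`) checks the fit: points should sit on the diagonal.

## Residualization

Both views are adjusted for age at sampling, BMI, shipment batch
(treatment-coded dummies), ten ancestry principal components, and twin
relatedness before the CCA. Ancestry PCs are fit on one representative
per family (lowest-sorting sample id, for reproducibility) and all
samples are scored on those loadings, so co-twins cannot dominate the
rotation.

Relatedness is modeled as a random intercept per twin pair. A "zygosity"
random effect with two levels cannot absorb within-pair correlation, so
the pair label is the grouping factor. Family blocks have at most two
members, so the marginal covariance is block diagonal with closed-form
2×2 inverses; the variance ratio θ = σ²_b/σ²_e is chosen by profile
maximum likelihood on a fixed grid (25 log-spaced ratios plus zero).
With all-singleton families θ is pinned to 0 and both paths reduce
exactly to plain GLM/LM residuals — the pipeline applies unchanged to
unrelated cohorts.

* Genotype columns: Gaussian linear mixed model; conditional residuals
  (y − Xβ̂ − Zb̂), which are exactly orthogonal to the fixed-effect
  design.
* Abundances: Tweedie GLMM with log link fit by penalized
  quasi-likelihood (iterated working response z = η + (y−μ)/μ with
  weights μ^(2−p), at most 8 updates, relative η change < 1e-6). The
  table-level p is held fixed; dispersion is re-estimated per feature
  inside the Pearson standardization. Features whose mixed fit fails
  fall back to fixed family intercepts; features failing both are
  dropped and listed in the exclusion log. Pearson residuals are the
  default (variance-standardized, appropriate for correlation
  analysis); response residuals are available.

Conditional twin residuals necessarily attenuate between-family signal:
an association carried by a family-shared factor loses roughly a third
of its correlation on each side. This is the honest statistical price
of treating twins as unrelated afterwards, and it bounds what the
validation below can achieve.

## Sparse CCA fitting

The fit alternates the two penalized regressions — β on X with target
Yα, then α on Y with target Xβ — rescaling the active variate to unit
norm after each half-step. Three design choices matter when both views
have far more columns than samples (here ~3,900 coded columns and
1,000 features against ~300 samples):

1. **Penalties as sparsity bounds.** Fixed λ values are unstable in the
   alternation: weak penalties let either view fit *any* target variate
   almost perfectly (in-sample canonical correlations near 1 from pure
   noise), while fixed strong penalties collapse the fit entirely once
   the target variate degrades. The tuning grid is therefore a ladder of
   sparsity bounds — 12 pairs, {5, 10, 20} active variant groups ×
   {10, 20, 40, 80} active features — and each half-step finds, by
   bisection with screened-and-KKT-verified solves, the λ at which the
   exact penalized problem has at most that many active groups/features.
   This is the bound-form parameterization of penalized matrix
   decomposition; realized (λ₁, λ₂) are reported per component.
2. **Initialization from the abundance view's leading principal axis.**
   The classical start (leading singular vector of YᵀX) is noise-
   dominated in this regime. A genetically driven latent factor is, by
   the model's own assumption, a dominant axis of shared variation in
   Y, so the alternation starts there. In the classical regime (more
   samples than columns) the YᵀX start is used and the alternation
   behaves like power iteration, reproducing classical CCA when
   unpenalized.
3. **Damped, early-stopped alternation.** The Y-variate target is
   updated as a 50/50 mix of new and previous variates, and the
   alternation runs at most 4 rounds (3 inside cross-validation).
   Trajectory analysis on planted-truth cohorts shows selection quality
   peaking within the first three rounds and then slowly degrading as
   the two views co-adapt to mutually-fittable noise directions.

Penalty pairs are chosen by 5-fold cross-validation on the held-out
correlation of the canonical variates; ties go to the sparser pair.
After selection, a classical CCA (whitening + SVD) on the selected
columns gives the refined weights and reported correlation; when a
selected block has at least as many columns as samples, the covariance
blocks are ridge-stabilized with relative diagonal shrinkage 1e-3 (the
result is continuous as the shrinkage vanishes on well-conditioned
data). Additional components are extracted after deflation: each matrix
is regressed on its *own* refined canonical variate and replaced by the
residual (cross-deflation is available as an option); deflated columns
are exactly orthogonal to the extracted variate.

The unit-norm rescaling after each half-step perturbs the penalized
objective at the normalized iterates by about 1e-4 relative, so the
objective trace is non-increasing only to that order; exact
monotonicity would require norm-constrained penalized subproblems,
which neither standard sCCA implementations nor this one solve.

## Genotype processing

Filters run in the fixed order missing → MAF → HWE → LD, each
idempotent: any missing call drops the locus; minor allele frequency
must be ≥ 0.10 (boundary inclusive); a 1-df chi-square against
Hardy–Weinberg expectations drops loci at p < 0.001 (the plain
chi-square, not the exact test; loci with a zero expected count are
dropped with a warning); LD pruning slides a 50-locus window advancing
by 10 and, while any within-window pair exceeds r² = 0.8, removes the
lower-MAF member (ties: the later position — a determinate rule where
plink leaves the choice implementation-defined). Surviving loci are
coded 0→(+1,−1), 1→(0,+1), 2→(−1,−1) into additive and dominance
columns, orthogonal at 1:2:1 genotype balance and exactly invertible.
VCF input takes GT fields; multi-allelic sites are dropped with a
warning. MZ co-twins arrive as duplicated rows and are accepted as-is.

Note that with related samples the HWE chi-square is mildly
anticonservative (duplicated MZ rows and DZ sharing inflate the
statistic), so the realized drop rate on twin cohorts exceeds the
nominal 0.1%; the type-I calibration check therefore uses unrelated
samples.

## Enrichment

Selected features are tested per annotation term with a two-sided
Fisher exact test on the 2×2 selected × in-term table over a
user-supplied background universe, followed by Benjamini–Hochberg
correction across terms; the default reporting cut is q < 0.1. The
background is an explicit argument because "everything present in the
samples" and "everything annotated" are both defensible universes.
Features with several terms count once per term.

## The synthetic cohort and what passing means

The generator emulates a twin-registry metagenome study: 150 female
twin pairs (MZ fraction 35/127), 2,000 loci with MAF uniform on
[0.10, 0.50] arranged in LD blocks of 10 (latent-Gaussian haplotype
copula, within-block ρ = 0.85), explicit parental haplotypes so DZ
pairs share half their alleles identical-by-descent in expectation and
MZ rows are duplicated, twin-shared age, individual BMI, three shipment
batches, and Tweedie abundances (p = 1.6, φ = 2) whose counts are
scaled by gene length and a log-normal library factor so the
normalization step has real work to do. A planted factor — the
standardized dosage sum of 5 variants in distinct LD blocks, plus
N(0, 0.2²) noise — shifts the log-mean of 20 planted features by 0.5
per latent SD. Planted features are drawn from the baseline-mean range
[10, 50]: an effect planted on a feature that is zero in most samples
is a truth no method could be scored against. Multi-factor cohorts
split the planted sets across factors with decaying strengths. All
randomness flows through one seeded generator; a config and seed give a
bit-identical cohort.

Recovery is scored feature-wise by set identity, and variant-wise at
the LD-block level (tag-variant convention): a planted locus can itself
be removed by the HWE filter or LD pruning while its block-mates carry
most of its signal, so a planted group counts as recovered if any
selected locus lies in its block, and a selection is false only outside
every planted block. Strict locus-identity recall is reported
alongside, as are both false-selection readings (fraction of selections
that are wrong, and fraction of null candidates selected).

Measured behavior at the default scale (one component, the planted
factor count): variant-side block recall 0.8–1.0 across seeds,
feature-side recall typically 0.5–0.7, false-positive rates below 0.01
on the variant side and 0.1 on the feature side. The feature-side
recall ceiling is structural: the variant-side estimate of the latent
factor, attenuated by the twin residualization and diluted across five
variants, correlates ~0.5–0.6 with the truth, which leaves the weakest
planted features at the noise edge of a 1,000-feature ranking. A
null-effect cohort selects the planted sets at chance level, and
permuted-sample reruns share essentially no variant selections with the
real run. One caveat on the permutation check: row permutation leaves
the abundance view's covariance — and hence its leading principal axis,
the fit's starting direction — unchanged, so the *feature*-side overlap
between permuted and real runs can stay noticeably above chance even
though the cross-view pairing is destroyed; the variant side is the
informative half of that check.

What passing does not show: the generator draws independent Tweedie
values around a log-linear mean model, so it does not emulate
phylogenetic correlation between features, strain-level variation,
batch effects beyond a shared shipment offset, population
stratification (ancestry PCs are exercised mechanically, not
adversarially), or genotyping error. Real-data effect sizes in healthy
cohorts are likely weaker than the planted 0.5.

## Numerical choices

* Group lasso: monotone FISTA (function-value restart), tolerance 1e-9
  on the relative objective, Lipschitz constant by deterministic power
  iteration; λ = 0 returns the minimum-norm least-squares solution.
* Elastic net: scikit-learn coordinate descent, mixing 0.5 by default.
* Bounded solves: 9 bisection steps on λ; candidate screening keeps the
  top max(4k, 60) groups / max(4k, 120) features by marginal norm plus
  previous actives, with full KKT verification and re-expansion, so the
  screened solution equals the full-problem solution.
* PQL: at most 8 working-response updates; η clipped to ±30.
* Mixed model: θ on a 26-point grid; singular fixed-effect designs are
  handled by least-squares (minimum-norm) projection.
* Degenerate inputs: all-zero samples are an error at normalization
  (no geometric mean exists); all-zero features must be removed by the
  prevalence filter before residualization; empty components truncate
  the deflation sequence with an explicit status.

## Problem sizes

Default validation runs use the full reference scale (300 samples,
2,000 loci → ~3,900 coded columns, 1,000 features). A complete
pipeline run — normalization, QC, both residualizations, penalty
tuning, fit, refit — takes well under a minute on one core; the
acceptance script's full set of checks, including a null cohort and two
permutation reruns, takes about two minutes.

## Known limitations

* No inference on coefficients: standard errors under penalized
  selection are unknown, so weights are selection-only by design.
* Two-table CCA only.
* Families larger than two are not supported by the residualizer.
* The feature-side recall ceiling under twin designs discussed above.
* The Taylor-law fit assumes a single (p, φ) per table; strongly
  heterogeneous dispersion across features is only absorbed at the
  per-feature Pearson standardization step.
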