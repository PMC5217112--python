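# Methods

## The problem and the design

A haploid strain carrying one extra chromosome (a disome) changes the
expression of the genes on that chromosome roughly in proportion to their
copy number, but the transcriptome-wide picture mixes several mechanisms:

1. **cis dosage** — genes on the doubled chromosome, expected at about the
   copy ratio (2x for a disome vs a haploid);
2. **trans regulation** — a dosage-sensitive regulator on the doubled
   chromosome drives downstream genes up or down in proportion (on the log
   scale) to its own expression change;
3. **shared responses** — karyotype-independent programs (stress-response-
   like signatures, consequences of an altered colony phenotype) common to
   different aneuploidies;
4. **nonlinear interactions** — genes whose response to the regulator
   depends on the copy number of the rest of the chromosome, so that no
   single proportionality constant explains their behaviour across
   perturbations.

The supported design contrasts a euploid reference with disomes, a disome
hemizygous for the regulator, a regulator-overexpression strain and its
vector control, in replicate batches each containing its own euploid
control. Batches are normalised and analysed separately throughout; no
between-batch normalisation is attempted.

## Normalization

Scale factors use the weighted-trimmed-mean-of-M estimator: against a
reference sample (the one whose upper-quartile relative abundance over the
reference gene set is closest to the across-sample mean), per-gene log2
ratios M are trimmed 30% on each M tail and 5% on each A (abundance) tail,
and averaged with inverse asymptotic-variance weights; factors are rescaled
to geometric mean 1. Two restrictions matter in an aneuploid design:

- the estimator sees **only nuclear-encoded ORFs on euploid chromosomes**
  (disomic chromosomes and unplaced/noncoding genes are excluded), and the
  resulting factor is applied to all genes;
- "library size" is the count total over that same reference gene set, so
  a disome's extra transcriptional mass inflates neither the factor nor the
  denominator of CPM.

On small fixtures where the reference set is the whole matrix the factors
agree with the reference TMM implementation to ~1e-6 (cross-checked in the
test suite).

For testing genes **on** a disomic chromosome independently of dosage, a
variant doubles the disomic samples' effective library size (twice the
restricted-set factor). Under pure dosage this centres those genes at zero
fold change; residual signal is expression change beyond copy number. In
the pipeline, pairwise contrasts involving a disome are run both ways and
the doubled-run results replace the base-run rows for genes on the disomic
chromosome(s).

Moderated log2 CPM is `log2((count + 2) / effective_library_size * 1e6)`;
the +2 prior stabilises low counts and no library-size moderation is
applied. Two gene filters mirror common practice for noisy colony material:
a **basal filter** keeping genes whose median unmoderated CPM across the
reference-genotype replicates is ≥ 1 (computed on raw CPM, so the boundary
case depends only on true expression, not the prior), and a per-genotype
**variance filter** dropping genes whose replicate variance of moderated
log2 CPM is ≥ 3 from any analysis using that genotype (paralog
cross-mapping and low-complexity regions show exactly this instability).
Genotypes with a single replicate keep all genes, with a warning.

## Differential expression

Counts follow NB(mu, phi) with variance `mu + phi mu^2`, log link, one
coefficient per genotype (cell-means coding) and per-sample offsets equal
to log effective library size. Fitting is iteratively reweighted least
squares, vectorised across genes.

Dispersions are estimated in three steps:

- **raw**: per-gene maximisation of the Cox–Reid adjusted profile
  likelihood (the GLM refit on a 17-point log-spaced dispersion grid with a
  parabolic refinement). The CR term `-0.5 log det(X'WX)` compensates for
  the estimated means; without it the dispersion MLE is biased low at
  few residual degrees of freedom and downstream tests become
  anticonservative (we measured a null p<0.05 fraction of 0.096 instead of
  0.05 in a 4v4 design).
- **trended**: lowess (span 0.3) of the raw estimates against average
  moderated log2 CPM, floored at 1e-6.
- **tagwise**: the convex combination
  `(df_resid * raw + prior_df * trended) / (df_resid + prior_df)` with
  `prior_df = 30`. The moment-form shrinkage guarantees the estimate lies
  between raw and trend. The prior weight was set by simulation
  calibration: with 6 residual df, prior df 10 leaves enough dispersion
  noise in the tail that the BH 0.01 false-discovery fraction reaches
  0.026; prior df 30 restores it to 0.018 with no measurable power loss
  (recall 0.999 on planted 4-fold changes). Heavier trend-anchoring is
  appropriate whenever dispersion varies smoothly with abundance; genuinely
  erratic genes are handled by the variance filter, not the prior.

A contrast `w` over the genotype coefficients is tested by likelihood
ratio: the null model refits the GLM with the design projected onto the
null space of `w` (reduced-basis reparameterisation), the statistic is the
deviance difference against chi-square with 1 df, and `log2FC = w·beta /
ln 2` (a plain A−B contrast yields log2(A/B)). BH-FDR is computed over the
genes that pass the filters, so the correction's m matches the tested set;
all-zero genes are excluded and reported as untested.

**Copy adjustment** subtracts `log2(copy ratio)` of each gene's chromosome
between the contrasted genotypes, using the nominal karyotype ratio (2 for
a disome), not an observed median. Genes on chromosome `unplaced` are never
adjusted. Significant-gene lists apply FDR < 0.01 and ≥ 2-fold adjusted
change by default.

## Interaction analysis

Two perturbation profiles are compared gene by gene: y = hemizygote vs
disome (the regulator halved on a disomic background), x = overexpression
vs vector control (the regulator raised ~4-fold on a euploid background).
Both axes are noisy, so the fitted line is total least squares — the
leading eigenvector of the 2x2 covariance of the centred cloud, sign fixed
to a positive x-component, intercept through the centroid. The rotation
whose first row is that direction (second row the perpendicular, oriented
so points displaced toward +y score positive) maps each gene to (PC1, PC2):
PC1 the shared linear trend, PC2 the signed orthogonal departure. Loadings
are computed on the filtered nuclear-ORF set and then applied to all genes.

If one perturbation multiplies the regulator by `r_up` and the other
divides it by `r_down`, proportional response predicts a slope of
`-log(r_down)/log(r_up)` (base-free) and zero intercept. The fit is
deliberately **unconstrained** — the zero intercept is a model prediction
to compare against, not a constraint. On simulations the fitted slope runs
slightly shallow of the prediction (e.g. −0.54 vs −0.57) because
measurement noise on the many null genes is isotropic and dilutes the
signal direction; the attenuation shrinks as the responding fraction or
depth grows.

Significant second-PC genes are found by the weighted LRT contrast
`(1, −1, |s|, −|s|)` over (hemizygote, disome, overexpression, control),
`s` the fitted slope: on-trend genes satisfy the weighted identity exactly
(verified in the tests: their LRT p-values are uniform), off-trend genes do
not. Significant genes split by contrast sign into "higher than expected in
the hemizygote" vs "lower than expected", with a twofold-deviation flag at
`|contrast| ≥ 1` on the hemizygote (weight-1) log2 scale — the raw, not
copy-adjusted, scale, since both profile contrasts are internally
dosage-matched. Quadrant enrichment of a motif set uses the two-tailed
Fisher exact test (p = sum of hypergeometric outcomes no more probable than
the observed table).

## Gene-set shifts and profile comparisons

Directional shifts of a signed set are tested by a two-sample rank-sum
(Mann–Whitney) on copy-adjusted log2 fold changes, set vs non-member
filtered nuclear ORFs, normal approximation with tie and continuity
corrections (exact enumeration below a combined n of 25); W is the U
statistic of the set sample, as in standard two-sample Wilcoxon reports.
Sets smaller than 5 after filtering are flagged low-power. Profile
similarity is Pearson's R on copy-adjusted fold changes with
`t = R sqrt(df/(1−R²))`, df = n−2; profiles are combined by per-gene means
(descriptive only — p/FDR are nulled).

## The simulator

Per gene: a baseline drawn uniformly on a log2 range (default 0–9,
CPM-scale); per genotype: the additive log2 sum of cis (`log2` copy ratio,
exactly), trans (`coefficient x log2` regulator multiplier), shared
(a common vector scaled per genotype, into which signed set shifts are
folded) and interaction offsets (nonzero only for designated genes).
Per sample: relative abundances renormalised to sum to 1, scaled by a
library size drawn uniformly (default 2–6 million reads, typical bulk
yeast depth), counts drawn NB with dispersion `phi(mu) = asymptote +
slope/mu` (default 0.05 + 2/mu — a Poisson-dominated low end rising to a
biological-CV asymptote of ~0.22), plus optional log-normal replicate noise
(default sd 0.05 log2). Randomness derives from one seed: gene-level
parameters from a root stream, each sample's counts from a child stream
spawned in fixed sample order, so outputs are byte-identical given a
config.

Default design magnitudes mirror the study system: the regulator 1.90-fold
up in the chromosome XVI disome, divided by 2.28 in the hemizygote,
4.25-fold up under overexpression; 30% of genes trans-responsive with
coefficient sd 0.5 (chosen so the fitted TLS slope shows the realistic
mild attenuation rather than being noise-dominated); four replicates per
genotype in batch one.

What the simulator does **not** emulate: read-level error or mappability
(counts are drawn, not aligned), paralog cross-mapping, GC/length bias,
batch-specific technical trends, correlated gene programs beyond the single
shared vector, or compositional extremes beyond whole-chromosome doubling.
Passing tests therefore demonstrate correctness of the estimators under the
generative model the analysis assumes — unbiased dosage recovery, FDR
control, interaction-gene detection — not robustness to artifacts the model
omits; the variance and basal filters are the main line of defence against
those on real data.

## Numerical conventions and degenerate inputs

IRLS runs at most 60 iterations to deviance tolerance 1e-10 with a 1e-12
ridge jitter (keeps all-zero groups solvable); non-converged genes are
flagged. Dispersion search spans 1e-8–10 with the Poisson branch used below
1e-10. TLS requires ≥ 3 finite pairs and raises on zero variance or a
vertical line. Fisher enrichment on an empty quadrant returns p = 1 with a
warning. All writers use 6-significant-digit scientific notation; pipeline
outputs carry a provenance header (package version, config hash excluding
the output path, seed) and reruns are byte-identical.

## Known limitations

- Dispersion/GLM internals are this package's own re-specification of
  standard count-model practice; numerical parity with any particular
  external implementation is a non-goal (the TMM factors, by contrast, do
  match the reference implementation on unrestricted masks).
- The LRT with plug-in shrunken dispersions remains very slightly liberal
  (null p<0.05 fraction ~0.052–0.056 in 4v4 designs); quasi-likelihood F
  tests would tighten this but are out of scope.
- The interaction machinery is the exact two-profile rotation, not a
  general n-profile PCA.
- Basal filtering uses raw CPM; with the +2 prior the boundary would differ
  only for near-zero genes.
- The rank-sum W depends on post-filter set sizes, so W is comparable
  across runs only under identical filtering.
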