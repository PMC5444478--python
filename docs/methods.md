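# Methods

`seminalseq` re-implements, as a tested library, the statistical workflow for
comparing wild-type and mutant maize embryo transcriptomes across three
developmental stages (25, 30, 35 days after pollination; four biological
replicates per genotype/stage cell). This note documents the models, the
numerical choices, and what the synthetic-data experiments do and do not
demonstrate.

## The count model and gene-activity calling

For gene *g* and sample *i*, read counts follow a negative binomial with

    y_gi ~ NB(mu_gi, phi_g),      Var = mu + phi * mu^2
    log mu_gi = beta_{g,cell(i)} + u_{lane(i)} + o_i + o_g

where `cell(i)` is the sample's genotype x stage combination (6 cells),
`u` is a sequencing-lane random effect, `o_i = log` (TMM-effective library
size) and `o_g` is a smooth capture offset in gene length and GC content.
The dispersion `phi_g` is constant within a gene.

Cross-gene priors are

* `beta_{g,c} ~ N(m_c, v_c)` independently per cell (a diagonal-covariance
  multivariate normal over the 6 cells),
* `log phi_g ~ N(m_phi, v_phi)`,
* lane precision `tau ~ Gamma(0.5, 0.005)` (vague; fixed, never updated).

**Inference.** Each gene's posterior over `(beta_1..6, u_1..L, log phi)` is a
Laplace approximation: the mode is found by damped Newton iteration with an
analytic gradient and a finite-difference Hessian (vectorized across genes),
and the Gaussian covariance is the inverse Hessian at the mode. The gamma
prior on the lane precision is marginalized analytically, which makes the
effective prior on the lane-effect vector a multivariate t; this avoids the
funnel-shaped joint mode that plagues hierarchical models when a variance is
optimized together with its effects. Genes whose optimizer fails to converge
or whose Hessian is not positive definite fall back to the prior and are
flagged (conservative: such genes cannot be called active by data they do
not support).

**Empirical Bayes.** The hyperparameters are estimated by an EM-style
moment-matching loop: (1) fit all genes under the current priors (warm
starts); (2) set `m_c` to the mean of posterior means and
`v_c` to mean((b - m)^2) + mean(posterior variance), identically for the log
dispersion; iterate to relative change < 1e-3, at most 25 sweeps. Two
limitations are documented rather than hidden: a constant shift between the
fixed effects and the lane effects is not identifiable (only their sum enters
the likelihood), so `m_c` absorbs the realized mean lane effect; and the
joint-mode Laplace slightly underestimates dispersion (the usual downward
bias of variance-type parameters at a mode), which does not move activity
calls because the call boundary depends on the posterior mean.

**Activity rule.** `P_gts(T) = 1 - Phi((T - mean)/sd)` under the Gaussian
marginal; a gene is ACTIVE in a cell iff `P_gts(T) > 0.5` (strictly), which
for a symmetric marginal is `mean > T`. The numeric threshold `T` is a free
parameter of the method. The default calibrates it against the only count
scale the workflow otherwise uses: `T = log(5) - median(sample offsets)`, the
fixed-effect level at which a gene would produce ~5 expected reads in a
median library. Numerical floors: posterior sd >= 1e-6, phi in [1e-8, 1e3].

## Normalization

* **Expression filter:** a gene is kept when at least one genotype/stage cell
  has >= 5 reads in every replicate. The scope is per cell by default because
  the differential contrasts are per stage; a `genotype` scope (all samples
  of one genotype) is exposed as a switch.
* **TMM factors** follow the published trimmed-mean-of-M-values algorithm
  exactly: genes with zero counts in either column excluded, 30% trimmed from
  each tail of M and 5% from each tail of A, inverse-delta-method weights,
  factors rescaled to geometric mean 1. The automatic reference column is the
  sample whose upper quartile of library-size-scaled counts is closest to the
  mean upper quartile. Agreement with the reference implementation in
  edgeR was verified to 1e-6 during development.
* **FPKM** divides by TMM-effective library size by default (switchable to
  raw), consistent with the model's offsets.
* **Length/GC offsets:** per-gene mean of `log((count + 0.5)/effective size)`
  regressed on additive cubic-regression splines (4 df each) in log length
  and GC; coefficients are estimated on the filtered genes, the smooth is
  evaluated for all annotated genes, and predictions are centered over the
  fitting set. Fewer than 50 genes is refused as unstable.

## Differential expression

Linear models on `log2(FPKM + 0.5)` (pseudocount and scale are the package's
choice, exposed in config) with the 6-cell design. The sequencing lane enters
as a random effect through a consensus intra-lane correlation `rho`: per-gene
REML profiles over a grid of `rho` values (restricted to where the block
covariance is positive definite), consensus by the tanh of the mean atanh.
Contrasts (WT - MUT within stage; later - earlier stage within genotype for
dynamics) are estimated by GLS under that block correlation. Residual
variances are shrunk by matching the moments of `log s^2` to a scaled
F distribution (digamma/trigamma equations; trigamma inverted by Newton),
giving prior df `d0` and prior variance `s0^2`; moderated t statistics use
`(d0*s0^2 + df*s^2)/(d0 + df)` on `d0 + df` degrees of freedom. Degenerate
inputs: equal variances across genes give `d0 = inf` and posterior variances
equal to the common value. Multiple testing is Benjamini-Hochberg within each
contrast (delegated to statsmodels; an exhaustive step-up oracle guards it in
the tests), and a DE call requires both `q < 0.05` and `|log2FC| >= 1`.

## Dynamic patterns

With `t` stages there are `3^(t-1) - 1` non-constant patterns of
consecutive-stage transitions (UP/DOWN/SAME); the all-SAME sequence is not a
pattern. The rule-based classifier is authoritative: a transition is UP when
`q < 0.05` and `log2FC >= 1` (later vs earlier stage), DOWN when
`q < 0.05` and `log2FC <= -1`, else SAME. K-means (Lloyd, k-means++
initialization, 25 restarts, seeded) on z-scored mean profiles is provided
as a companion view only — of the two procedures the study describes, only
the rule-based one is reproducible from stated thresholds.

## Promoter motifs

Promoters are the 1000 bases upstream of the ATG translation start (not the
TSS), strand-corrected, clipped at contig edges with a warning. Scanning is
exact overlapping sliding-window matching of 5'-GCGGCG-3'; N never matches.
The motif is not palindromic, so strand matters: the default scans the sense
strand only, with a `both_strands` switch that also reports CGCCGC-on-sense
hits with their strand.

## Enrichment

2x2 chi-square with Yates' continuity correction,
`sum(max(|O - E| - 0.5, 0)^2 / E)` on 1 df, expected counts from the margins;
the floor keeps near-null tables at zero rather than negative. Category
tables are built per category (in-category vs not x in-set vs rest of
background) against the expressed background — the activity-union set when
available, else the filter-passing set (switchable). Genes with UNKNOWN
synteny are excluded with a logged count. The significance level is 0.01 for
both over- and under-representation. At the small expected counts typical of
32-category tables the Yates test is conservative (its realized size is well
below the nominal 0.01); the null-calibration experiment quantifies this.

## Sample QC

PCA by SVD of the gene-centered log-expression matrix (scores and
explained-variance fractions), and agglomerative clustering of samples on
1 - Pearson correlation with average linkage by default (complete/single
switchable); ties break deterministically by sample order.

## The synthetic-data generator

The generator emulates the study design: 2 genotypes x 3 stages x 4
replicates, 4 lanes (replicate r on lane r in every cell — a realistic
multiplexing layout that makes lane effects estimable), NB counts from the
same model the activity caller assumes. Defaults, with the reasoning:

| parameter | default | meaning |
|---|---|---|
| `baseline_logmean` | N(-10, 1.5) | log per-fragment rate of active genes; ~45 reads in a 1e6-fragment library |
| `inactive_level` | -14.2 | ~0.7 expected reads; 2 natural-log units below the activity threshold |
| `activity_threshold` | -12.2 | the 5-expected-read calibration at libsize 1e6; used for truth labels |
| `inactive_fraction` | 0.2 | nested thresholds: a gene below the cut is inactive in every cell, so activity is mostly constitutive, as observed in real embryos |
| `genotype_specific_fraction` | 0.04 | genes forced active in one genotype only |
| `de_fraction`, effect | 0.10, \|log2FC\| = 1 + Exp(0.7) | DE genes satisfy the \|log2FC\| >= 1 definition by construction; random non-empty stage subset |
| `pattern_fraction`, step | 0.15, 2.0 log2/transition | planted trajectories are centered on the baseline, so the baseline is the gene's average abundance |
| `dispersion` | lognormal(log 0.1, 0.6) | typical bulk RNA-seq biological dispersion |
| `lane_sd` | 0.1 | ~10% multiplicative lane effects |
| `libsize` | lognormal(log 1e6, 0.15) | desk-scale libraries |
| capture | `1.0*log(len) - 2.0*(gc - 0.5)^2`, centered | a parametric stand-in for "a smooth function" with known truth |
| synteny | 51% non-syntenic base, 1.7x odds among DE | mirrors the genome-wide share and the enrichment the analysis is meant to detect |
| motifs | fraction 0.30 of 1-kb promoters | promoters are rejection-sampled motif-free, then GCGGCG planted at a recorded position |

Truth labels are defined from the generating parameters: a gene is truly
active in a cell iff its fixed effect exceeds `activity_threshold`; DE flags
per stage iff the true |log2FC| >= 1; pattern labels by applying the
transition rule to the true fixed effects. `build_genome` embeds each
promoter in a one-gene contig (half on each strand) so coordinate-based
extraction can be validated against the planted sequences exactly.

**What the generator does not emulate:** read-level artifacts (mapping
ambiguity, stacked-read deduplication, positional bias), correlated genes
(truth draws are independent), annotation errors, and any real maize
structure (the synteny and category labels are synthetic). Passing recovery
tests therefore demonstrates correctness of the statistical machinery under
its own assumptions, not performance on the deposited embryo data, whose
headline gene counts are not reproducible without the sequencing archive and
the B73 genome.

## Validation experiments (`seminalseq.experiments`)

Problem sizes were chosen to exercise the estimators at stable scale while
keeping each experiment in seconds on one CPU:

* **Activity recovery** — 2000 genes, half at `T + 2`, half at `T - 2`, four
  replicates; the blind caller's sensitivity and specificity are both ~1.0.
* **Type-I error** — 2000 genes with no genotype differences of any kind;
  the moderated test's fraction of p < 0.05 is ~0.05.
* **Observed FDR** — 10% planted DE genes; the realized false-discovery
  proportion among calls stays below the nominal 5% plus sampling noise.
* **Pattern recovery** — 2000 genes, 30% carrying planted patterns with
  2-log2 steps, baselines N(-8.5, 0.5) so every planted trajectory stays at
  roughly >= 20 expected reads. The narrow baseline is deliberate: the
  experiment isolates classifier correctness from detection power. Under the
  generator's default abundance distribution, carriers whose trajectories
  dip to a few reads are undetectable at 4 replicates and overall recovery
  drops to ~0.88 — a power limit of the design, reported here so the 0.95+
  recovery figure is not over-read.
* **Hyperparameter recovery** — `beta ~ N(2, 1)` per cell; the recovered
  prior mean is compared against truth plus the realized mean lane effect
  (the identifiable quantity), the prior sd against 1.
* **Enrichment null calibration** — uniformly drawn DE sets over 32
  categories, 200 rounds; significant categories per round (never more than
  ~2, mean well under the nominal 0.32).

## Known limitations

* The activity model's dispersion point estimates are biased low (joint-mode
  Laplace); rank-based and call-level results are unaffected.
* The value of the activity threshold `T` in the original study is unknown;
  all activity counts depend on it, so only threshold-relative behaviour
  (monotonicity, recovery under stated separations) is validated.
* FPKM+pseudocount log modelling loses power and attenuates fold changes
  below ~5 reads; count-based quasi-likelihood tests are out of scope.
* The lane design must cross lanes with cells for `rho` to be estimable; a
  single lane degrades gracefully to `rho = 0` with a warning.
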