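# Methods

This note documents the statistical machinery, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
design decisions taken where more than one reasonable choice existed.

## Study design emulated by the generator

The generator reproduces the structure of a three-arm acute-intervention
cohort: endurance (EE), resistance (RE) and non-exercise control (CON)
arms randomized roughly 8:8:3 (defaults 65/73/37 participants, fully
configurable), three tissues (skeletal muscle, adipose, blood) with
tissue-specific timepoints, and a second randomization to a *temporal
profile* (all / early / middle / late) that decides which post-exercise
collections a participant undergoes. Fixed rules: every participant has a
pre-exercise sample in all three tissues; blood is drawn during exercise
only in EE and CON (no draws during resistance bouts); the immediately-post
blood draw exists in all arms. Timepoint codes are normalized to
`{Pre, D20M, D40M, P10M, PEarly, PMid, PLate}` with the tissue-specific
minute mapping early = 15/30/45 min (muscle/blood/adipose), mid = 3.5/4 h,
late = 24 h.

Profile mixture: no published proportion exists for the profile
randomization, so the default assigns the four profiles with equal
probability; allocation uses largest-remainder exact counts within each arm
so the realized missing-cell fractions equal the configured mixture up to
integer rounding.

## Non-normal repeated measures

Molecular values decompose as

```
y = mean + participant intercept + correlated non-normal residual + planted effect
```

with the intercept variance equal to `ICC x total variance`. Residual
margins are generated by Fleishman third-order polynomials
`Y = a + bZ + cZ^2 + dZ^3` solved from target (skewness, excess kurtosis)
by a hybrid root solve (residual tolerance 1e-8; pairs violating
`gamma2 >= gamma1^2 - 2`, or failing all starts, raise an explicit
inadmissible-moments error). Cross-timepoint dependence uses Vale-Maurelli
intermediate correlations: the pre-transform correlation solving the cubic
polynomial relation, assembled into a matrix and eigenvalue-clipped to PSD
when needed. This family was chosen because it is closed-form,
moment-exact, and standard for simulating non-normal multivariate data; the
generator matches first four moments and correlation only, not full
marginal families.

Counts path: the continuous latent value is mapped through `exp` and
Poisson-sampled with per-sample log-normal size factors
(`log-mean log(50)`, `log-SD 0.3` by default) — enough mean-variance
structure to exercise the CPM/TMM/weights path realistically, without
assay-specific artifacts (TMT plexes, UMI duplication are out of scope).

What passing tests on these data do *not* show: robustness to batch
structure correlated with arms, to informative (non-design) missingness, or
to marginal distributions outside the power-method family.

## The differential-analysis engine

The cell-means model has one fixed-effect column per observed
(group, timepoint) cell plus covariates (site, age, sex, BMI; continuous
covariates centered, categorical ones treatment-coded), a participant
random intercept, and optional per-observation precision weights. The REML
criterion is profiled to the variance ratio `lambda = sigma_b^2/sigma_e^2`
and minimized on the log scale over `[e^-12, e^12]`, with the `lambda = 0`
boundary always checked — a design with one observation per participant
therefore reduces exactly to OLS/WLS. All per-participant quantities use
Sherman-Morrison closed forms, so one fit plus one contrast takes ~2-5 ms,
which is what makes the 5,000-replicate calibration studies routine.

Contrast degrees of freedom use the Satterthwaite approximation:
`df = 2 g^2 / (grad g' A grad g)` where `g` is the contrast variance as a
function of `(sigma_b^2, sigma_e^2)` (numerical central-difference
gradient) and `A` is the inverse curvature of the REML log-likelihood
(numerical Hessian). If the curvature is singular or yields a non-positive
quadratic form — typical when the intercept variance collapses to the
boundary — the residual degrees of freedom are used as the fallback, and
the Satterthwaite value is capped at the residual df. This choice hits the
small-sample calibration target (empirical type-I error within [0.04, 0.06]
at n = 20/20/10 under a Gaussian null) that simpler df rules miss.

Eligibility follows the paired-participant floor: a feature-contrast is
tested only if every involved arm has at least 3 participants with both the
pre-exercise and the target timepoint observed. BH adjustment is applied
within each (contrast kind, group, timepoint) stratum; tissue and ome are
fixed within one results table, so this matches stratification by the full
contrast-group-tissue-ome-timepoint combination.

Response classification (exercise effect / control-driven /
non-exercise change) is a declared rule over three significance bits — the
delta-delta call, the within-exercise-arm change and the within-control
change — because only the category names, not the Boolean rule, are
published; the rule is documented in `classify_response` and recovered on
planted scenarios in the tests.

Variance-explained fractions use a sequential (type-I) orthogonalized
decomposition over covariate blocks, which is exactly additive (fractions
plus residual sum to one) at the cost of order dependence; the order is the
caller's covariate order. PC-covariate association reports the canonical
correlation of each leading principal component with each covariate block
(for a single PC this is the square root of the regression R^2).

An empirical-Bayes residual-variance squeeze is deliberately not applied:
the weighted random-intercept strategy exists in the simulation study, and
moderation settings are not published; contrasts are tested on the plain
REML fit.

## Model-selection simulation study

Six strategies share the identical delta-delta hypothesis: paired
change-score t-test, cell-means OLS (ignoring clustering), the
random-intercept LMM (unweighted and weighted), an unstructured-covariance
MMRM (iterated available-case GLS), and GEE with AR(1) working correlation
and the uncorrected robust sandwich — uncorrected on purpose, so the known
small-sample anti-conservatism of the sandwich is visible; a bias-corrected
run is a caller option via statsmodels. The published strategy list counts
seven but enumerates six; the weighted-LMM variant is implemented as the
seventh. Replicate counts default to desk scale (thousands per arm rather
than millions); the acceptance calibration uses 5,000 null replicates at the
full 65/73/37 design, which yields a Monte-Carlo standard error of about
0.3 percentage points on the type-I error.

Analytic power uses the exact noncentral-t: two-sample power at
`ncp = d sqrt(n/2)` on `2n - 2` df, and the 2x2 interaction contrast
`(mu11 - mu12) - (mu21 - mu22)` with standard error `2/sqrt(n)` per unit SD
on `4(n-1)` df — whence the "interaction needs double the effect" rule:
the interaction test at effect `2d` with half-size cells has the same
noncentrality as the main-effect test at `d`.

## Temporal clustering

Signed z-scores `sign(estimate) x Phi^-1(1 - p/2)` (capped at |z| = 40 when
p underflows) are computed per feature and contrast column, genes collapse
to the most extreme z (sign preserved), during-exercise contrasts are
excluded, and each row is divided by the sample SD of its values plus two
appended zeros — the zero anchor representing the identically-zero
pre-exercise baseline, which prevents flat-but-offset profiles from being
inflated. Fuzzy c-means uses Euclidean distance, the heuristic fuzzifier
`m(N, D)` from the expression-clustering literature, seeded initialization
by sampling k distinct rows, and 10 restarts keeping the best objective
(the published analysis does not state its restart policy). The validity
index is the minimum pairwise centroid distance scanned over k = 3..14; it
stays high while centroids track distinct temporal shapes and collapses
once clusters split, so the programmatic elbow is the k immediately before
the largest drop — with manual override supported, since the published
cluster counts were chosen by inspection. Hard assignment takes the argmax
membership when it is at least 0.3 (ties to the lowest cluster index);
below that, features stay unassigned.

## Enrichment

The parametric pre-ranked competitive test compares the mean statistic of a
set against the rest with pooled variance and a variance-inflation factor
`VIF = 1 + (m-1) rho` on `G - 2` df; at `rho = 0` it reduces exactly to the
two-sample t-test. The rank variant uses the set rank sum with the
arcsine-identity null variance, which reduces to the Wilcoxon variance
`mn(m+n+1)/12` at `rho = 0`; midranks handle ties and the normal
approximation supplies p-values (upper-tailed for cluster-membership
enrichment, two-sided for contrast enrichment). The default `rho = 0.01`
follows the test's convention and is configurable. Set filtering: at least
5 members present, and gene sets additionally retain at least 70% of their
original members (both boundaries inclusive); metabolite-class and kinase
collections apply only the size floor. BH runs within each collection;
significance is 0.05 except kinase collections at 0.1. Multi-site
phosphosite ids split into single sites carrying the same statistics, with
duplicates resolved by maximum |z|.

## Exerkine funnel

Tissues and plasma align on ordinal timepoint ranks (during-exercise draws
precede all post ranks; early/mid/late share ranks across tissues). A gene
is matched when at least one tissue feature and at least one plasma protein
both pass adjusted p < 0.1 (strict). Concordance compares the signs of the
most significant effect on each side — the "most significant" convention is
this package's declared rule for the case where signs differ across
timepoints. Precedence requires the earliest significant tissue rank to be
at or before the earliest significant plasma rank. The extracellular score
is the maximum over the four extracellular compartments (region, space,
exosome, vesicle; 0-5 scale; absent genes score 0); primary candidates
need score strictly greater than 4 *and* a plasma increase. The bundled
compartment table builder is synthetic — real compartment databases are
optional inputs, never required. Biweight midcorrelation uses Tukey
weights `(1 - u^2)^2` inside `|u| < 1` with `u = (x - med)/(9 MAD)`,
falling back to Pearson when a MAD is zero; gene-program context feeds
z-scaled bicor values into the parametric competitive test.

## Networks and motif scores

Regulator matrices drop rows with more than 40% missing values (40% kept),
impute the rest by 15 chained-equation imputations averaged (observed
values never change), and optionally restrict to transcription-factor
genes. Edge weights come from a pluggable backend — tree-ensemble feature
importance (seeded) or absolute partial correlation — normalized to sum to
one per target; a feature serving as both regulator and target is excluded
from its own regression. Trimming pools all edge weights from 100
sample-shuffled re-inferences into one null distribution (pooled rather
than per-edge, as the per-edge choice is unpublished; with importances
normalized per target, weights are exchangeable across edges), assigns
upper-tail rank p-values with add-one continuity, BH-adjusts, and keeps
edges with adjusted p < 0.05 and weight strictly greater than 0.1.
Modality networks merge by edge union with per-modality rows retained.
Motifs are counted exhaustively: FFL (A->B, A->C, B->C), diamond (A->B,
A->C, B->D, C->D, mid pair unordered), and 3-chain (A->B->C, including
chains inside FFLs); the NMS is the unweighted sum of a node's
participation counts (per-motif weights are exposed in configuration, as
the cited scoring allows weighting but prints none).

## Numerical conventions and degenerate inputs

- CPM low-count filter: keep features with CPM > 0.5 in at least 10% of
  samples. The keep direction is standard practice; the boundary (exactly
  10%) is inclusive. Zero-total-count samples are an error naming the
  sample.
- TMM: reference sample by 75th-percentile CPM closest to the mean; double
  trim 30% (M) and 5% (A) by ranks; precision weights from the asymptotic
  binomial variance; factors normalized to geometric mean 1. Verified
  against an external reference implementation on a frozen fixture to 1e-8.
- Proteomics: quantification in fewer than 30% of samples removes a
  feature (exactly 30% retained); per-sample median centering is exact and
  idempotent.
- Metabolomics: duplicates averaged, nonpositive values to missing, > 20%
  missing dropped (20% kept), kNN imputation (k = 10, over feature vectors)
  when more than 12 features remain else half-minimum, `log2(x+1)`, then
  median-MAD scaling (MAD x 1.4826) unless sample medians or upper
  quartiles associate with sex or sex-stratified group at Kruskal-Wallis
  p < 0.01. Redundant metabolites resolve to the platform with the lowest
  reference-standard CV; ties break lexicographically; ids with no CV fall
  back to the platform with the most observed values.
- PCA outliers: boxplot whiskers at `m x IQR` on the first `n_pcs` scores
  (m = 5 metabolomics, 3 affinity proteomics); requesting more PCs than the
  matrix rank is an error.
- Batch regression fits `[protected | centered batch indicators]` jointly
  and subtracts only the batch component, so protected estimates are
  unchanged to 1e-8; batch collinear with the protected design is refused
  outright rather than silently absorbed.
- FCM: distances floored at 1e-300 before the membership power; a centroid
  whose total membership mass collapses (duplicate points) is re-seeded
  from the data.
- Seeds: one master seed; every stream derives from
  `SeedSequence(master, spawn_key=...)` with fixed keys per stage, so any
  stage is reproducible in isolation.

## Desk-scale problem sizes

Defaults are sized for interactive runs: the demo pipeline uses a
36-participant cohort with 200 genes (~30 s end to end); the calibration
study uses 5,000 null replicates at the full 65/73/37 design (~1 minute);
strategy-comparison defaults are thousands of replicates per arm. All sizes
are parameters; the statistical machinery is unchanged at larger scale.

## Known limitations

- The random-effect structure is a single participant intercept; random
  slopes, heteroscedastic participants and Kenward-Roger df are out of
  scope.
- The MMRM uses available-case covariance iteration with a
  participants-minus-arms df rule, adequate for the comparison study but
  not a full REML MMRM.
- The generator's count path models library size and overdispersion but
  not zero inflation or transcript-length bias.
- Cluster-count selection is a heuristic suggestion; like the original
  analyses, final k is a judgment call supported by the scree trace.
- The sequential variance decomposition depends on covariate order;
  reporting conventions should fix the order once.
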