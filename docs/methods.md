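# Methods

`recipro` re-implements, as a tested pipeline, the statistical analysis of an
elevational reciprocal-transplant experiment on maize landraces: four
populations (Mexican Highland, Mexican Lowland, South American Highland,
South American Lowland; 30 accessions each, organised in within-continent
latitude pairs of one highland and one lowland accession) grown in a lowland
(54 m) and a highland (2852 m) common garden, two complete blocks per garden,
one row of 15 seeds per accession per block, two tagged plants per row.  This
note records the models, the numerical choices, and what the synthetic data
generator does and does not emulate.

## Derived traits

Row-level survival counts combine with plant-level ear traits into two
fitness indices:

    FITplantveg = PE/15 * sqrt(EN)
    FITplant    = PE/15 * sqrt(EN) * EW

PE is the row's ear-producing stand count (so survival to reproduction is a
row property), EN the tagged plant's ear number (square-rooted to discount
secondary ears), EW the primary-ear weight in grams.  `FITplant` is missing
wherever EW is; `FITplantveg` is defined whenever the row was scored.  The
plant-level EN (not a row mean) enters the product; a row-mean variant is a
one-line change in `traits.add_derived_traits` if ever needed.  Barrenness is
`BRN = 1 - PE/STD` (missing when STD = 0), the anthesis-silking interval is
`ASI = DTS - DTA` with negative values preserved (early pollen shed is
biologically meaningful), and carbon isotope composition is
`delta13C = (R_sample/R_standard - 1) * 1000` per mil against the Vienna Pee
Dee Belemnite standard.

## REML engine

All mixed models are Gaussian with independent random intercepts:
`V = s2_e I + sum_k s2_k Z_k Z_k'`.  Fixed effects are profiled analytically;
the restricted likelihood is maximised over log-variances by L-BFGS with the
analytic score, then polished with Newton steps on the active (interior)
components targeting a score norm of 1e-10 (fits are declared converged
below 1e-4 on the scaled log-variance score, far inside the tolerance of
standard mixed-model software).  This reaches the
closed-form optimum to ~1e-12 on balanced designs (the test suite checks
equality with the ANOVA method-of-moments estimator and, via `Rscript`, with
lme4 on a crossed design).  Variances are bounded below by zero; a component
whose scaled estimate falls below 1e-9 is reported as exactly 0.  With no
random terms the fit reduces to closed-form OLS REML (`s2 = RSS/(n-p)`).
Cholesky factorisations get an escalating diagonal jitter (from 1e-12 of the
mean diagonal) only when extreme variance ratios make `V` numerically
indefinite during line search.

Contrast inference uses the Satterthwaite approximation:
`g(theta) = c'(X'V^-1 X)^-1 c`, `df = 2 g^2 / (grad g' Cov(theta) grad g)`,
with `Cov(theta)` from the observed information of the restricted likelihood
(central differences of the analytic score; boundary components held fixed).
df is clamped to `[1, n-p]`; in the OLS limit it equals `n-p` exactly, which
makes two-group contrasts reproduce the pooled two-sample t test.  On
balanced G x E designs the resulting estimate/SE/df triples match
lmerTest + emmeans output.

## The G x E model and its contrasts

Per trait:

    TRAIT ~ GARDEN * CONTINENT * ELEVATION + BLOCK:GARDEN
            + (1|LATITUDE) + (1|LATITUDE:GARDEN)

GARDEN is the common-garden site, CONTINENT/ELEVATION the origin classes,
BLOCK is nested in GARDEN (non-reference block dummies within each garden).
LATITUDE is taken to be the latitude-pair identifier — the design groups
accessions into 1-degree bins realised as pairs, and the pair id is the
finest latitude grouping the data define.  Plant-level traits are analysed at
plant level and row-level traits at row level; plants are never averaged to
rows.  Marginal means for a (garden, continent, elevation) cell average the
fixed-effect prediction over blocks with equal weights (unweighted-grid
least-squares-means semantics).  Twelve contrasts in three families of four
(between gardens within each population; between continents within garden and
elevation class; between elevation classes within garden and continent) are
tested at the Bonferroni-corrected per-test level `alpha = 0.05/4 = 0.0125`.

## Q_ST / F_ST scan

For each trait and contrast, phenotypic variance is partitioned on the
contrast's accessions with

    TRAIT ~ 1 + (1|POPULATION) + (1|LINE) + (1|GARDEN) + (1|BLOCK in GARDEN)

and `Q_ST = s2_GB / (s2_GB + 2 s2_GW)` with `s2_GB` the POPULATION and
`s2_GW` the LINE component.  The LINE component is used as-is (broad-sense,
h2 = 1); a heritability rescaling argument exists but defaults off.  For the
pooled contrasts (all High vs all Low, all Mex vs all SA) POPULATION means
the two contrast sides; for the within-continent contrasts this coincides
with the predefined populations.  The model is fit on the contrast subset,
not on all four populations with post-hoc pairing.

Per-SNP Hudson F_ST between the two accession groups uses the finite-sample
form

    fst = [(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)]
          / [p1(1-p2) + p2(1-p1)]

with n the allele counts (2 x genotyped individuals), missing calls excluded
per marker, negative estimates retained and no MAF filter by default.
Per-SNP values are kept (no ratio-of-averages pooling) because the
significance rule needs the distribution: a trait is flagged when
`Q_ST > mean(F_ST) + 2 SD(F_ST)`.  The two corrections are summed before
subtracting so the estimator is bitwise symmetric in the two groups.
Averaging per-SNP ratios under a Balding-Nichols truth sits slightly below
the generating F (about 0.086 at F = 0.10 with these sample sizes) — a
property of mean-of-ratios estimators, within the calibration tolerance used
here, and worth remembering when reading mean-F_ST values as absolute
differentiation levels.

With only two populations the between-group component has a single degree of
freedom, so neutral Q_ST estimates are heavy-tailed; the mean + 2 SD rule is
calibrated empirically in the acceptance checks (neutral flag rate <= 10%,
3-sigma divergent shifts flagged >= 90%).  The parameter-recovery study for
Q_ST uses 8 populations x 15 lines: the check targets the *median* of
replicate estimates, and with few populations the median of a
chi-square-shaped between-group estimator sits visibly below its mean (with
3 df the gap is ~0.06 in Q_ST units), which would measure estimator-shape
bias rather than implementation error.  Eight populations make the median an
honest probe while keeping 50 replicates inside a couple of minutes.

## Environmental distance

`DISTANCE = Value_GARDEN - Value_ORIGIN` for each of elevation plus the 19
bioclim-style variables.  (Note the sign: a negative distance means the
origin value exceeds the garden value.)  Stage 1 regresses accession-by-
garden mean `FITplantveg` on DISTANCE, absorbing unequal mean fitness between
gardens and any linear trend; stage 2 regresses the stage-1 residuals on
DISTANCE + DISTANCE^2 and reports the quadratic coefficient's t, two-sided p
(t distribution on n-3 df) and the stage-2 R^2.  Variables are tested
independently with no cross-variable multiplicity correction (a correction
option exists but defaults off, since per-variable p values are the quantity
of interest).  Under the null the p-values are uniform (checked by
Kolmogorov-Smirnov at 2000 replicates) and the nominal 5% level is held to
within +/- 1%.

## Correlations and clusters

Garden-specific Pearson correlations use pairwise-complete observations,
with plant records inheriting their row's row-level traits so mixed-level
pairs correlate at plant level.  Significance defaults to the t-test on r
(`t = r sqrt((n-2)/(1-r^2))`, n-2 df — the behavior of R's `cor.test`); a
Fisher-z normal test is available via `method="fisher-z"`.  delta13C is
excluded by default from both the correlation panel and the trait-cluster
step (its sample is much smaller than the other traits').  Trait clusters
come from average-linkage hierarchical clustering on distance `1 - r`, cut
to k = 5 clusters by default.

## Synthetic data generator

Genotypes follow the Balding-Nichols model (ancestral frequency
Uniform(0.05, 0.95), per-population Beta draw parameterised by F, dosages
Binomial(2, p) — Hardy-Weinberg within populations), with F = 0.05 by
default, 2000 markers (a scaled-down stand-in for the ~67k marker panel) and
2% missing calls.  Markers are independent: no linkage disequilibrium,
recombination map, or spatial autocorrelation of origins beyond the latitude
pairing.  Origins place High accessions at 2100-3400 m and Low at 60-950 m;
bioclim variables are affine in elevation plus noise, emulating the strong
collinearity of real bioclim panels; the two gardens sit at the real site
elevations (54 m, 2852 m).

Continuous traits follow the Gaussian random-effects model that the analysis
assumes, with field-plausible means and variances per trait (e.g. plant
height: mean 220 cm, residual SD ~19 cm) and a shared population x garden
offset matrix scaled per trait: the default pattern is +1 at a population's
home-elevation garden and -1 away, which generates crossing reaction norms —
the local-adaptation signature.  Survival and ear counts are
Binomial(15, p_survival) and Binomial(STD, p_ear) with probabilities decaying
as `env_decay * (elevation distance in km)^2` (default -0.02 per km^2,
clipped into [0.01, 0.999] with a warning), which is what makes fitness fall
with environmental distance.  EN is 1 + Poisson(0.4), EW is lognormal with a
site x population location, and ordinal 0-4 scores threshold a latent
Gaussian at its {0.2, 0.4, 0.6, 0.8} quantiles (uniform category usage; the
percent-extent traits multiply the score by 25).

Every draw comes from an RNG stream keyed by (seed, purpose-name) via CRC-32,
so outputs are bit-reproducible and adding a trait never perturbs another
trait's draws.

What the generator does *not* emulate — hence what passing tests do not show
about real data: no plot-level spatial field effects, no virus-year
replanting (each garden is a single season), no genotype-specific
heritable variation in the survival probabilities themselves (fitness
heritability arises only through the origin-elevation decay, so fitness-trait
line components can legitimately hit the zero boundary and Q_ST for fitness
can be extreme), no selection-driven marker-trait associations (genotypes
and phenotypes are independent given population labels), and no missing-data
mechanism beyond marker-wise random dropout.

## Default problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen to keep Monte-Carlo error well inside each tolerance: F_ST
consistency at 2 pops x 200 lines x 2000 SNPs; scan calibration at 100
replicates of 2 pops x 30 lines with 500 SNPs; Q_ST recovery at 50
replicates of 8 pops x 15 lines; the environmental-distance null at 2000
replicates of n = 240 (the number of accession x garden units in the full
design); crossing checks at 10 replicates.  The full-design pipeline (120
accessions, both gardens, all traits) runs end to end via
`recipro run`.

## Known limitations

* Ordinal 0-4 scores are analysed as numeric responses throughout (mirroring
  the field practice the pipeline reproduces); no threshold model is fit.
* The predefined populations are geographic/elevational bins, not
  demonstrated demes; Q_ST/F_ST results inherit that caveat.
* Satterthwaite df relies on the asymptotic covariance of the variance
  parameters; with very few grouping levels it is approximate (df is clamped
  to [1, n-p]).
* The Hudson mean-of-ratios offset noted above (~-0.015 at F = 0.10) is a
  property of per-SNP averaging, retained deliberately because the 2-SD rule
  operates on the per-SNP distribution.
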