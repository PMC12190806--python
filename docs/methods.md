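# Methods

This note records the statistical models implemented in `effscape`, the
choices made where the methodology was genuinely open, and what the
synthetic generator does and does not emulate.

## Data model

The canonical representation of a census is a unit × functional-group
**count** matrix (units are site × season combinations). Published census
tables usually print percentages; `core.read_assemblage` detects percentage
rows (group columns summing to ~100 next to a `total` column) and converts
them by `round(total · pct / 100)`. Percentages are never propagated
downstream because the diversity estimators and their bootstrap need integer
totals. Reconstruction is validated by re-normalising: the packaged census
reproduces every printed percentage to 0.1. The packaged table carries a
documented internal inconsistency — its per-population totals sum to
4785 (spring) and 1944 (summer) while its own pooled "Total" columns print
4625 and 2104 — which the reader reports but does not attempt to resolve;
all analyses here use the per-population reconstruction. One unit (Baza in
summer) was never sampled and is kept as an all-zero row, flagged, and
dropped before any dissimilarity computation (Bray–Curtis is undefined on an
empty assemblage).

Seasons and morphs are closed two-level vocabularies; unrecognised labels
are hard errors rather than new factor levels.

## Alpha diversity

Hurlbert's PIE is implemented once: the plug-in form
`N/(N−1)·(1−Σp̂ᵢ²)` is algebraically identical on counts to the unbiased
pair-count estimator `1−ΣXᵢ(Xᵢ−1)/(N(N−1))` (the Simpson-type asymptotic
estimator reduces to this form for abundance data), so no separate
"bias-corrected" code path exists. Uncertainty comes from a multinomial
bootstrap (default B = 1000 resamples of N individuals from p̂): SE is the
SD of replicate PIEs, the CI is the percentile interval, and two assemblages
are declared different when their 95 % CIs are disjoint. The resampling unit
is the individual insect, not the census: the comparison of interest pools
counts per season. B < 100 warns rather than errors.

## Composition (beta diversity)

Bray–Curtis dissimilarities feed both the permutational MANOVA and the
ordination. **The default input is the raw count matrix**, not relative
abundances. Both are defensible a priori; on the packaged census the
count-based analysis reproduces the study system's published statistics
(season pseudo-F 3.77 vs 3.66 printed; population 0.96 vs 0.91; two-axis
variation 61 % vs 56 %) while the proportion-based one is qualitatively
incompatible (season F 8.5, 79 %), so counts were adopted as the default and
`scale="proportions"` kept as an option. The residual gap is expected: the
original analysis used survey-level raw data, whereas this package works
from the pooled published table.

The permutational MANOVA partitions the Gower-centred inner-product matrix
`G = −½ J D² J` by **sequential (entry-order) sums of squares** over nested
hat matrices, so a covariate listed first (population) is removed before the
term of interest (season) is assessed; pseudo-F uses the full-model residual
mean square, and p-values use free permutation of units with
`p = (1 + #{F* ≥ F}) / (1 + n_perm)`. The implementation was verified to
machine precision against vegan's `adonis2` (two-factor sequential) and
scikit-bio's `permanova` (single factor); those values are frozen in the
test suite. Type-I error is calibrated on null synthetic censuses
(rejection rate at α = 0.05 within [0.03, 0.07] over 500 scenarios).

PCoA is the eigendecomposition of the same centred matrix; coordinates are
eigenvectors scaled by √eigenvalue, and the variation share of an axis is
its eigenvalue over the **sum of positive eigenvalues** (the cmdscale
convention; scikit-bio divides by the full trace instead, which is why only
coordinates, not proportions, are cross-checked against it). Negative
eigenvalues — expected for Bray–Curtis — are reported, excluded from the
denominator, and never "corrected". Functional groups are projected onto
axes by the correlation method: score = Pearson r(group abundance across
units, axis coordinate) × axis SD; zero-variance groups score 0 with a
warning.

## Preference

Jacobs' D is computed on pooled counts per group (ratio of sums over
trials), not as a mean of per-trial indices: per-trial visit counts are in
the single digits and the pooled ratio is the stable estimator. The
denominator is evaluated as `r(1−p) + p(1−r)` to avoid cancellation at the
saturation boundaries. Availability `p` comes from the open-flower counts
recorded per trial (not the nominal plant ratio), pooled flower-weighted
over the trials in which the group appears. The goodness-of-fit test
compares the pooled visit split with expected counts proportional to
availability (χ², 1 df), switching automatically to the exact binomial test
when any expected count is below 5. Groups with fewer than 20 pooled visits
(configurable) are flagged as insufficient rather than dropped.

## Effectiveness

QTC divides a group's visit total on a morph by the total plant-observation
hours on that morph — the denominator is survey effort, shared across
groups. QLC divides viable seeds by **visited flowers** (not fruits):
a visit that sets no fruit is a real datum about per-visit quality.
Effectiveness is the exact product; a group missing either component is
omitted from the landscape rather than imputed. Seed shares within a morph
are effectiveness values normalised to 1.

Deviance tests for among-group differences use logit-link binomial GLMs
(IRLS via statsmodels), reporting the likelihood-ratio deviance between the
intercept-only and the factor model with a χ² p-value on (levels − 1) df.
For a single categorical predictor the fitted level proportions equal the
pooled observed proportions, which gives a closed-form deviance used as the
test oracle. Two response codings are supported, matching the two reported
uses: per-flower (viable seeds, ovule total) for the morph comparison, and
fruit-set successes per flower. Coefficients are clipped at ±30 on the
logit scale under complete separation.

The visitation-vs-effectiveness comparison feeds PIE with integer seed
counts obtained by largest-remainder apportionment of effectiveness shares
over the morph's seed (or visit) total, so the N/(N−1) correction stays
defined; both weightings then run through the identical bootstrap and the
CI-overlap verdict.

## Landscape diagnostics

Both effectiveness axes are min-max scaled to [0, 1] before any spatial
statistic, making the window the unit square and nearest-neighbour distances
comparable across axes. This is an interpretive choice: the axes have
incommensurable units (visits · plant⁻¹ · h⁻¹ vs seeds · visit⁻¹), and
nearest-neighbour statistics need a common metric; the scaling is monotone
and invertible from the stored ranges.

Clark–Evans R is the mean observed nearest-neighbour distance over its CSR
expectation; the Donnelly correction inflates the expectation to
`0.5√(A/n) + (0.0514 + 0.041/√n)·P/n` (area A, perimeter P), so the
corrected R never exceeds the uncorrected one. Hopkins–Skellam
`A = Σ d²(event→nearest event) / Σ d²(origin→nearest event)` with as many
uniform sampling origins as events; clustered patterns give A < 1.
Significance for both is the two-sided Monte-Carlo rank among CSR
simulations of n points in the same window (the standard null for these
statistics; the default is 1000 simulations). Calibration note: the
Monte-Carlo test is exactly calibrated by construction, and the mean of R
under CSR is ≈ 1 (the Donnelly correction's purpose), but the **mean of A
under CSR sits above 1 at small n** (≈ 1.19 at n = 20): the numerator's
nearest-neighbour distances see n−1 events where the denominator's origins
see n, and a ratio of sums of ~n skewed terms is itself right-biased. This
finite-sample bias is a property of the statistic, affects no p-value, and
vanishes as n grows.

The cluster count is the majority vote of ten validity indices — silhouette,
Calinski–Harabasz, Davies–Bouldin, Dunn, C-index, McClain–Rao,
point-biserial, gap statistic (20 uniform reference sets, one-standard-error
rule, fixed internal seed), Hartigan (threshold 10) and Krzanowski–Lai —
each evaluated on Ward-linkage partitions over k = 2…8 (truncated with a
warning when points are scarce). A fixed, fully specified panel replaces
the larger published panels whose membership includes graphical/subjective
indices; the panel is part of the public API. Ties go to the smaller k and
are recorded. The whole vote is deterministic given the points.

The QTC–QLC association is the Pearson correlation on the raw (unscaled)
components with the two-sided t-test; a positive correlation flags
functionally specialised systems.

## Synthetic generator

`synthetic.paper_like()` encodes the study conditions: ten main functional
groups; season abundance vectors equal to the published pooled census
margins renormalised over those groups (spring dominated at ~70 % by
long-tongued large bees, summer much more even); Jacobs' D targets of ±0.2–
0.6 matching the published preference directions; overall visit rates of 8
(spring) and 4 (summer) visits · plant⁻¹ · h⁻¹ apportioned by abundance; and
two-stage seed models with m = 24 ovules and per-group quality chosen so
spring seed production concentrates in the dominant group (~78 %, beeflies
~11 %) while summer seed production is spread more evenly than visits.
Sample sizes mirror the study design: censuses of 4625/2104 insects over six
sites, 200 five-minute trials with ~120 open flowers per morph, 600
five-minute watches per morph, 40 single-visit flowers per group × morph.
The 80/20 split of failed ovules into unfertilised vs aborted is an
arbitrary, documented default that no estimator consumes.

What the generator does **not** emulate: between-year variation,
within-season temporal trends, spatial foraging or bee movement,
overdispersion beyond Poisson/multinomial sampling, observer effects, and
pollen (male-fitness) pathways. Passing recovery tests therefore shows the
estimators are correct under the stated sampling models, not that field data
meet those models.

## Numerical and degenerate-input conventions

Distances via scipy (`braycurtis`, `pdist`); eigendecomposition via
symmetric `eigh` with a relative tolerance of 1e-9 for calling an eigenvalue
positive. PIE requires N ≥ 2. Jacobs' D at (r, p) = (0, 0) or (1, 1)
returns 0 by continuity with a warning. Coincident landscape points give
R = A = 0 and are legal. All Monte-Carlo machinery takes explicit seeds;
the pipeline derives per-stage seeds from one master seed and records them
in its summary, so a rerun is byte-identical.

## Problem sizes used in the validation suite

Calibration checks run at 500 replicates (PERMANOVA type-I error with 199
permutations; CSR calibration at n = 20 with 199 simulations each), 1000
replicates for GOF-uniformity and index oracles, 100 seeds for
cluster-count recovery, and B = 1000 bootstrap replicates end-to-end —
sizes at which the binomial noise on a 5 % rate is about ±1 % and each
check completes in seconds.

## Known limitations

* From a pooled published census the composition statistics can only
  approximate analyses performed on survey-level raw data (see the
  count-vs-proportion discussion above).
* The Hopkins–Skellam mean-bias at small n (documented above) means A
  should be read against its Monte-Carlo band, never against 1.0 directly.
* Electivity pooled over trials ignores trial-level heterogeneity; a
  mixed-model treatment is out of scope.
* Seed-share apportionment assumes effectiveness is proportional to realised
  seed production — exact under the generator, an approximation in the
  field.
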