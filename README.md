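# effscape

Statistical machinery for asking how **pollinator effectiveness** changes the
measured generalisation of a plant's pollination system — built around the
case of a Mediterranean mustard whose individual plants display two seasonal
floral morphs (large lilac cross-shaped flowers in spring, small white
rounded flowers in summer) and are therefore visited by two contrasting
insect assemblages.

It is aimed at pollination ecologists who have the four standard data tables
of an effectiveness study — visitation censuses, two-morph preference
trials, timed per-plant surveys, and single-visit seed-set records — and
want the full analysis chain behind them, plus a ground-truth synthetic
generator to validate every step.

## What it computes

**Interaction diversity.** The generalisation of each floral morph is the
probability of interspecific encounter (Hurlbert's PIE) of its pollinator
assemblage,

```
PIE = N/(N-1) · (1 - Σᵢ pᵢ²)
```

with `N` insects and `pᵢ` the relative abundance of functional group `i`;
equivalently the unbiased pair-count estimator `1 - Σᵢ Xᵢ(Xᵢ-1)/(N(N-1))`.
CIs come from a multinomial bootstrap, and morphs are called different when
their 95 % CIs do not overlap. Composition differences between seasons are
tested by permutational multivariate ANOVA on Bray–Curtis dissimilarities
with sequential sums of squares (population entered first, as a covariate)
and visualised by principal coordinates with functional-group projections.

**Preference.** Electivity of each functional group for the spring morph by
Jacobs' index `D = (r - p)/(r + p - 2rp)` (with Ivlev's `E = (r-p)/(r+p)`
alongside), where `r` is the group's share of visits to the spring morph and
`p` the spring morph's share of open flowers; significance by a goodness-of-
fit test of visits against availability.

**Effectiveness.** Per functional group and morph, quantity `QTC` =
visits · plant⁻¹ · h⁻¹, quality `QLC` = viable seeds per single visit
(failed visits count), and effectiveness `E = QTC × QLC` — the group's
contribution to female fitness. Groups are placed on the (QTC, QLC)
effectiveness landscape; clumping is tested with the Clark–Evans R statistic
(Donnelly edge correction) and the Hopkins–Skellam A index against
Monte-Carlo CSR simulations, and the number of functionally equivalent
clusters is the majority vote of ten validity indices over Ward partitions.
Finally, PIE on visit counts is compared with PIE on seed counts to see
whether effectiveness weighting makes the system look more specialised or
more generalised.

**Synthetic data.** `effscape.synthetic` generates all four tables from
known parameters (multinomial season assemblages, Poisson/binomial trials
with exact Jacobs'-D inversion, Poisson surveys, and a two-stage
Bernoulli × binomial seed model with closed-form `E[QLC] = f·m·q`), so every
estimator is testable by parameter recovery.

## Worked example

```
python analysis/01_simulate_scenario.py
python analysis/05_generalisation_comparison.py
```

prints, for the packaged field-like scenario:

```
spring:
  visit-weighted PIE 0.493 [0.486, 0.499]
  seed-weighted  PIE 0.390 [0.383, 0.397]
  verdict: different (more specialised under effectiveness weighting)
summer:
  visit-weighted PIE 0.770 [0.764, 0.775]
  seed-weighted  PIE 0.788 [0.784, 0.792]
  verdict: different (more generalised under effectiveness weighting)
```

i.e. in spring, seed production is concentrated in the dominant long-tongued
bee group (~77 % of seeds), so the system is *more specialised* than its
visit counts suggest; in summer, seeds are spread more evenly than visits
and the system becomes *more generalised* — opposite shifts in the two
morphs. `analysis/02_assemblage_diversity.py` runs the same diversity and
ordination chain on the packaged field census (spring PIE 0.587, summer
0.812; season F = 3.77, p ≈ 0.01 with population controlled; first two
principal coordinates carry 61.1 % of variation), and scripts 03–04 produce
the electivity table and landscape diagnostics.

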