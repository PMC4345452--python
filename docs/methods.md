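# Methods

## The model

Hamilton's rule states that altruism is favoured when the benefit to the
recipient, devalued by the coefficient of relatedness, exceeds the cost to
the donor: `b r > c`.  Applied to food transfers, `b` and `c` are the
marginal utilities of calories to the recipient and donor, which
life-history theory ties to the age-schedules of production and
consumption: immature individuals consume more than they produce, prime-age
adults produce large surpluses, so the marginal cost of giving falls and
the marginal benefit of receiving rises exactly where the generations meet.
The package implements this as a testable pipeline with four stages.

**Relatedness.** `kinflows.pedigree` computes Wright's coefficient of
relationship as twice the kinship coefficient by the standard recursion
over parents, with founders assumed mutually unrelated and non-inbred.
Family-level relatedness is the arithmetic mean over all cross-family pairs
of living members (the choice of mean vs. head-to-head is exposed through
`mean_cross_relatedness`).  Family dyads are classified from the
genealogical links between core adults (members without a co-resident
parent) with precedence parent-offspring > sibling > other kin, and non-kin
exactly when mean relatedness is zero.  An independent gene-dropping oracle
(`kinflows.validation`) transmits founder alleles through the pedigree and
estimates relatedness as identity-by-descent sharing; the test battery
holds the recursion to this oracle.  Because the oracle battery makes on
the order of 1500 correlated Monte-Carlo comparisons, the agreement test
uses a Sidak-corrected per-pair threshold that keeps a 3-sigma error rate
family-wise; a flat per-pair 3 s.e. bound would reject a correct
implementation almost surely.

**Transfers.** `kinflows.simulate.allocate_transfers` moves calories from
donors to recipients while `r u'(c_recipient) > u'(c_donor)` under
isoelastic utility `u'(c) = c^-gamma` of per-adult-equivalent consumption.
For a single donor this greedy rule has a water-filling fixed point (every
eligible recipient is brought to `r^{1/gamma}` times the donor's final
per-capita consumption), which the kernel solves directly and rounds to the
gift granularity; donors act in order of satiation.  The two-agent
logarithmic case has the closed form `t = (r A_d - A_r) / (1 + r)`, which
the tests pin at `t = 333.33` kcal for availabilities 3000/1000 and
`r = 0.5`.

## The synthetic society

No field data ship with the package, so `kinflows.simulate` generates
communities with the statistical structure the analysis assumes.  Choices
that matter, with defaults:

- **Age schedules** (piecewise linear, kcal/day).  Consumption rises from
  ~500 (infancy) to 2700 (adult men) / 2300 (adult women); production is
  zero in early childhood, climbs slowly through adolescence and a
  young-adult learning phase, peaks at 45 (4900 men, 3300 women) and
  declines but stays substantial into the 60s.  Net production is negative
  through the teens (crossover ~21 for men) and positive from the
  early 20s through the 60s.  Family budgets (head-age profile) are in
  deficit until roughly 45 and in surplus after, with the deficit deepest
  for households full of young dependents.
- **Demography.**  Each community holds several unrelated founding
  "grand-lineages" of 2-3 sibling couples whose dead parents remain in the
  pedigree as links.  75% of founding sibships are mid-aged (eldest 40-55)
  with no living parental generation — without them, sibling-to-sibling
  provisioning is crowded out by parent-offspring support and degenerates
  to noise.  First birth at wife's age ~18, closed birth intervals of
  1.8-3.0 years until ~35 (completed family sizes near 5-7).  Men head
  independent households from ~24, women marry from ~22; couples with a
  younger wife stay in the natal household, giving three-generational
  pooling units.  25% of elders die before the study (remaining in the
  table, flagged), creating widowed households and uncrowded sibships.
- **Transfer policy.**  `gamma = 5`: marginal utility falls steeply around
  the subsistence requirement, so moderate per-capita gaps move food at
  family-level relatedness of 0.1-0.3.  (With `gamma = 1` a recipient must
  be four times worse off before an `r = 0.25` donor gives at all, and the
  simulated society shares almost nothing.)  A kin-salience floor of
  `r >= 0.1` concentrates each donor's network on close kin, matching the
  empirical regime in which distant kin and non-kin receive essentially
  zero net flows.  Null variants: `charity` (need-directed, kin-blind,
  flat `r = 0.5` for everyone) and `random` (kin- and need-blind gifts of
  100-600 kcal at rate 0.3/family-day).
- **Observation.**  Families are interviewed about twice a week with a
  two-day recall window; only flows on covered days enter the ledger.
  Dyadic rates divide by jointly observed days, which keeps them unbiased
  under this design (verified by simulation).  Optional multiplicative
  log-normal reporting noise (mean-one) is off by default.
- **Seeding.**  One seed feeds a named generator hierarchy (demography /
  production noise / interview sampling), so stages can be varied
  independently and identical config + seed reproduce outputs byte for
  byte.

What the generator does *not* emulate: seasonality, market foods,
food-specific sharing norms, storage or debt (allocation is myopic and
daily), lactation, food processing, and any attempt to match real vital
rates beyond the qualitative life-course shapes above.  Passing tests
therefore show that the analysis chain recovers the generating structure
under these idealised conditions, not that the field estimates themselves
are reproduced.

## Ledger reduction and need indices

Within families, food is pooled: each producer's retained output is
recorded as meal portions to members in proportion to their consumption
requirements; between-family gifts are recorded from producing members
(pro rata by production) to consuming members (pro rata by requirement).
Net transfer matrices are antisymmetric by construction, and within-family
flows cancel at the family level while remaining available for the
individual-level spouse and parent-child analyses.

Measured net need is realized consumption minus gross production per
observed day (positive = needy).  Because that quantity is partly
determined by the transfers being modelled, an instrumental variant
predicts production and consumption from age-sex composition alone, using
5-year x sex cell means fitted with the focal family left out; identical
rosters receive identical estimates regardless of realized output, and
empty cells borrow from the nearest populated cell of the same sex (logged).
Both indices are standardized over the dyadic modelling sample, not per
community.

## Models

The family-dyad model regresses standardized net transfers (older family i
to younger family j, oriented by the age of the eldest core adult, ties to
the smaller id) on mean relatedness, the standardized need of each family,
and the need x relatedness interactions, with random intercepts for
community and variance components for donor and recipient family (crossed
membership within community).  Estimation is maximum likelihood
(`statsmodels` MixedLM, lbfgs with one warm restart) with Wald p-values; a
fit whose fixed-effect standard errors fall outside 0.01-100x the
cluster-robust OLS values — or that cannot be fit at all — falls back to
OLS with community-clustered errors and is flagged loudly.  Per-category
models report the mean net transfer and the standardized need coefficients
per relationship category, and age-profile models report age-bin x sex
means of a focal's summed transfers with community intercepts.  A focal
contributes a single row per profile, so a focal-level random intercept
would be confounded with the residual and is not included.

The estimator is calibrated on data generated under its own assumptions
(`simulate_lmm_dyads`: 8 communities x 28 families, Gaussian community /
donor / recipient intercepts of s.d. 0.2/0.3/0.3, unit residual): over 200
replicates, per-coefficient bias is below 0.05 standardized units and Wald
95% CI coverage is within 95 +- 3%.

## Problem sizes

The sign-recovery and null-calibration batteries run 25 societies of 4
communities x ~40 families (100 simulated communities; 3000-4500 dyads per
society, the same order as a real multi-village study sample) over a 75-day
window; the age-profile battery runs 100 societies of 2 communities x 12
families.  These sizes give the models the cluster counts they need while
keeping a full battery inside a coffee break on one CPU.
`scripts/acceptance.py` re-runs the same pipeline at 12 seeds per regime.

## Numerical details and edge cases

- Gifts are floored at zero, rounded down to the granularity (10 kcal
  default), and capped by donor availability; total calories are conserved
  every simulated day (production = intake, property-tested).
- Orientation ties between equally aged family heads resolve to the
  smaller family id and are logged.
- Degenerate inputs raise typed errors: unknown ids, overlapping family
  groups, families without a core adult, single-known-parent records,
  non-concave utility, constant inputs to standardization, rank-deficient
  designs (naming the collinear terms), ledgers mentioning persons with
  zero observed days.
- An empty ledger yields empty-but-valid analysis outputs with a warning
  rather than an error.

## Known limitations

- The instrumental need index is a leave-one-family-out cell-mean
  predictor; a field analysis might add household covariates beyond age-sex
  composition.
- The interview model is a plausible stand-in for a real sampling/recall
  protocol, not a reconstruction of one.
- Relatedness is genealogical only; affinal ties carry r = 0 and are
  analysed through relationship categories instead.
- With three-generational households, category labels attach to core
  adults, so a dyad mixing, say, a resident son-in-law and his brother is
  classified as sibling even though most members of the two households are
  unrelated.
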