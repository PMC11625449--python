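# Methods

## The model

The analysis treats a child's diet as a multiset of consumption events
(participant, day, food, grams) over a consecutive 4-day semi-weighed
diary that includes at least one weekend day.  Nutrient intakes follow
by linear accounting against a per-100 g composition table; the mean
daily intake divides by the number of *distinct recorded days* rather
than a hard-coded 4, so partial diaries degrade gracefully.

Percent of total energy uses each child's own energy intake
(`%TE = g/d × factor / kcal/d × 100`); population %TE means are means of
the individual %TE values, not a ratio of population sums.  Energy
conversion factors follow the UK convention of the composition-table
lineage (all fat classes 9 kcal/g, protein 4, carbohydrate and sugars
3.75); they are module constants, not magic numbers, and configurable.

The food-exchange scenario is a pure relabelling of diary entries: an
ordered rule list (category selector + optional case-insensitive
description regex → one replacement food code) is applied in a single
pass, first match wins, and replacements are never re-matched.  Grams,
days, and entry counts are invariant by construction; only the food
types change.  Consequences that the test suite checks as theorems of
this design:

* **Conservation** — per-child, per-day gram totals and entry counts are
  identical across arms.
* **Complete removal** — a category whose every food is matched
  contributes exactly 0 afterwards, so its contribution change is
  exactly −100 %.
* **Directionality** — if each rule's replacement has lower SFA per
  100 g than everything the rule selects, every child's modelled SFA g/d
  is ≤ baseline, and upper-bound SFA compliance cannot fall.
* **Idempotence** — applying the rule set twice equals applying it once,
  because per-source rules use anchored, escaped description patterns
  that can never select a replacement.

## Statistics

All test statistics are written from their closed forms so they can be
checked against brute-force enumeration (scipy supplies only the F and
t distributions, and serves as an independent oracle in the tests):

* One-way ANOVA from sums of squares; degenerate all-equal groups are
  reported as F = 0, p = 1 (no evidence of difference) rather than NaN.
* Scheffé pairwise criterion:
  `(m_i − m_j)² / (MSW (1/n_i + 1/n_j)) > (k−1) F_crit(α; k−1, N−k)`.
  Letter groupings are the maximal cliques of the
  not-significantly-different graph, ordered by group mean — the
  superscript-letter convention of survey tables.
* Paired t: `t = mean(d) / (sd(d)/√n)`, two-sided on n−1 df.  Zero
  variance of differences is flagged: identical arms give a "no-change"
  result; a constant nonzero shift gives p = 0 with a zero-variance flag.
* Bonferroni: `p_adj = min(1, p·m)`.  The family for the tertile table
  is the number of category rows tested; for the baseline-vs-model table
  it is the number of nutrient endpoint rows.  Both are configurable
  since published reports rarely state m.
* α = 0.05 throughout.

Relative changes (contribution changes, compliance improvements) are
always computed from unrounded values; rounding before division can
shift a reported relative change by tens of percentage points.  A
category absent at baseline but present post-exchange has no defined
relative change and is reported as status `new`, never as a number.

Tertile assignment is a stable sort on (value, participant_id) split
into thirds, remainder to the lower tertiles; ties straddling a boundary
are allowed (logged warning) so the assignment is deterministic and
order-invariant.  Survey-weighted ANOVA (integerised frequency weights)
is available but off by default, since weighting of the published
tertile comparisons is typically unstated.

## Units and conventions

Energy is kcal everywhere; fatty acids and macronutrients g; vitamin E
mg; EPA+DHA converted to mg only at reporting/compliance boundaries.
Reports of child vitamin E intakes near 7 "µg/d" in this literature are
physiologically implausible as µg (typical intakes are mg/d); this
package stores and reports vitamin E in mg/d and never rescales user
data.  Recommendation bounds are inclusive, as printed ("≤ 10 %TE"
admits exactly 10.0).  The numeric cut-offs for total fat (≤ 35 %TE),
MUFA (≥ 10 %TE) and trans-fat (≤ 2 %TE) are implementer defaults flagged
`assumed` in the recommendation set — compliance with them is
conventionally reported, but authorities differ on the numbers — whereas
SFA ≤ 10 %TE, PUFA ≥ 6 %TE and EPA+DHA ≥ 250 mg/d are guideline values.

Category contributions default to the population-proportion method
(ratio of weighted sums), the convention of the Irish national surveys;
`mean_of_ratios` is offered for sensitivity analysis, and a per-child
category-%TE variant (`participant_category_pct_te`) covers the
alternative reading of "contribution (%TE)" table captions.

## The synthetic cohort

The survey this analysis design emulates is not deposited, so the
generator produces a cohort with the structure the analysis needs,
without claiming to reproduce the real survey's distributions:

* 600 children (300 boys, 300 girls), integer ages uniform on 5–12,
  4-day diaries; diary start day drawn from Thursday–Sunday so every
  window contains a weekend day.
* A composition table of 68 foods across the 26 categories, each
  category ≥ 2 foods, with a paired lower-SFA replacement for every
  exchangeable food (the butter→spread pair also strictly higher in
  PUFA).  Profiles are realistic template values with ±3 % seeded
  jitter; the jitter is small relative to every pair's SFA margin, so
  the ordering constraints hold for all seeds.
* Each child carries a latent fat-propensity z ~ N(0,1) that loads
  positively on the whole-milk, cheese, butter, biscuit, processed-meat
  and chocolate category weights and negatively on low-fat milks,
  spreads, fish, fruit and vegetables.  This builds the tertile gradient
  (whole-milk contribution strictly increasing from low to high SFA
  consumers) into the data-generating process.
* Eating events: 9–14 per day, category via per-child multinomial
  (log-weights = base + z·loading), portion log-normal (σ = 0.35) with
  age-scaled medians, then all amounts in a day scaled so the day meets
  the child's energy target (1100 + 70·age kcal, ±10 % child-level and
  ±5 % day-level log-normal noise — roughly 1500–2000 kcal/d across the
  age range).  Scaling to an energy target makes %TE depend only on the
  food mix, which keeps calibration one-dimensional.
* Calibration: a single "rich-food" logit decides, per event, whether
  the high-SFA or the lighter variant of the chosen category is eaten
  (probability sigmoid(a + 0.3·z)).  Because all random draws are fixed
  before calibration, the realised cohort mean SFA %TE is monotone in
  a, and bisection (≤ 40 iterations, tolerance 0.05 %TE) is exact,
  bounded, and fully deterministic.  An unattainable target raises a
  calibration error rather than looping.
* Dispersion: the loadings were set once so the default cohort's
  realised SFA sd is ≈ 2.6 %TE, placing tertile means near 11/14/17 %TE.
  `CohortSpec.sfa_sd` scales the loadings linearly around that default.

What the generator does **not** emulate: day-of-week and seasonal menu
structure, within-food brand variation, correlated food pairings (tea
with biscuits), under-reporting, supplement use, or the real survey's
demographic weighting (the optional "social-class" weight model is a
three-point distribution, nothing more).  Passing tests therefore
demonstrate correctness of the accounting, statistics and exchange
machinery under realistic marginal structure — not that the synthetic
cohort reproduces any published population's point estimates beyond the
calibrated mean and the built-in gradient.

## Problem sizes

The default analysis and test suite run on the full 600-child cohort
(~27,000 diary entries); generation plus calibration takes well under a
second and the whole pipeline a few seconds.  The paired-t null
calibration check uses 5,000 seeded replicates at n = 100.

## Known limitations

* Cheese exchanges act on the cheese category only; cheese inside
  composite dishes is untouched (composite-dish decomposition is out of
  scope).
* No usual-intake deconvolution (4-day means are used directly) and no
  energy-misreporting adjustment — matching the design this emulates,
  which applies neither.
* The compliance metric is the individual-level proportion meeting each
  cut-off; more elaborate habitual-intake compliance methods exist but
  require replicate-day variance modelling that 4-day means do not
  support well.
* Exchange rules operate at food-code granularity; a rule set whose
  replacement is itself selected by a later rule would not be idempotent
  (the default set is constructed so this cannot happen, and the
  validator rejects self-selection).
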