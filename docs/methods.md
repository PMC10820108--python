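# Methods

## Scope and data model

The pipeline analyzes packaged fruit-snack launches as exported from a
product-launch registry: one row per product with free-text metadata
(name, brand, description, package type, ingredient list, claims), a
launch date, a serving size, and a per-serving Nutrition Facts panel.
Panel cells are modelled as `CodedValue`s with three states — numeric,
censored-below ("<1"), missing — because label transcription genuinely
produces all three and silently coercing them corrupts downstream means.

Canonical units are kcal for energy; grams for fats, sugars, fiber and
protein; milligrams for cholesterol, sodium, potassium, calcium and iron;
micrograms for vitamin D. Registry exports are inconsistent about units
(cholesterol is sometimes printed in grams, vitamin D in IU), so parsing
converts at ingestion; vitamin D uses the FDA label conversion
40 IU = 1 mcg. Dates must be ISO-8601; other dialects are ambiguous
(05/04 vs 04/05) and are rejected rather than guessed.

## Cleaning rules

Applied in screening order, each step logged in the exclusion ledger:

1. **Scope screen** — products matching no category rule are out of scope.
2. **No-label screen** — a panel with every cell missing is unscorable.
3. **Duplicates and dual labels** — exact duplicates are dropped on
   `record_id` (first occurrence kept); records sharing
   (brand, name, launch date) are treated as one product with multiple
   printed panels and replaced by the arithmetic mean of their numeric
   nutrients (a nutrient missing on any panel stays missing). A second
   dedup pass on (brand, name, serving mass) catches re-entered rows with
   distinct IDs. The averaging step runs *between* the two dedup passes:
   running the mass-based pass first would silently discard the second
   panel of a dual-label product instead of averaging it.
4. **Censored-value imputation** — "<1" g fiber is back-calculated from the
   printed %DV against the 28 g daily value (e.g. 3% → 0.84 g); without a
   printed %DV the fallback is half the bound (0.5 g). "<0.1" g saturated
   fat → 0.1 g; "<5" mg sodium or cholesterol → 5 mg; "<1" g protein →
   0.75 g. Any other "<x" code (e.g. "<2" g fiber) is imputed at x/2 and
   logged. Imputation is total and state-preserving: numeric cells are
   never touched, missing cells never invented.
5. **Completeness screen** — products missing added sugar, vitamin D,
   calcium or iron (the nutrients newly mandated on the post-2016 label)
   are removed; zero is a value, absence is not.
6. **Serving normalization** — serving mass must resolve to grams, either
   from the numeric field or from text like "30 g"; "1 pouch" with no gram
   measure is excluded with its own ledger reason.

The full pass is idempotent, and the ledger enforces conservation
(removals + final remainder = initial count) after every step. Besides the
four canonical screening steps the ledger admits extra labelled steps
(unparseable serving, non-positive energy at scoring), since both
exclusions need an audit trail too.

## Category assignment

Nine market categories are assigned by an ordered, case-insensitive,
whole-word keyword rule set over name, description, package type and
ingredients — an explicit surrogate for the manual categorization such
surveys perform, kept in code/config so it is auditable and refinable.
Precedence is most-specific-first: fruit chips → canned fruit with juice →
canned fruit → fruit puree (pouch cue) → fruit-based bar → formed fruit
(leather/roll/strip/twist/jerky) → dried flavored fruit (dried + flavor
cue) → dried fruit → fruit-flavored snack; all dried products would match
"dried", so specificity ordering is what makes classification a function.
Chips and bar rules additionally require a fruit term, so "Potato Chips"
and "Chocolate Bar" fall out of scope. Products named "bar" are split
between fruit-based bars and formed fruit by ingredient-list complexity:
at least two non-fruit entries among the first five ingredients indicates
a composite bar recipe; an all-fruit list indicates pressed formed fruit.
This split is interpretive — label data do not distinguish the two
unambiguously — and is therefore a tunable rule parameter.

## NRF6.4 scoring

`NRF6.4 = NR6 − LIM4`, both sub-scores computed per 100 kcal with
per-nutrient %DV capped at 100. Decisions worth making explicit:

- **Protein DV = 50 g.** The qualifying set includes protein but the
  updated label DV tables omit it (protein %DV is rarely printed); 50 g is
  the FDA adult value and is used here. This constant affects every NR
  score, so it sits in the default daily-value table where it can be
  overridden.
- **Capping** applies per nutrient, after conversion to the 100 kcal
  basis, to qualifying and disqualifying nutrients alike (so 0 ≤ NR ≤ 600,
  0 ≤ LIM ≤ 400). Capping before vs after basis conversion is not
  equivalent; the after-conversion rule is the simplest consistent reading
  and is applied uniformly.
- **Energy density** uses the labelled serving mass (kcal per serving ×
  100 / serving g), not the RACC.
- Trans fat and total sugar are carried through I/O but never scored.
- Products with non-positive energy or serving mass are excluded with a
  ledger reason, never scored as zero.
- Reported tables round to 1 d.p.; all internal computation is full
  precision.

The score is invariant to serving rescaling, strictly decreasing in added
sugar and increasing in fiber below the caps, and satisfies
mean(NRF6.4) = mean(NR) − mean(LIM) exactly — all enforced by tests.

## Group statistics

Implemented from their rank-sum definitions so the inferential chain is
auditable (library implementations are used only as test oracles):

- Kruskal–Wallis H on pooled mid-ranks with the standard tie correction
  `1 − Σ(t³−t)/(N³−N)`; p from the χ²(k−1) upper tail. If every pooled
  value is identical the statistic is defined as H = 0, p = 1.
- Dunn's pairwise z with tie-corrected pooled variance
  `(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_a + 1/n_b)`, two-sided normal
  p-values, no continuity correction — matching the defaults of the R
  implementation conventionally used with this procedure.
- Holm step-down adjustment over all k(k−1)/2 pairs, α = 0.05.
- Compact letters by insert-and-absorb: start with one letter covering all
  groups; each significant pair splits every letter set containing both;
  subset letter sets are absorbed. The output is validated on every call
  against the defining invariant (share a letter ⇔ not significantly
  different); letters are computed per metric independently.

Null calibration is verified by simulation in the test suite: the omnibus
test's empirical size at α = 0.05 lies in [0.03, 0.07] and the Dunn+Holm
familywise error stays ≤ 0.07, each over 2,000 replicates of nine groups
of 30.

## Synthetic market snapshot

The generator emulates the statistical structure the analysis assumes,
using published per-category summary statistics (per-100 g mean/SD of
energy density, added sugar and fiber; launch counts per category and
year) as generative defaults:

- **Distributions.** Each per-100 g nutrient is drawn from a
  positive-support distribution moment-matched to its (mean, SD). Cells
  with CV < 0.75 use a zero-truncated normal whose underlying parameters
  are solved so the *truncated* moments hit the targets (naive truncation
  would shift them). Cells with CV ≥ 0.75 use a zero-inflated gamma
  (shape 4), because a zero-truncated normal cannot attain CV ≥ 1 while
  several published cells demand CV up to 10 — such cells describe
  mostly-zero nutrients with a positive tail, which the point mass
  captures directly.
- **Stratified sampling.** Draws use inverse-CDF sampling at one uniform
  per equal-probability stratum (randomly permuted). Marginals are exact
  and the Monte Carlo error of sample means drops from O(1/√n) to O(1/n),
  so end-to-end moment-recovery tests measure pipeline fidelity rather
  than sampling noise.
- **Independence.** No inter-nutrient correlations are published, so
  nutrients are drawn independently. This is the generator's main
  departure from real data, and it has a visible consequence: for
  categories with high energy-density variance (canned fruit), E[sugar/energy]
  exceeds mean sugar / mean energy, inflating the expected LIM and pushing
  the category's mean NRF6.4 below the published value (≈ −18 vs −10).
  The per-100 g metrics the recovery criteria check are unaffected.
- **Non-published nutrients.** Protein, micronutrients, saturated fat,
  sodium and cholesterol are not summarized per category in the source
  tables. Their generative means (flagged as non-survey defaults in code) are
  back-solved so the expected NR and LIM sub-scores approximate the
  published per-category values, distributing the residual sub-score over
  nutrients in fixed shares (potassium 45%, protein 25%, iron 12%,
  calcium 12%, vitamin D 6%; saturated fat 45%, sodium 45%, cholesterol
  10%) with CV 0.5. The back-solve uses the exact E[1/energy] of the
  configured energy distribution since %DV per 100 kcal divides by energy.
- **Label artifacts.** Fiber cells are coded "<1" at rate 0.10 (the
  printed %DV is retained, so imputation can invert it); saturated fat,
  sodium, cholesterol and protein cells below their code bounds are
  censored at rate 0.30; one of the four newly mandated nutrients is
  blanked at rate 0.378 (matching the surveyed screening proportion,
  908/2405); exact duplicates at 0.04; dual-label siblings (same brand/
  name/date, panels jittered ±4%) at 0.03; out-of-scope contaminants at
  15% and unlabeled rows at 4.5% of the core count, mirroring the surveyed
  screening flow (2874 → 2405 → 1497).
- **Serving masses** are typical label servings per category (e.g. 40 g
  dried fruit, 122 g canned, 90 g pouch puree), drawn normally with ~12%
  SD, floored at 10 g and rounded to whole grams. All scored metrics are
  serving-invariant, so these defaults affect realism, not results.

What passing the recovery tests shows: the pipeline returns the generative
per-category means (within 2 SE at n = 200/category) *through* the coding,
duplication and screening artifacts, and reproduces the qualitative
category ordering (dried fruit most fiber-rich and nutrient-dense;
fruit-flavored snacks most added sugar, least fiber, lowest score). What
it does not show: recovery of any real market's values — real label data
have rounding, correlated nutrients, and category-dependent missingness
the generator does not model.

## Numerical and reporting choices

- Problem sizes: recovery tests use 200 core products per category; null
  calibration uses 2,000 replicates; the analysis drivers use the full
  surveyed category sizes (2,405 core products). All complete in seconds
  to a few minutes on a single CPU.
- Display rounding is 1 d.p. for means/SDs and whole percent for the
  launch matrix; machine-readable CSVs keep full precision.
- The launch matrix reports row percentages (share of a category's
  launches per year), rounded to whole percent; totals are exact counts.
- Classification must recover ≥95% of planted categories on synthetic
  data; the shipped rule set and the generator's name templates share the
  same cue vocabulary, so failures indicate rule-order regressions.
- `ProductRecord` equality of coded cells ignores the preserved raw text:
  round-trips guarantee substance (state, value, bound), not byte-level
  cell text, though canonical serialization does preserve "<1" style codes.

## Known limitations

- The keyword classifier approximates a manual, judgment-based
  categorization; borderline products (flavored vs plain dried fruit,
  bar vs formed fruit) depend on the shipped cue lists.
- The "<1" fiber inversion trusts the printed %DV; where labels round
  aggressively the imputed value inherits that rounding (±0.14 g).
- Independence across nutrients in the generator understates real
  covariance (sugar–energy, fat–energy), so synthetic NRF6.4 means for
  high-variance categories deviate from published ones even though all
  per-100 g inputs match; see above.
- Compact letter displays are not unique; the insert-and-absorb output is
  one valid minimal-form display, deterministic for a given input order.
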