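# snackprofiler

Nutrient profiling of packaged fruit snacks on the US market.

Fruit snacks — dried fruit, fruit leathers and rolls, fruit-based bars,
canned fruit, purees, fruit chips and gummy-style fruit-flavored snacks —
are marketed as healthy, but their nutritional quality varies enormously
with processing and formulation. This package implements a reproducible
pipeline for assessing that quality from label data of the kind exported by
product-launch registries (e.g. Mintel GNPD): one row per product with a
per-serving Nutrition Facts panel, including the label's coded cells
("<1" g fiber, "<5" mg sodium) and the gaps left by products that predate
the post-2016 label (missing added sugar, vitamin D, calcium, iron).

It is written for food scientists and nutrition researchers who want to
audit or extend category-level nutrient-density comparisons, and ships a
synthetic market-snapshot generator so the entire analysis is runnable and
testable without access to proprietary product databases.

## The model

Nutrient density is scored with the Nutrient Rich Food index **NRF6.4**,
computed per 100 kcal on the updated US Nutrition Facts label basis:

```
NRF6.4 = NR6 − LIM4
NR6    = Σ_{i∈Q} min(100, 100·content_i / DV_i)     Q = {protein, fiber, potassium,
                                                         vitamin D, calcium, iron}
LIM4   = Σ_{j∈D} min(100, 100·content_j / DV_j)     D = {saturated fat, cholesterol,
                                                         added sugar, sodium}
```

with daily values DV on the 2000 kcal label basis (fiber 28 g, added sugar
50 g, potassium 4700 mg, vitamin D 20 mcg, calcium 1300 mg, iron 18 mg,
saturated fat 20 g, cholesterol 300 mg, sodium 2300 mg; protein 50 g).
Percent daily values are capped at 100 per nutrient after conversion to the
100 kcal basis. Added sugar and fiber are additionally reported per 100 g
and per the category's FDA Reference Amount Customarily Consumed (RACC:
40 g dried/flavored dried fruit and bars, 30 g formed fruit, chips and
fruit-flavored snacks, 140 g canned fruit, 125 g puree), and energy density
as kcal per 100 g of labelled serving mass.

Category differences are tested nonparametrically: tie-corrected
Kruskal–Wallis omnibus tests, Dunn's pairwise post hoc z-tests on pooled
mid-ranks with Holm adjustment (α = 0.05), and compact letter displays
(two categories share a letter iff not significantly different).

## Worked example

Generate a synthetic snapshot of 3,073 product rows (2,405 in-scope core
products at the surveyed category sizes, plus out-of-scope, unlabeled and
duplicate contaminants), clean, score and compare:

```sh
python analysis/01_simulate.py
python analysis/02_clean_classify.py
python analysis/03_score.py
python analysis/04_group_stats.py
python analysis/05_report.py
```

`02_clean_classify.py` prints the screening audit trail:

```
initial records: 3073
  - out_of_scope: removed 386, remaining 2687
  - no_nutrition_label: removed 116, remaining 2571
  - duplicate: removed 166, remaining 2405
  - missing_new_label_nutrients: removed 935, remaining 1470
  - unparseable_serving: removed 0, remaining 1470
```

i.e. 386 products did not match any fruit-snack category rule, 116 had no
nutrition panel, 166 were duplicate or dual-label rows, and 935 lacked at
least one newly mandated label nutrient, leaving 1,470 scorable products.
`03_score.py` then reports per-category means (1 d.p.):

```
               category   n  nr_mean  lim_mean  nrf64_mean  energy_density_100g_mean  added_sugar_100g_mean  fiber_100g_mean
           canned_fruit 140     13.4      31.4       -18.0                      74.0                    8.6              1.1
canned_fruit_with_juice  98     14.9       2.2        12.7                      55.7                    0.2              0.8
            dried_fruit 327     22.6       1.8        20.8                     324.6                    0.3              9.0
   dried_flavored_fruit 192     11.2      24.0       -12.8                     358.1                   33.7              5.5
           formed_fruit 100     17.4       7.4        10.0                     316.9                    9.2              7.9
            fruit_chips 118     11.1      18.6        -7.5                     509.2                    6.8              7.2
        fruit_based_bar 194     20.8      15.1         5.6                     404.1                   15.7              7.5
            fruit_puree 139     17.6       7.9         9.7                      69.3                    1.8              1.8
   fruit_flavored_snack 162      2.8      32.1       -29.3                     325.5                   47.9              0.5
```

Dried fruit is the most nutrient-dense category (NRF6.4 ≈ 21, highest
fiber, essentially no added sugar); fruit-flavored snacks are the least
(NRF6.4 ≈ −29, highest added sugar, lowest fiber); canned fruit with juice
and fruit puree combine positive scores with low energy density. Every
mean NRF6.4 equals mean NR − mean LIM by construction. `04_group_stats.py`
confirms strong category separation (e.g. NRF6.4: H = 991.8, df = 8,
p < 10⁻²⁰⁰) and prints the letter displays; `05_report.py` writes the
launch-year matrix, bubble-plot data and a recovery table showing all 27
per-category means of energy density, added sugar and fiber within 2
standard errors of the generative values.

The same pipeline runs on a real export via the CLI:

```sh
snackprofiler run --input products.csv --out out/
snackprofiler simulate --seed 17 --n-per-category 200 --out sim/
```

## Layout

- `src/snackprofiler/` — library: `gnpd_io` (coded-cell parsing, product
  tables, exclusion ledger), `cleaning` (dedup, dual-label averaging,
  imputation, screening), `categorize` (nine-category keyword rules),
  `nrf_scoring` (NRF6.4, per-100 g / per-RACC), `group_stats`
  (Kruskal–Wallis, Dunn, Holm, letters), `synthetic_data` (generator),
  `reporting` (summaries, pipeline), `cli`.
- `analysis/` — the numbered drivers above; large intermediates go to
  `scratch/`, tables to `results/`.
- `docs/methods.md` — modelling and design notes.
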