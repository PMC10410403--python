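# menuopt — multi-objective school-lunch menu optimisation

`menuopt` plans weekly elementary-school lunch menus by integer linear
programming and weighted goal programming. It is written for researchers
and food-service analysts who want to explore the tension between four
interests that every US National School Lunch Programme (NSLP) district
juggles: **nutritional quality** (Healthy Eating Index 2015), **cost**
(a fixed food budget per lunch), **student consumption** (plate-waste
adjusted intake) and **environmental impact** (global warming potential
and water scarcity).

## The model

The decision variables are integer serving counts `x_i >= 0` over a pool
of menu items for one 5-lunch week. Constraints enforce the weekly K-5
meal pattern (one entrée, fruit and milk per lunch; one to two vegetables;
weekly bounds on energy, sodium, saturated fat as % of energy, fruit and
vegetable cups including subgroups, grain and meat/meat-alternative oz-eq,
milk cups), a weekly budget `sum(c_i x_i) <= 6.70` USD (1.34 USD per
lunch), and repetition caps per item, per entrée protein type and per
flavour profile.

Seven objectives are solved over this common feasible set:

| model | objective |
|---|---|
| MAX-CALCON | maximise `sum(kcal_i * f_i * x_i)` — energy consumed, where `f_i` is the item's plate-waste consumption fraction |
| MAX-COSTCON | maximise `sum(c_i * f_i * x_i)` — food value consumed |
| MIN-COST | minimise `sum(c_i * x_i)` |
| MAX-HEI | goal program driving all 13 HEI-2015 components to their max-score standards |
| MIN-DEV | minimise `sum_g w_g * d_g / |G_g|`, equal weights |
| MIN-DEV10 | as MIN-DEV, weight 10 on the kcal-consumed goal |
| MIN-DEV30 | as MIN-DEV, weight 30 on the kcal-consumed goal |

For the multi-objective models each goal `g` (kcal consumed, cost, GWP,
water scarcity, and the 13 HEI components) gets a non-negative deviation
variable `d_g` linked by `achieved_g + d_g >= G_g` (at-least goals) or
`achieved_g - d_g <= G_g` (at-most goals); goal values `G_g` default to
the *ideal point* — each quantity's own single-objective optimum under the
same constraints. HEI itself is a ratio of linear forms and cannot be
maximised directly by a linear program; MAX-HEI therefore fixes the
density denominator at a reference weekly energy and the exact HEI of
every solved menu is recomputed afterwards by the scorer.

Models are solved to proven optimality with branch-and-bound (HiGHS via
`scipy.optimize.milp`); an independent exhaustive-enumeration oracle
verifies the solver on small instances.

Because no real item-level district dataset ships with the package, a
seeded synthetic generator produces a 142-item pool (77 entrées, 18
fruits, 43 vegetables, 4 milks) with the qualitative structure that makes
the trade-offs real: beef and cheese entrées are cheap, well consumed and
carbon-intensive; legumes are cheapest and least consumed; fish is
expensive but nutritionally strong; vegetables are poorly consumed.

## Worked example

```python
from menuopt import PoolRecipe, generate_pool, run_all_models
from menuopt.pipeline import report

pool = generate_pool(PoolRecipe(seed=1))
results = run_all_models(pool)
print(report(results)[0])
```

prints

```
model       status       objective   cost kcal_off kcal_con HEI_off HEI_con    GWP  water
-----------------------------------------------------------------------------------------
MAX-CALCON  optimal       2310.587   6.59     3248     2311    83.3    79.7  11.43   3.32
MAX-COSTCON optimal          4.667   6.70     3189     2263    82.3    80.2  11.40   3.24
MIN-COST    optimal          5.130   5.13     3250     1854    87.9    78.3  10.08   2.96
MAX-HEI     optimal          0.000   6.68     3224     1779    99.9    86.6   7.65   2.74
MIN-DEV     optimal          1.089   6.69     3250     1616    99.0    89.3   4.60   2.15
MIN-DEV10   optimal          3.045   6.46     3246     1843    97.3    88.7   4.88   2.24
MIN-DEV30   optimal          6.376   6.59     3249     1973    97.7    85.3   7.24   2.92
```

Each row is one optimal weekly menu: its cost (USD), energy offered and
consumed (kcal), HEI-2015 on the offered and consumed basis, GWP
(kg CO2-eq) and water scarcity (m3 water-eq). The consumption-maximising
models deliver the most kcal consumed but the highest footprints;
MIN-COST saves about 2.2 USD/week (~80 USD per student over a 36-week
year) at the price of the lowest consumed quality; the multi-objective
menus stay within budget, push HEI toward 100 and roughly halve GWP.
Raising the kcal-consumed weight (MIN-DEV → MIN-DEV10 → MIN-DEV30) buys
back consumption (1616 → 1843 → 1973 kcal) by giving ground on the
environmental goals.

The `examples/` scripts walk through each capability (pool generation,
HEI scoring, the seven models, baseline comparison), and the same
workflow is scriptable from a shell:

```sh
menuopt generate --seed 1 -o pool.tsv
menuopt optimize --pool pool.tsv --baseline-weeks 36 -o out/
menuopt score --pool pool.tsv --menu out/menu_MIN-DEV.json --basis consumed
```

Defaults (NSLP K-5 bounds, budget, repetition caps, HEI-2015 cut-points)
are all overridable through a YAML config; see
`src/menuopt/data/default_config.yaml` for the complete reference.

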