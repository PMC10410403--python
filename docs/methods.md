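# Methods

## Scope and unit of analysis

The package optimises one week of K-5 school lunches (default 5 lunches).
A weekly menu is a *multiset* of menu items — integer serving counts over
a pool — with no assignment of items to days. This matches how the NSLP
meal pattern is written (weekly quantity standards) and keeps every model
a pure integer linear program; per-day scheduling and student choice among
daily options are out of scope. Daily-stated quantities (energy, sodium,
milk cups, the budget) are enforced at the weekly level, multiplied by the
week length.

## HEI-2015 scoring

HEI-2015 awards up to 100 points over 13 components, nine adequacy and
four moderation, each scored on a density basis: amount per 1000 kcal for
the food-group components, percent of energy for added sugars and
saturated fat, and the (PUFA+MUFA)/SFA ratio for fatty acids. Scores are
linear between each component's cut-points and clamped at the ends, so
over-supply past the max-score standard never adds points (this is why a
menu can lose dairy cups without losing dairy points once the cap is met).
The shipped cut-points are the published HEI-2015 standards and are
config-overridable. Numerical choices:

* Added sugar is stored in teaspoon-equivalents and converted at scoring
  time with 16 kcal per tsp-eq (configurable constant); the cut-points are
  % of energy.
* Fatty-acid ratio with `sfa = 0`: treated as the limit of the ratio —
  max score if any unsaturated fat is present, zero if there is no fat at
  all.
* Legumes count in both greens-and-beans and seafood/plant-proteins, per
  the component definitions; item tables pre-assign component amounts, no
  allocation algorithm is run.
* The *consumed* basis multiplies each item's component amounts by its
  plate-waste consumption fraction but keeps the energy **offered** as the
  denominator, so the consumed score reads as "how much of the offered
  quality was realised" and is always ≤ the offered score when fractions
  are ≤ 1... strictly, it is lower whenever adequacy components are left
  on the tray; moderation components can move either way.

## The integer programs

Serving counts are integer (no partial portions); goal-program deviation
variables are continuous and non-negative. Upper bounds come from the
repetition caps (default 1 per entrée, 2 per fruit or vegetable, 5 per
milk, tightened by the implied category counts), with additional group
caps of 2 servings per entrée protein type and per flavour profile. The
saturated-fat cap, stated as a fraction of energy, is linearised by moving
all terms to one side: `sum((satfat_kcal_i − 0.10·kcal_i)·x_i) ≤ 0`.

The backend is branch-and-bound over the simplex relaxation (HiGHS via
`scipy.optimize.milp`) with a zero relative MIP gap, i.e. proven
optimality; integrality and feasibility tolerances are 1e-6 in absolute
terms, appropriate because all coefficients are small (USD, kcal, grams).
The reported objective value is re-evaluated in closed form from the
integer solution, so solver round-off cannot leak into reported numbers.
Ties between optimal menus are broken arbitrarily by the solver; all
comparisons in tests and reports are on objective values, never on the
identity of the serving vector. Infeasible models return a structured
report with a coarse hint (the first constraint unreachable within the
variable bounds alone).

### MAX-HEI as a goal program

HEI is a sum of clamped ratios of linear forms and cannot be maximised by
a linear objective. MAX-HEI instead poses 13 goals: each adequacy
component must reach `max_standard × E_ref/1000` (at-least), each
moderation component must stay under `min_standard × E_ref/1000`
(at-most; percent-energy components use `min_standard% × E_ref` kcal),
where `E_ref` is the midpoint of the weekly energy band (3000 kcal by
default). The fatty-acid ratio goal is linearised as
`sum((pufa+mufa − 2.5·sfa)·x) ≥ 0`; because its goal value is zero, its
relative deviation is normalised by an explicit scale (`E_ref/1000`
grams) instead of |G|. Fixing the denominator restores linearity but
means the goal program maximises a *proxy*: the exact HEI of every menu
is recomputed post-hoc by the scorer, and a multi-objective menu can
occasionally out-score the MAX-HEI menu on exact HEI — an expected
artefact of the linearisation, observed in practice.

### Multi-objective goal programs

MIN-DEV/-DEV10/-DEV30 share one goal set: kcal consumed (at-least), cost
(at-most), GWP and water scarcity (at-most), plus the 13 HEI component
goals. Goal values default to the *ideal point* — each quantity's own
single-objective optimum under identical constraints — so every goal is
individually attainable and the objective `sum w_g·d_g/|G_g|` measures
the price of pursuing them jointly. The three models differ only in the
weight on the kcal-consumed goal (1, 10, 30), applied to the *relative*
deviation. Raising that weight weakly increases the optimal kcal consumed
(a standard weighted-goal-programming exchange argument, verified in
tests). All goal values and weights are config-overridable.

## The enumeration oracle

`brute_force_optimum` walks the full integer lattice inside the variable
bounds, filters by the constraints, and evaluates the objective in closed
form — for goal programs the optimal deviations are determined by the
serving vector, so deviations need not be enumerated. It shares no code
path with the MILP route beyond the model description, making it an
independent check; it refuses lattices above ~1e7 points. The oracle
suite runs 50 seeded pools of 15 items with 3-day weeks (lattice ≈ 2.2M),
sharing one feasible-set enumeration across the seven objectives per
pool.

At this scale the K-5 bounds are rescaled by 3/5 with two adjustments:
vegetable-subgroup minima are dropped (a 4-item vegetable list cannot
cover five subgroups) and the energy/grain/meat upper bands are widened
(with only six entrées, three draws often overshoot a strictly scaled
band). These test-scale standards are fixed in the suite's fixtures.

## Synthetic data

The generator emulates the structure of a large urban district's 2018-19
K-5 offerings; no real item-level data ships with the package. Defaults:

* **Counts**: 142 items — 77 entrées, 18 fruits, 43 vegetables, 4 milks
  (two plain, two flavoured).
* **Entrée protein mixture**: beef 29 %, chicken 28 %, turkey 3 %,
  fish 5 %, and the 34 % vegetarian share split into cheese 12 %,
  legume 5 % and other-vegetarian 18 % so that beef+cheese versus
  fish+legume shifts are observable. Integer counts by largest remainder.
* **Orderings by construction**: per-attribute values are drawn from
  normals truncated to windows that are disjoint wherever an ordering
  matters — consumption fractions beef > cheese > chicken > turkey >
  fish ≈ other-vegetarian > legume; costs legume < beef < cheese <
  poultry/vegetarian < fish; GWP beef ≫ cheese > poultry/fish >
  other-vegetarian > legume. Directional optimisation tests (e.g. the
  multi-objective model trading beef for legumes) are therefore
  meaningful rather than luck of the draw.
* **Magnitudes** are plausible K-5 per-serving values (entrées ≈ 380
  kcal, fruit ≈ 80, milk 90-150; serving weights 80-300 g) chosen so the
  generated baseline lands near the district-scale weekly aggregates
  (cost slightly above the 6.70 USD budget, ≈ 1.9k kcal consumed of
  ≈ 3.3k offered, HEI in the mid-80s offered / high-70s consumed, GWP
  ≈ 9 kg CO2-eq, water ≈ 3 m3). Consumption fractions take the
  conservative (low) reading of measured plate-waste rates.
* **Baseline weeks** are sampled to satisfy the structural constraints
  (category counts, repetition caps) with entrée types drawn from the
  mixture; they are deliberately *not* constrained to the budget or
  nutrient bounds — real baselines ran slightly over budget.
* **Determinism**: a single `numpy.random.Generator` seeded from one
  integer; identical seeds give bit-identical pools, menus and reports.

What passing tests on this pool do **not** show: that the magnitudes of
improvement transfer to any real district. The generator encodes
orderings and rough aggregates, not fitted distributions; correlations
beyond the protein-type tiers (e.g. cost-consumption correlation within a
type, seasonal effects, student selection behaviour) are absent. Results
on synthetic pools demonstrate the method's correctness and the
direction of its trade-offs, not district-specific effect sizes.

## Degenerate inputs and edge cases

Empty menus cannot be scored or evaluated (undefined densities); zero
serving weight makes the consumption fraction undefined; a zero-valued
goal requires an explicit deviation scale; pools missing a whole category
raise a structural infeasibility error before any solve. Baseline HEI is
by default the score of the pooled average week (HEI is ratio-based, so
the mean of weekly scores is a different, also available, statistic).
The annual extrapolation multiplies a weekly saving by a 36-week school
year and optionally by enrollment (default 50 000).

## Known limitations

* One week at a time; no multi-week cycle constraints or produce
  seasonality.
* Participation (how many students buy lunch) is assumed constant and is
  not modelled.
* GWP and water-scarcity coefficients are item-level inputs; no LCA is
  performed and waste management is outside the system boundary.
* The MAX-HEI proxy can be out-scored on exact HEI by a multi-objective
  menu (see above); shadow-price analysis of the constraints is not
  implemented.
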