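"""Score a weekly menu with the Healthy Eating Index 2015.

HEI-2015 awards up to 100 points over 13 components: 9 adequacy components
(fruit, vegetables, whole grains, dairy, protein, fatty-acid ratio -- more
is better) and 4 moderation components (refined grains, sodium, added
sugars, saturated fat -- less is better), each scored on a density basis
(per 1000 kcal or % of energy) with linear interpolation between its
cut-points.  The "consumed" basis rescales every component by the item's
plate-waste fraction but keeps the energy OFFERED as the denominator.
"""

from menuopt import PoolRecipe, generate_baseline_menus, generate_pool, \
    score_menu

pool = generate_pool(PoolRecipe(seed=1))
week = generate_baseline_menus(pool, n_weeks=1, seed=2)[0]

for basis in ("offered", "consumed"):
    score = score_menu(week, pool, basis=basis)
    print(f"--- HEI-2015, {basis} basis ---")
    for name, pts in score.component_scores.items():
        print(f"  {name:<24}{pts:6.2f}")
    print(f"  {'total':<24}{score.total:6.2f}\n")

# The offered total is the menu's nutritional quality as planned; the
# consumed total is lower because students leave part of each serving, so
# the same offerings deliver fewer cup/oz-equivalents per 1000 kcal offered.
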