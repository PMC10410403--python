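"""Generate the default synthetic menu-item pool and look at its structure.

The pool emulates a large urban district's K-5 lunch offerings: 142 items
(77 entrees, 18 fruit sides, 43 vegetable sides, 4 milk options) whose
protein types carry the trade-offs the optimisation explores -- beef and
cheese are cheap, well consumed and carbon-intensive; legumes are the
cheapest and least consumed; fish is expensive but nutritionally strong.
"""

from collections import defaultdict

import numpy as np

from menuopt import PoolRecipe, consumption_fraction, generate_pool, \
    write_menu_pool

pool = generate_pool(PoolRecipe(seed=1))
write_menu_pool(pool, "pool.tsv")
print(f"wrote {len(pool)} items to pool.tsv\n")

stats = defaultdict(lambda: defaultdict(list))
for it in pool:
    if it.category == "entree":
        s = stats[it.protein_subcategory]
        s["cost"].append(it.cost)
        s["frac"].append(consumption_fraction(it))
        s["gwp"].append(it.gwp)

print(f"{'protein type':<18}{'n':>3}{'cost $':>8}{'consumed':>10}"
      f"{'GWP kg':>8}")
for sub in sorted(stats, key=lambda s: -np.mean(stats[s]['frac'])):
    s = stats[sub]
    print(f"{sub:<18}{len(s['cost']):>3}{np.mean(s['cost']):>8.2f}"
          f"{np.mean(s['frac']):>10.2f}{np.mean(s['gwp']):>8.2f}")

# Each row: per-serving averages by entree protein type.  The consumed
# column is the plate-waste fraction (grams eaten / grams served); the
# orderings (beef most consumed, legume cheapest, beef highest GWP) are
# what make the cost / consumption / footprint trade-offs non-trivial.
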