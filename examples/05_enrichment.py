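"""Gene-set over-representation of a query list against the toy collection.

Draws a query enriched for one synthetic set and prints the ranked
hypergeometric results with BH-adjusted p-values.
"""

import numpy as np

from poccnv import enrich
from poccnv.io import load_toy_gmt

collection = load_toy_gmt()
rng = np.random.default_rng(0)
# query: most of one set plus random background genes
target = collection.sets[2]
query = list(target.members[:8]) + list(rng.choice(sorted(collection.universe), 6, replace=False))

print(f"query of {len(set(query))} genes against {len(collection.sets)} sets "
      f"(universe {len(collection.universe)} genes):")
for row in enrich(query, collection):
    print(f"  {row.set_id:<12} k={row.k:>2}/{row.K:<2}  p={row.p_value:.2e}  "
          f"BH-adjusted={row.adjusted_p:.2e}")
print(f"(the planted set {target.set_id} should rank first)")
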