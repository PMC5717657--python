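"""Ancestral states and time slices on a dated tree.

Reconstructs internal-node shape values by squared-change parsimony
(Brownian-motion ML point estimates), then samples every lineage alive
at chosen times by linear interpolation along the branches (the
"gradual" model) and sums the per-axis variances.
"""

import numpy as np

from disparitree import (ancestral_states, build_tree, interpolate_at_time,
                         sum_of_variances)

# ((A,B),C) with node ages: root 11 Ma, inner node 10.5 Ma
tree = build_tree((("A", "B"), "C"),
                  ages={"A": 10.0, "B": 5.0, "C": 0.0})
tree.root.age = 11.0
tree.mrca(["A", "B"]).age = 10.5

mapped = ancestral_states(tree, {"A": [0.0], "B": [4.0], "C": [8.0]})
print("root estimate:", np.round(mapped.root.traits, 3))
print("inner-node estimate:",
      np.round(mapped.mrca(["A", "B"]).traits, 3))

for t in (10.0, 7.0, 2.0):
    sl = interpolate_at_time(mapped, t)
    sov = sum_of_variances(sl)
    print(f"t = {t:5.1f} Ma: {sl.n_lineages} lineages, "
          f"sum of variances = {sov if sov is None else round(sov, 3)}")
# Each slice holds one interpolated value per branch crossing that age;
# the sum of variances is the disparity of the clade at that moment and
# is undefined (None) when fewer than two lineages are alive.
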