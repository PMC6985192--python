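"""Enforce temporal consistency on multi-year class trajectories.

Shows the base-map fusion against a deforestation reference layer and
the trajectory rewriting rules, including the two rules that create the
secondary-vegetation class for forest regrowth on cleared land.
"""

import numpy as np

from lucmap import (
    AmazonClass,
    ClassMap,
    DEFAULT_VOCABULARY as V,
    ReferenceLayers,
    TrajectoryStack,
    apply_basemap_rules,
    apply_luc_rules,
)

# Base-map fusion: the 2001 map says forest, but the reference layer
# records the pixel as deforested -- so it must be regrowth, not forest.
refs = ReferenceLayers(
    np.full((1, 1), AmazonClass.DEFORESTATION, dtype=np.uint8),
    np.zeros((1, 1), dtype=np.uint8),
)
base = ClassMap(2001, np.full((1, 1), V.code("forest"), dtype=np.uint8))
fused = apply_basemap_rules(base, refs)
print("base map: forest + reference Deforestation ->",
      V.label(int(fused.grid[0, 0])))

# Trajectory rules: a forest pixel cleared to pasture and then showing a
# forest signal again is secondary vegetation, not pristine forest.
def rewrite(*labels):
    arr = np.array([V.code(c) for c in labels], np.uint8).reshape(-1, 1, 1)
    stack = TrajectoryStack(tuple(range(2001, 2001 + len(labels))), arr)
    out, report = apply_luc_rules(stack)
    result = [V.label(int(c)) for c in out.codes[:, 0, 0]]
    fired = [rule for rule, n in report.items() if n]
    print(f"{list(labels)} -> {result} (rules fired: {fired})")

rewrite("forest", "forest", "pasture", "forest")
rewrite("cerrado", "forest")
rewrite("forest", "cerrado", "forest", "forest")
# Rule 9 relabels the regrown year as secondary vegetation; cerrado can
# never become pristine forest; a one-year cerrado blip inside stable
# forest is repaired as classification noise.
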