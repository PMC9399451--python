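"""Clean, thin, and summarize presence records.

Deduplicates records to one per 5 m pixel, spatially thins them to 100 m,
and prints the per-geologic-unit occupancy table (share of occurrences vs
share of area) plus slope/curvature summaries at the retained records.
"""

from maxhab import environment, occurrences, simulate
from maxhab.simulate import LandscapeParams

stack, truth = simulate.generate_landscape(LandscapeParams(seed=42))
occ = simulate.sample_presences(truth, stack, n=300, seed=43)

occ = occurrences.deduplicate(occ, stack.grid)
thinned = occurrences.spatial_thin(occ, thin_dist=100.0, n_reps=10, seed=44)
print(f"thinning: {len(occ)} -> {len(thinned)} records "
      f"(no surviving pair closer than 100 m)")

table = occurrences.unit_occupancy(thinned, stack["geology"], min_count=10)
table = table[table["presented"]].sort_values("ratio", ascending=False)
print("\nunit occupancy (classes with >10 occurrences):")
print(table[["unit", "occurrence_pct", "area_pct", "ratio"]]
      .round(2).to_string(index=False))
# ratio > 1 means the unit holds more occurrences than its area share —
# the favored truth classes should stand out with ratios around 3+.

topo = occurrences.topo_summary(thinned, slope=stack["slope"], curvature=stack["curvature"])
print("\ntopography at presences:")
print(topo.round(2).to_string(index=False))
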