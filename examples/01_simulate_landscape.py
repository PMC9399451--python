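"""Simulate a virtual landscape and presence sample.

Builds the default 400x400-cell (2 x 2 km at 5 m) landscape — geology
mosaic, terrain, coarse-then-downscaled climate — with a known log-linear
suitability truth, and draws 189 presence cells from it.
"""

import numpy as np

from maxhab import simulate
from maxhab.simulate import LandscapeParams

params = LandscapeParams(seed=42)
stack, truth = simulate.generate_landscape(params)

print("layers:", ", ".join(stack.names))
elev = stack["elevation"].values
print(f"elevation range: {elev.min():.0f}-{elev.max():.0f} m")
print(f"geologic units present: {len(np.unique(stack['geology'].values))}")
print("truth drivers (strongest first):", truth.dominant_variables[:3])

occ = simulate.sample_presences(truth, stack, n=189, seed=43)
occ = simulate.inject_coordinate_error(occ, [0.0, 10.0, 25.0], seed=44)
print(f"sampled {len(occ)} presences; error radii used:",
      sorted(occ.records['error_m'].unique()))
# The presences concentrate in the favored geologic units and the mid-band
# of winter maximum temperature, because the truth surface is log-linear in
# those covariates.
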