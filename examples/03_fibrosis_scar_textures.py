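"""Synthetic fibrotic scars: gradient profile, textures and controls.

Builds the study's standard scar — a 6.4 cm disk whose fibrosis percentage
falls linearly from 50 % at the center to 0 % at the rim — draws seeded
obstacle textures from it, and prints how the realized obstacle fraction
tracks the map.  Also shows the two control geometries (no scar /
necrotic-only solid disk).
"""

import numpy as np

from rotoranchor import ScarSpec, make_controls, make_fibrosis_map, sample_texture

shape = (300, 300)
spec = ScarSpec(center=(150, 150), diameter=6.4, profile="radial_linear",
                level=50.0)
fmap = make_fibrosis_map(spec, shape)
print(f"fibrosis map: center = {fmap.values[150, 150]:.0f} %, "
      f"half-radius = {fmap.values[150, 214]:.0f} %, rim = 0 %")

for seed in (0, 1):
    tex = sample_texture(fmap, seed)
    inside = fmap.values > 0
    print(f"  texture seed {seed}: {tex.mask.sum():5d} obstacle nodes, "
          f"fraction inside scar = {tex.mask[inside].mean():.3f} "
          f"(map mean {fmap.values[inside].mean() / 100:.3f})")

no_scar, necrotic = make_controls(spec, shape)
print(f"controls: no-scar has {no_scar.obstacle_mask.sum()} obstacles, "
      f"necrotic-only has a solid disk of {necrotic.obstacle_mask.sum()} nodes")
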