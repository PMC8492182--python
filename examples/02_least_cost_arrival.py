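"""Equation-based arrival times over null and forest-weighted cost surfaces.

Builds the synthetic two-block corridor landscape, then maps arrival dates
as start - least-cost distance / front speed. With uniform cost (null
model) the wave crosses the savanna gap unhindered; charging non-forest
biomes 4x friction (alternative model) delays arrival beyond the gap.
"""

import numpy as np

from demicdiff import (
    CorridorScenario,
    FrontSpeedParams,
    biome_at,
    build_cost_surface,
    ebm_arrival,
    front_speed,
    make_corridor_series,
)

series = make_corridor_series(CorridorScenario())
raster = biome_at(series, 5000.0)  # oldest slice: corridor still closed
origin = (20, 8)
speed = front_speed(FrontSpeedParams())

for name, cost_map in [("null (all biomes cost 1)", {1: 1.0, 2: 1.0}),
                       ("alternative (non-forest cost 4)", {1: 1.0, 2: 4.0})]:
    surface = ebm_arrival(
        build_cost_surface(raster, cost_map), origin, speed, 5000.0, 500.0
    )
    far_block = surface.arrival[:, 24:]  # forest block across the gap
    print(f"{name}:")
    print(f"  earliest arrival in the far block: "
          f"{np.nanmax(far_block):.0f} BP")
    print(f"  mean far-block arrival: {np.nanmean(far_block):.0f} BP")
print("The 4x non-forest cost delays the far block by roughly a millennium "
      "— the arrival-date signature of forest-corridor dependence.")
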