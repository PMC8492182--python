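"""Recovering the generating scenario from synthetic radiocarbon-style dates.

Dates are drawn from the forest-restricted reference run (arrival minus an
exponential lag plus noise), then both models are scored against them by
RMSE under null and alternative rules. The alternative (forest-dependent)
variants fit the dates better — the evaluation recovers the scenario that
generated them.
"""

from demicdiff import (
    CAParams,
    FrontSpeedParams,
    biome_at,
    build_cost_surface,
    ebm_arrival,
    front_speed,
    reference_experiment,
    rmse,
    run_ca,
)

ref = reference_experiment(seed=1)
print(f"{len(ref.dates)} synthetic dated sites "
      f"(lag mean {ref.date_config.lag_mean:.0f} yr, "
      f"noise sd {ref.date_config.noise_sd:.0f} yr)\n")

# cellular automaton: all-land settlement vs forest-only settlement
ca_null = run_ca(ref.series, CAParams(suitable_codes=frozenset({1, 2})),
                 ref.origin)
print(f"CA   null RMSE: {rmse(ca_null.arrival, ref.dates)[0]:7.1f} yr")
print(f"CA   alt  RMSE: {rmse(ref.result.arrival, ref.dates)[0]:7.1f} yr")

# equation-based model: uniform cost vs non-forest cost 4
raster = biome_at(ref.series, 5000.0)
speed = front_speed(FrontSpeedParams())
for name, cm in [("null", {1: 1.0, 2: 1.0}), ("alt ", {1: 1.0, 2: 4.0})]:
    surface = ebm_arrival(build_cost_surface(raster, cm), ref.origin,
                          speed, 5000.0, 500.0)
    print(f"EBM  {name} RMSE: {rmse(surface, ref.dates)[0]:7.1f} yr")
print("\nLower alternative-model RMSE in both frameworks: the dates carry "
      "the corridor delay, and only forest-aware dynamics reproduce it.")
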