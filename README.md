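# demicdiff

Spatial demic-diffusion modelling of the Tupi expansion across lowland
South America — and, more generally, of any farming population spreading
through a patchy, time-varying biome mosaic. The package asks a concrete
palaeoecological question: did Late-Holocene forest expansion open the
corridors through which Tupi-speaking farmers left the Amazon? It answers
it by simulating dispersal under a *null* hypothesis (all land equally
traversable/settleable) and an *alternative* hypothesis (non-forest biomes
are costlier or cannot be settled), then scoring both against dated
archaeological sites.

Two complementary models share one world — categorical biome rasters on an
equal-area grid of 50 × 50 km cells, one raster per 1000-year time slice:

- **Equation-based model (EBM).** The colonization front of a growing,
  diffusing population advances at the time-delayed Fisher speed

  $$v = \frac{2\sqrt{aD}}{1 + a\tau/2}, \qquad D = \frac{\langle\Delta\rangle^2}{4\tau},$$

  with annual growth rate $a$, mean displacement per generation
  $\langle\Delta\rangle$ (km) and generation time $\tau$ (yr). Arrival at a
  cell is the start date minus its least-cost distance from the origin
  (Dijkstra over a 16-direction knight's-move graph, edge weight =
  centre-to-centre length × mean endpoint friction) divided by $v$.
- **Cellular automaton (CA).** Per generation and per inhabited cell:
  logistic growth $N_t = KN_0/((K-N_0)e^{-a\tau}+N_0)$, density-dependent
  emigration $\varepsilon_t = \varepsilon (N_t/K)^{\gamma}$, equal
  redistribution to the available eight neighbours, leapfrogging up to
  150 km from forest-border cells when the neighbourhood is blocked, and
  relocation or extinction when the updated biome slice turns a settled
  cell unsuitable.

Evaluation keeps the earliest date per 100-km spatial bin (dates mostly
postdate first arrival, so later dates are uninformative about the front)
and reports the RMSE, in years, between simulated and observed dates. A
synthetic-data module generates corridor landscapes and date tables with
the same statistical structure as the real inputs, so the whole pipeline
is testable offline.

## Worked example

```bash
python examples/04_scenario_recovery.py
```

```
80 synthetic dated sites (lag mean 200 yr, noise sd 100 yr)

CA   null RMSE:  1502.3 yr
CA   alt  RMSE:   289.6 yr
EBM  null RMSE:  1091.6 yr
EBM  alt  RMSE:   357.1 yr
```

The dates were drawn from a forest-restricted reference run on a landscape
whose forest corridor opens at 3000 BP. Both null models cross the savanna
gap far too early and miss the dates by over a millennium; both
alternative models reproduce the "pulse and pause" delay and land within a
few centuries — the evaluation recovers the scenario that generated the
data. The other scripts in `examples/` walk through the front speed
(`1.050 km/yr` at the default demography), the least-cost arrival maps,
a full CA run, and the parameter sweep.

A thin CLI mirrors the pipeline (`demicdiff synth | ebm | ca | evaluate |
sweep`); landscapes travel as ESRI ASCII grids plus a manifest CSV, dates
as `site_id,x,y,med_cal_bp` CSV, and every run writes a JSON run record
with its resolved configuration.

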