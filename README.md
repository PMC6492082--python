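# n2opools

Source partitioning of soil N₂O emissions with a two-pool Rayleigh-type
isotope model.

When nitrate fertiliser is applied to soil under denitrifying conditions,
the emitted N₂O mixes nitrogen from two pools: the fertiliser-derived
nitrate (pool 1) and the native soil nitrate (pool 2). `n2opools` is for
biogeochemists working with flow-through soil-core incubations (DENIS-style
systems that measure NO, N₂O, N₂ and CO₂ fluxes directly) who want to
partition the N₂O flux between those pools and interpret its isotopic
signatures. It provides:

- **flux processing** — concentration → flux conversion, CO₂ baseline
  subtraction, cumulative emissions by trapezoidal integration over per-gas
  peak windows, total denitrification and the product ratio N₂O/(N₂O+N₂);
- **¹⁵N tracer partitioning** — converting atom-% ¹⁵N of emitted N₂O from
  5 at%-labelled vessels into the percent contribution of the fertiliser
  pool, and calibrating the cubic pool-mixing function f(x) used by the
  model;
- **the Rayleigh model** — forward simulation and net-isotope-effect (NIE)
  fitting of δ¹⁵N-bulk of emitted N₂O under one-pool and two-pool dynamics;
- **isotopocule descriptors** — site preference SP = 2(δ¹⁵Nα − δ¹⁵N-bulk),
  δ¹⁵Nβ, dual-isotope regression, and classification on the SP–δ¹⁸O map
  against user-supplied endmember regions and reduction lines;
- **a synthetic-experiment generator** with exact ground truth, so every
  stage can be validated by inversion without any external data.

## The model

For each pool, consuming nitrate down to a fraction *f* of its initial mass
enriches the residual substrate along the closed-system Rayleigh curve

```
δ_S = (δ_S0 + 1000) · f^(η_P–S/1000) − 1000,
f   = (N_NO3,i − N_N2+N2O) / N_NO3,i ,
```

where η_P–S is the net isotope effect of N₂O production from nitrate
(η = δ_product − δ_substrate, so normal fractionation is negative).
Instantaneously produced N₂O takes δ¹⁵N_N2O-p ≅ δ¹⁵N_NO3-r + η_N2O-NO3;
partial reduction of N₂O to N₂ shifts the surviving N₂O along a second
Rayleigh curve whose *f* is the measured product ratio N₂O/(N₂O+N₂), with
NIE η_N2-N2O. In the two-pool model, the tracer-calibrated cubic
f(x) (percent of emitted N₂O from pool 1 at day x) apportions each step's
N loss between the pools and mixes their emitted signatures:
δ_bulk = x₁δ₁ + (1−x₁)δ₂.

## Worked example

```python
import numpy as np
import n2opools as n

sc = n.SyntheticScenario(seed=1, noise_flux_rel=0.0,
                         noise_delta_permil=0.0, noise_at_percent=0.0)
_, truth = n.generate_fluxes(sc)
params = sc.params["1c"]
n2o, n2 = truth.fluxes["1c"]["N2O"], truth.fluxes["1c"]["N2"]

days = np.asarray(sc.unlabelled_days)
two = truth.trajectories["1c"]
obs = np.interp(days, two.times, two.delta_bulk_mixed)
res = n.fit_nie(days, obs, n2o, n2, sc.mixing["1c"], params.pools)
print(res.params.eta_production, res.params.eta_reduction, res.r_squared)
```

Running `python examples/03_two_pool_model.py` prints:

```
delta15N-bulk of emitted N2O (per mil):
  day   one-pool   two-pool   x1 (%)
   0.5    -29.94    -25.94    60.0
   2.0    -27.96    -25.20    66.5
   4.0    -20.92    -20.31    61.2
   6.0    -12.93    -14.66    46.6
   9.0     -4.96     -7.98    22.8
  11.0     -2.05     -5.14    15.9
true NIEs:   production -30.0, reduction -6.0 per mil
fitted NIEs: production -30.00, reduction -6.00 per mil  (R^2 = 1.0000, 81 starts)
```

The one-pool signal climbs steadily as the fertiliser nitrate enriches;
the two-pool signal is damped late in the incubation because the
less-fractionated soil pool takes over the emission (x₁ falls from ~60 %
to ~16 %). Fitting the sampled series recovers the generating NIEs
exactly on noise-free data.

The other `examples/` scripts cover flux processing, tracer calibration,
the isotopocule map and the end-to-end pipeline; each prints the numbers
it computes and what they mean. The same pipeline is available from the
shell:

```bash
n2opools all --outdir out --seed 1
```

which writes cumulative emissions, fold changes, the fitted mixing cubics,
NIE fits, trajectories, isotopocule tables and a manifest.

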