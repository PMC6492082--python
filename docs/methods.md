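# Methods

## Model and assumptions

`n2opools` treats denitrification in a closed incubation vessel as drawing
on one or two nitrate pools: pool 1, the nitrate added with the amendment,
and pool 2, the native soil nitrate. Each pool is a closed system for
Rayleigh fractionation — no nitrate input during the incubation, and the
NO and NO₂⁻ intermediates are assumed negligible in the N balance, so the
cumulative N₂O + N₂ loss measures pool consumption directly.

Per time step the model computes, for each pool:

1. the unconsumed fraction `f = (N_i − L(t)) / N_i`, with `L(t)` the
   cumulative N₂O+N₂-N loss apportioned to the pool (trapezoidal
   integration of the summed fluxes on the native bi-hourly grid);
2. the residual-substrate signature
   `δ_S = (δ_S0 + 1000)·f^(η_prod/1000) − 1000`;
3. the instantaneously produced N₂O, `δ_p ≅ δ_S + η_prod`;
4. the emitted (unreduced) N₂O by a second Rayleigh step with
   `f = r = N₂O/(N₂O+N₂)`, the instantaneous product ratio:
   `δ_e = (δ_p + 1000)·r^(η_red/1000) − 1000`.

In the two-pool variant the loss increment in each interval is split by
the pool-mixing fraction x₁ evaluated at the interval midpoint, and the
emitted bulk signal is the convex mixture `x₁δ₁ + (1−x₁)δ₂`. x₁(t) comes
from the tracer-calibrated cubic (percent scale, clamped to [0, 100]);
before the first labelled sample it extrapolates as the polynomial's t = 0
value, which the clamped cubic provides naturally. The one-pool variant is
the degenerate case x₁ ≡ 1 and is computed by the same kernel, so the two
agree bitwise when the mixing function is the constant 100 %.

Sign conventions, stated once and used everywhere: δ values are per mil vs
air-N₂ (¹⁵N) or VSMOW (¹⁸O); net isotope effects are
η = δ_product − δ_substrate, so *normal* fractionation is negative. The
literature is split on this sign; all defaults here (−30 ‰ production,
−6 ‰ reduction) follow the negative convention.

An open-system (steady-state) reduction form,
`δ_e = δ_p − η_red·(1 − r)`, is available behind the `reduction_form`
switch; the closed form is the default because the product ratio is an
instantaneous, per-step quantity here.

## Parameters

| parameter | units | default | rationale |
|---|---|---|---|
| η production (η_N2O-NO3) | ‰ | −30 (generator truth) | centre of the range observed for bacterial denitrification of nitrate |
| η reduction (η_N2-N2O) | ‰ | −6 (generator truth) | typical net effect of N₂O reduction on δ¹⁵N-bulk |
| pool-1 δ¹⁵N_NO3,i | ‰ | 0, with a loud log message | a measurable property of the applied KNO₃; must be supplied for real data |
| pool-2 δ¹⁵N_NO3,i | ‰ | +10 | literature value for native soil nitrate |
| pool-1 N mass | kg N ha⁻¹ | whole-vessel applied rate (25 for 1c, 75 for 3c) | the amendment is the pool |
| pool-2 N mass | kg N ha⁻¹ | ≈27.6 | soil NO₃⁻-N content 4.6·10⁻² mg N g⁻¹ dry soil × 285.9 g per vessel, per vessel area |
| pool-1 volume fraction | – | 0.33 (1c) / 1.0 (3c) | amended share of the vessel surface |
| CO₂ baseline | kg C ha⁻¹ h⁻¹ | 0.67 | constant respiration flux outside the amendment peak; subtracted from CO₂ only |
| integration windows | d | NO 0–4, N₂O 0–10, N₂ 4.5–9.5, CO₂ 0–10 | brackets of each gas's emission peak |
| natural abundance | at% ¹⁵N | 0.3663 | air-N₂ standard, R_std = 0.0036765 |

All are configuration, not constants: temperature/pressure of the
ideal-gas flux conversion (default 20 °C, 101.325 kPa), windows, baselines,
pool definitions and NIE bounds are arguments or config-file fields.

## Fitting

`fit_nie` is bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) on the residual
between the simulated mixed δ¹⁵N-bulk (interpolated to the observation
times) and the measured series. Because f(t), r(t) and x₁(t) do not depend
on the NIEs, they are precomputed once; each objective evaluation is then
a closed-form expression, making the deterministic multi-start cheap. The
start grid places each free NIE at every 10 ‰ across [−80, 0] ‰ (81 starts
for two free parameters); the best converged solution wins and
non-convergence from every start raises rather than returning a
best-so-far. δ_S0 of pool 1 can optionally float as a third free
parameter. R² = 1 − SS_res/SS_tot; for a zero-variance target it is
defined as 1 when the residuals vanish exactly and 0 otherwise. The same
convention applies to the cubic mixing fit, which is unweighted OLS on a
numerically scaled polynomial basis.

## Numerical choices and edge cases

- "Linear interpolation of the area between sampling points" is realised
  as the trapezoidal rule; window endpoints falling between samples are
  linearly interpolated, and integration never extrapolates beyond the
  observed range.
- Product-ratio points with non-positive denominator or negative fluxes
  are flagged undefined (NaN), never filled; the simulation carries the
  produced δ through such points, where nothing is emitted anyway.
- Fluxes driven negative by baseline subtraction are retained in
  integrals (conservative mass balance) but flagged.
- Pool exhaustion (cumulative loss ≥ initial nitrate) raises an error
  carrying the pool name and first offending time.
- Tracer fractions are clamped to [0, 1]; inputs outside the end-member
  interval beyond a small tolerance are logged.
- The Rayleigh expression is the delta-space approximation: against exact
  heavy/light atom bookkeeping it agrees to better than 0.5 ‰ for
  |δ|, |η| < 100 ‰ (tested), and to < 0.01 ‰ against direct numerical
  integration of the instantaneous fractionation ODE.

## Synthetic generator

The generator emulates the DENIS design: 12 vessels × 3 cores, three
treatments (1c, 3c, control; four vessels each, two labelled per amended
treatment), bi-hourly flux sampling over 12 days, isotopocule sampling at
days 0, 2, 4, 6, 9, 11 (unlabelled) and 0, 4 h, daily to day 7, day 11
(labelled). Emission pulses are gamma densities — fast rise, slow decay —
normalised so the analytic integral over each gas's standard window equals
the reference cumulative emission for that treatment; peak days follow the
observed flux shapes (NO day 1, N₂O day 3.5 for 3c and ~3 for 1c's
plateau, CO₂ day 3, N₂ delayed to day 5). CO₂ rides the constant
respiration baseline. δ¹⁵N-bulk is generated by the two-pool model itself
with the calibrated mixing cubics as truth; labelled at% follows the
two-end-member atom-fraction balance at% = x₁·5.0 + (1−x₁)·0.3663. Noise
is multiplicative Gaussian on fluxes (5 %), additive on δ (2 ‰) and at%
(0.1 absolute). Each vessel draws from its own stream keyed by
(master seed, CRC32 of the vessel id), so adding vessels never perturbs
existing ones.

What the generator does *not* emulate: SP and δ¹⁸O are phenomenological
interpolations through the reference measurements, not process model
outputs (the model describes δ¹⁵N only); there is no microbial growth or
enzyme kinetics, no spatial heterogeneity within a pool, no instrument
drift, and control-vessel δ¹⁵N is purely empirical. Passing tests
therefore demonstrate the *pipeline's* correctness and identifiability
under the stated conditions, not the model's adequacy for any particular
real soil.

## Design decisions

- The Rayleigh offsets use the standard (δ + 1000) convention throughout.
- The substrate fraction f is remaining/initial nitrate.
- Loss apportionment uses x₁ at interval midpoints (symmetric; any
  consistent choice is equivalent for fitting because the forward model is
  shared).
- Endmember polygons and reduction-line slopes for the SP–δ¹⁸O map are
  user configuration with no package defaults; the shipped example map is
  synthetic and labelled as such. Reduction progress is inverted from the
  SP displacement via the same closed-system Rayleigh convention as the
  main model.
- The dual-isotope regression is δ¹⁵N-bulk on δ¹⁸O by default (transpose
  available); the observed joint-enrichment ratio is treated as
  qualitative.
- Per-vessel screening of tracer fits uses a configurable R² threshold
  (default 0.89); it is config because per-vessel reference fits are not
  available to re-derive it.

## Problem sizes

Tests and examples run the full 12-vessel, bi-hourly (145-point) grid;
the Monte-Carlo recovery envelope frozen into the acceptance tests was
precomputed from 200 replicate fits at 2 ‰ observation noise on 6
sampling times, and the suite re-checks representative fixed-seed
replicates against it. The whole suite completes in a few seconds on one
CPU.

## Known limitations

- The delta-space Rayleigh form degrades for very strong enrichment
  (|δ| ≫ 100 ‰) or near-exhausted pools (f → 0); use the atom-fraction
  bookkeeping of the tests as a cross-check if operating there.
- η_production and η_reduction are assumed constant in time within a fit;
  the measured decline of net isotope effects at high denitrification
  rates is outside the model.
- The mixing cubic is an empirical summary of the tracer data; it carries
  no mass-balance constraint of its own beyond the [0, 100] % clamp.
- δ¹⁸O is never modelled mechanistically (O-exchange with water is
  process-dependent); it enters only as a map coordinate.
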