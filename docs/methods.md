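# Methods

`krillgrowth` implements a suite of eight published growth models for
Antarctic krill (*Euphausia superba*) behind one model contract, together
with the forcing layer, simulation protocol and intercomparison analytics
needed to compare them under identical environmental conditions. This note
documents the science of each component, the parameters that matter, the
numerical choices, and what the synthetic test conditions do and do not
show about real data.

## The model suite

All eight models map daily sea-surface temperature `T` (degC) and
chlorophyll a `F` (mg m^-3, the food proxy; POC = 50 F mg C m^-3 where a
model feeds on carbon) to a change in body length `L` (mm).

### Empirical models

**Instantaneous growth rate (Atkinson-type).** An additive regression

    DGR = a + b L + c L^2 + d F/(e + F) + f T + g T^2     [mm/d]

fit to summer field observations from the Scotia Sea region, with
juvenile, adult-female and all-krill parameterizations. The food term is
saturating (Michaelis-Menten), so the rate is non-decreasing in
chlorophyll; the temperature term is a downward parabola. The pure-rate
model applies the DGR every day (juvenile below the 35 mm stage switch,
all-krill above).

**Per-moult increment.** The same fits expressed per moult: the increment
at moulting is the DGR scaled by the reference intermoult period of the
calibration data (9.2 d juvenile, 10.5 d otherwise) and proportional to
body length relative to the calibration reference length. Moult-based
trajectories are stepwise constant: length changes only on moult days.

**Intermoult periods (IMP).** Two structurally different models:

* temperature-only (Kawaguchi-type): `IMP = 30 exp(-0.45 T)` days — an
  exponential decay, 30 d at 0 degC;
* length/stage/temperature (Tarling-type): adult females follow
  `IMP = 10 (L/35) / (1 + 0.03 T - 0.03 T^2)` — a hyperbolic temperature
  shape whose moult rate peaks at 0.5 degC, so IMPs lengthen above
  0.5 degC; 10 d at (0 degC, 35 mm). The juvenile fit
  `IMP = 9 (1 - 0.01 (T - 3)^2)` is nearly length-independent with an
  interior maximum at 3 degC.

The two IMP functions agree near 1.5-2.5 degC and diverge strongly below
1 degC and above 3 degC; at 0 degC the temperature-only IMP is three times
the adult-female Tarling IMP. Both composites use the Atkinson increment
evaluated at the mean temperature and chlorophyll over the elapsed IMP, so
growth at moulting reflects the conditions experienced since the previous
moult. Sea-ice days extend the IMP by one day each and are excluded from
the running means.

### Mechanistic models

**Carbon budgets (Hofmann/Lascara-type, Fach-type).** Body carbon
`W = 0.002 L^3` mg C. Ingestion saturates on POC (Ivlev form, saturation
constant 150 mg C m^-3) and scales with `W^(2/3)`; assimilation efficiency
0.8; respiration scales with `W^0.85` and a Q10 temperature correction.
The net carbon balance maps to a length change through `dW/dL` and is
capped at +0.25 mm/d; shrinkage is permitted. The Fach variant differs
only by a weaker respiration Q10 (1.5 vs 2.5) — a registry entry, not a
code branch. Heterotrophic and ice-algal food inputs are fixed to zero
because no plausible large-scale datasets exist for them; this lowers the
energy available to these models outside summer.

**DEB family (simplified and photoperiod variants).** In DEBkiss form,
assimilation scales with volumetric length squared and maintenance with
volumetric length cubed (volumetric length = shape factor x physical
length, shape factor 0.2). That allometry reduces, in physical length, to
a von-Bertalanffy equation

    dL/dt = rB(T) * s(P) * (f L_inf - L)

with `L_inf = 60 mm`, `rB = 0.0035 /d` at 0 degC and an Arrhenius
temperature correction (T_A = 7421 K). Growth ceases at ~60 mm because
maintenance overtakes assimilation — the asymptote holds for any f <= 1.
`f` is a Holling type II response `F/(F + 1.35)`; the simplified variant's
original publication assumed unlimited food (`f = 1`), and this suite
follows the intercomparison protocol of borrowing the photoperiod
variant's food scaling instead (an `unlimited_food` flag restores the
original assumption). The photoperiod variant multiplies both ingestion
and maintenance by a bounded day-length activity
`s(P) = 0.45 + 0.55 P/24` (monotone over [0, 24] h), which lowers the
energetic cost of the dark season at high latitudes; the simplified
variant has `s = 1`.

**Energy partitioning (Ryabov-type).** Holling II uptake with a much
lower half-saturation (0.35 mg m^-3, reflecting its in-situ calibration
data with modest bloom peaks), metabolism charged first and the residual
allocated to somatic growth, in the same von-Bertalanffy reduction with
rate constant 0.004 /d. The low half-saturation makes it the only
mechanistic model with positive growth at 0.3 mg chl m^-3, and it grows
roughly +5 mm over a 166-day season of moderate (~0.8 mg m^-3) food.

**Winter metabolic switch.** The carbon-budget and energy-partitioning
models reduce metabolism by a fixed factor (0.5) inside a calendar window
(1 May-30 Sep, late fall to early spring in the south). The window lies
entirely outside the 1 Nov-15 Apr simulation protocol, so the factor is 1
throughout every standard run — asserted by a config-audit test.

## Parameter provenance

The coefficient registries (`krillgrowth/registry/*.yaml`) carry one
citation per coefficient and the calibration metadata (region, season,
food proxy, chlorophyll range) of each model/stage. The all-krill
Atkinson growth equation is transcribed verbatim from its widely-quoted
published form. The remaining coefficient sets could not be transcribed
digit-for-digit from the original publications; they were reconstructed
from the published functional forms and calibrated, once and before any
simulation, against the published benchmark behaviours of each model:
the 30 d / 10 d IMP contrast at 0 degC, the >0.3 mm/d juvenile surface
peak, the 0.25 mm/d cap with onset at 1.4-1.7 mg chl m^-3, the ~60 mm DEB
asymptote, the opposite growth signs of the simplified DEB and the
Tarling composite at (1 mg m^-3, 0 degC), the adult-female IMP rising
above 0.5 degC and the juvenile IMP maximum at 3 degC, and the relative
food sensitivities of the mechanistic models. Quantities that depend on
coefficients beyond these anchors (e.g. exact trajectory magnitudes)
should be read as representative of each model family's behaviour, not as
digit-level reproductions of the original codes.

## Forcing

* **Photoperiod** is sunrise-to-sunset hours from the standard
  solar-declination formula with a zero-elevation horizon and no
  twilight, saturating at 0/24 h inside the polar circles. Against a
  NOAA-style solar-position computation the simple declination is good to
  ~0.25 h, adequate since only the photoperiod-DEB model consumes it
  through a gentle linear scaling.
* **Climatologies** are per-cell day-of-year means (365 bins, 29 February
  folded onto day 59) over the available observations only; cells with
  fewer samples than a configurable minimum are flagged, not dropped.
  Input grids are block-mean downsampled to the target resolution
  (default 0.25 degrees; the target must be an integer multiple of the
  input spacing) and smoothed with a centered 15-day rolling mean that
  ignores missing values. NetCDF I/O uses the NetCDF3 (classic) dialect.
* **Units are fixed** at degC, mg m^-3, mg C m^-3 and hours; the
  climatology reader fails loudly when a file's units attribute does not
  match.
* **Polar-front mask**: the mean front line (per-longitude average of
  weekly boundary lines) masks out cells north of it; the boundary must
  span the grid's longitudes.

## The synthetic season

The synthetic South-Orkney-like forcing (1 Nov-15 Apr, 166 days,
latitude -60.7) anchors the start exactly at -1.5 degC and
0.3 mg chl m^-3, places a Gaussian bloom (amplitude 1.0 mg m^-3,
sigma 25 d) at 15 January — peak ~1.3 mg m^-3, declining through
February onward — and an SST sinusoid peaking at ~0.8 degC in
mid-February. These values emulate a multi-year satellite climatology of
the region, in which the 15-day smoothing and across-year averaging
flatten individual bloom peaks. What passing tests on this forcing show
is the *relative* behaviour of the models — sign changes, orderings,
divergence — under a realistic seasonal envelope. They do not show skill
against in-situ data, interannual variability, extreme blooms (>2 mg
m^-3, where several mechanistic models would leave their insensitive
regime), sea-ice dynamics, or heterotrophic food, all of which the
generator omits by design. Optional Gaussian noise (seeded, default off)
exercises reproducibility, not realism.

## Simulation protocol and numerics

* Window 1 Nov-15 Apr inclusive (166 daily steps); one 26 mm individual
  per location (the smallest common calibrated size); stage switch at
  35 mm (to all-krill parameters for the Atkinson family, adult-female
  for the Tarling composite; re-evaluated daily for the pure-rate model,
  at moult events for the moult-based ones, since length cannot change
  mid-IMP).
* Continuous-rate models integrate with RK4 by default (forcing
  interpolated linearly between consecutive daily values for the
  half-step), Euler as an option; the two agree within 0.1 mm over a
  season, which is a test. Moult-based models advance by discrete daily
  events and are integrator-independent.
* IMP durations are rounded to whole days (minimum 1) for the clock;
  response surfaces use the unrounded IMP, so trajectory-vs-surface
  agreement is exact up to that rounding.
* The first IMP at simulation start is drawn from the IMP function at
  day-1 conditions with zero elapsed days — a deterministic choice, since
  the initial moult phase is unobservable.
* Sea-ice days: growth is zero for every model and, by default, no
  metabolic cost is charged (`charge_maintenance_on_ice` enables the
  alternative for sensitivity analyses); IMP clocks extend by one day per
  ice day. Permanently ice-covered cells therefore end at exactly their
  initial length.
* Negative increments shrink the individual (no floor; a floor at zero is
  available for sensitivity runs). Lengths are kept positive and finite;
  non-finite states raise immediately.
* Grid runs are embarrassingly parallel with a determinism contract:
  results are independent of execution order and chunking, and identical
  configuration + registry + forcing is bit-reproducible.

## Analytics

* Response surfaces default to sst in [-2, 4] degC and chl in [0, 5]
  mg m^-3 at 0.05 steps (the exact published axis ranges are not stated;
  these cover circumpolar habitat conditions) for a 26 mm krill on
  15 January with photoperiod 20 h. The photoperiod is an explicit
  argument because the reference day length does not identify a unique
  latitude.
* Required-chlorophyll inverts a model's rate-vs-food curve by bisection
  on [0, 20] mg m^-3 to 1e-3; monotonicity is verified on a scan first,
  and targets above a model's plateau/cap return "unreachable".
* Ensemble spread and divergence maps use population standard deviations
  (divide by the number of models — the model set is the whole
  population, not a sample). CV = SD/|mean| of final lengths; cells with
  |mean| below 0.1 mm are flagged undefined rather than dropped.

## Known limitations

Reproduction/spawning fluxes of the DEB models, overwintering dynamics
beyond the metabolic switches, larval stages, heterotrophic and ice-algal
food fields, advection between grid cells, mortality and parameter
uncertainty propagation are out of scope. The chlorophyll:POC ratio is a
fixed 50 although it varies seasonally from ~20 to ~100 in the Southern
Ocean, biasing the carbon-fed models. All conclusions drawn from this
package concern model behaviour under a shared forcing protocol, not
validated krill growth.
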