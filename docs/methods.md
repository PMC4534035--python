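# Methods

`standclim` couples a daily forest water balance to an annual stand
growth, decomposition and nutrient-cycling engine through normalized
climate response indices. This note records the model equations, the
defaults and their units, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Daily water balance

The soil is a stack of buckets (humus over mineral horizons). Each
layer's storage capacity is `field_capacity x depth x (1 - coarse/100) x 10`
mm; each species has its own wilting point per layer kind below which it
cannot extract water. The daily update order is fixed and pinned by
tests: rain/snow split → degree-day snowmelt → canopy interception →
infiltration → per-species uptake (in configuration order) → soil
evaporation → drainage cascade. Water above field capacity cascades
downward; bottom-layer excess leaves as deep drainage. The daily budget
`P = ΔS + interception + transpiration + soil evaporation + drainage`
closes to ~1e-13 mm.

Potential evapotranspiration is Priestley–Taylor,
`PET = α · Δ/(Δ+γ) · R_net/λ` with α = 1.26, γ = 0.066 kPa °C⁻¹ and
λ = 2.45 MJ kg⁻¹. Shortwave radiation is partitioned through canopy
strata (trees shade understory shades soil) by Beer–Lambert extinction
with k = 0.5; within a stratum species share the intercepted flux in
proportion to leaf area, each absorbing `1 - albedo` of its share.
Per-species transpiration demand is the PET of its absorbed radiation
divided by `1 + R_canopy`. Actual uptake is capped by the
occupancy-weighted plant-available water and withdrawn from layers in
proportion to `occupancy x available`, which cannot draw any layer below
the species' wilting point. The daily transpiration deficit index is
`TDI = (demand - actual)/demand`, defined as 0 when demand is 0 (the
winter convention; this matters for annual TDI means and is pinned by a
test).

Several sub-process closures are this package's own documented
defaults, exposed as module constants: canopy interception storage
0.2 mm per unit LAI (intercepted rain evaporates the same day, without
debiting the energy budget), degree-day snowmelt at 3 mm °C⁻¹ day⁻¹
above 0 °C, and a soil-evaporation supply factor `1 - exp(-3 w)` in the
humus layer's relative water content (suppressed under snowpack).
Whether canopy resistance belongs inside PET or only in the demand
partition is a genuine ambiguity; here it enters multiplicatively as
`1/(1+R)` on the demand side, consistent with the additive resistance
adjustment of the CO₂ response and with resistance values of order 0.3.
There is no lateral flow, soil freezing, or infiltration-rate limit.

## CO₂ and water use efficiency

Relative net assimilation
`A_n(rel) = [(c_a - r′)(c_a0 + 2r′)] / [(c_a + 2r′)(c_a0 - r′)]` with
compensation point r′ = 40 ppm; relative stomatal conductance
`g_w(rel) = A_n(rel)/(c_a/c_a0)`; adjusted canopy resistance
`R_adj = R_ref + R_ref (1 - g_w(rel))`. At the reference concentration
the chain is the identity. `c_a0` is configurable (360 ppm matches
published conductance compilations; 380 ppm is the 2005-pinned reference
scenario default) and is never hard-coded. Below the compensation point
the assimilation branch is negative and nonphysical; it is clamped to
zero inside the conductance/resistance pipeline, while the raw closed
form remains available (and is what root-finding on the compensation
point needs). There is no direct CO₂ fertilization of growth.

## Growth indices and climate-limited growth

Daily growth potential is `GRI_day = T_growth(T) · S_growth(TDI)`, a
product of piecewise-linear response curves (clamped outside their
breakpoints). Annual `GRI` is the 365-day sum. Calibration averages
annual GRI over the reference climate into `NGRI`; each simulated year
then carries `CRF = (GRI - NGRI)/NGRI`.

The printed form of the growth coupling (base rate times CRF) would
zero out growth in an average year while the factor is described as
"near zero for a year similar to the historical average"; the two are
reconcilable only as `CGR = BGR · (1 + CRF)`, which this package
implements, with CRF floored at -1 so growth cannot go negative. The
same `1 + CDF` reading applies to decomposition. This is the package's
single most consequential interpretive choice and is deliberately
prominent here.

The temperature curves break dormancy sharply near 5 °C with
species-specific optima and high-temperature declines; the exact
breakpoints are editable config, not constants. The temperature-limited
growing season is counted as days with `T_growth ≥ 0.25`.

## Decomposition and nitrogen

The daily decomposition index per layer is
`DRI = T_decomp(T) · M_decomp(w)`. `T_decomp` is a Q₁₀ = 2 exponential
anchored to 1.0 at 25 °C and capped there, so responses double per
10 °C everywhere below the cap. `M_decomp` takes *relative* water
content (fraction of field capacity; the absolute-vs-relative choice is
not externally fixed and relative is used) with distinct curves for
litter, humus and mineral soil. A virtual "litter" index layer shares
the humus layer's moisture but uses the litter curve. Annual DRI sums
are normalized over the reference into per-layer `NDRI`, giving
`CDF = (DRI - NDRI)/NDRI`, computed per layer and applied to every
cohort resident in that layer.

Litter cohorts lose `BDR · (1 + CDF)` of their mass annually (clamped
to [0, 1]); nitrogen is released proportionally, with no immobilization
phase and no litter-mixing effects. When remaining mass falls to the
transfer threshold (default 0.175 of original, configurable within the
0.15–0.20 range) the residue moves to humus, split 80/20 between the
active and passive pools (the split is not externally specified; it is
a config fraction). Humus decays at `(1/residence) · (1 + CDF)`; under
a neutral climate the implied residence times are exactly the
configured 50 (active) and 600 (passive) years. The annual
decomposition step runs on start-of-year pools, before the current
year's litter inputs (the alternative ordering is not recoverable from
the model description; this one is pinned by the budget tests).

Mineralized N plus 2 kg ha⁻¹ y⁻¹ of deposition feeds the available-N
pool; half of any N left unused at the end of a year leaches below the
rooting zone. Mass and N budgets (live + litter + humus + available +
leached) close to ~1e-15 relative per year.

## Stand engine

The growth core is intentionally minimal: light-limited potential =
radiation-use efficiency (0.3 g DM per MJ absorbed growing-season
shortwave) times absorbed May–Sep radiation, down-regulated by a Liebig
nitrogen modifier `min(1, supply/demand)`. It is isolated behind one
function so a calibrated engine could replace it. Allocation fractions
(foliage 0.25, sapwood 0.35, branches 0.10, fine roots 0.20, coarse
roots 0.10), per-pool turnover, tissue N concentrations and specific
leaf areas are editable per-species defaults chosen to be realistic for
montane interior conifers; they are not externally prescribed values.
LAI is `0.1 · SLA · foliage mass`.

Drought mortality evaluates a species response curve at the two-year
running mean of growing-season (May 1–Sep 30) mean TDI, so consecutive
dry years kill more trees than an isolated one; a 0.5 % y⁻¹ background
rate adds independently. Dead foliage/fine roots route to fast litter
types, dead wood to slow snag types, and the resulting leaf-area loss
lowers the next year's water demand — the stabilizing feedback that
caps die-off episodes. The curve breakpoints were placed iteratively
against the reference-climate baseline (growing-season mean TDI on the
summer-dry default site is ~0.65–0.70) so that baseline drought
mortality stays sub-percent while drier-than-reference years climb
steeply; Douglas-fir's curve sits at or below lodgepole pine's at every
stress level (the assumed tolerance ordering, asserted on the shipped
defaults).

## Calibration and the cycling identity

Calibration runs the daily pass over the reference climate with a fixed
canopy (default LAI 2.5 per species) at the reference CO₂ and averages
the annual indices. Because capacity clamping during spring recharge in
this snow-dominated climate erases soil-moisture memory, the
end-of-year water state converges to an exactly periodic fixed point;
`calibrate` iterates full reference passes (at most a handful) until
the end state reproduces the start state bit for bit and reports that
state as the run's initial condition. A reference series cycled five
times and run from that state reproduces every cycle exactly, so the
mean CRF and CDF over each cycle vanish to floating-point noise — an
algebraic identity of the normalization, verified to 1e-10 in the
acceptance suite.

## Climate inputs

Fixed 365-day calendar (Feb 29 dropped on read) keeps cycling and
day-index arithmetic exact. Shortwave radiation, when not supplied, is
estimated from the diurnal temperature range with the Bristow–Campbell
model (`tau = a(1 - e^{-b ΔT^c})`, a = 0.7, b = 0.005, c = 2.4) applied
to closed-form extraterrestrial radiation. Scenario downscaling is the
delta method: 12 monthly temperature offsets and precipitation ratios
per anchor period, interpolated linearly on the year axis between
anchors (the interpolation rule between anchor periods is an
assumption; constant extrapolation beyond the last anchor), applied to
the cycled reference so observed interannual variability is retained;
CO₂ follows the scenario trajectory. Snow fraction, when not supplied,
ramps linearly from all-snow at 0 °C to all-rain at +2 °C.

The synthetic generator emulates a montane interior climate: sinusoidal
seasonal temperature (annual mean 3.6 °C, amplitude 12 °C, giving a
May–Sep mean of ~12.5 °C) with an AR(1) daily anomaly (SD 3 °C,
autocorrelation 0.7), seasonal occurrence/amount precipitation
(winter-wet, summer-dry, ~450–470 mm y⁻¹), and a constant 380 ppm CO₂
unless a scenario overrides it. It does **not** reproduce real-weather
features such as multi-day synoptic persistence beyond AR(1), extreme
events, trends within the reference period, or temperature–
precipitation cross-correlation. Passing tests therefore demonstrate
the internal consistency and qualitative climate sensitivity of the
model, not agreement with any particular station record.

## Established-stand runs

For scenario runs flagged `established`, the first 60 simulated years
repeat the reference climate (cycled) before the perturbation begins,
so the stand reaches the climate-change period at age 61 with the high
leaf area that makes older stands drought-vulnerable.

## Problem sizes and determinism

Default experiment sizes are a 30-year reference, 100-year coupled runs,
and 1000-replicate Monte-Carlo noise experiments; a century of coupled
simulation takes a few seconds. All randomness flows from a single
configured seed (synthetic climate, chronology noise); the hydrology,
indices and stand update are fully deterministic, and identical
configurations reproduce bit-identical output tables.

## Known limitations

No phenology (bud break, frost), no disturbance agents (fire, insects),
no soil temperature or freeze–thaw, no lateral water flow, no
individual-tree competition or height/diameter structure, no direct CO₂
fertilization, no litter-mixing effects, and a stand-in growth core in
place of a bioassay-calibrated engine. Scenario results on the synthetic
climate are direction checks, not site predictions.
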