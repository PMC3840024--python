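# Methods

## Scope and framing

`nscsim` models one forest stand as a single 30 m grid cell: vertical
water and carbon fluxes only, no lateral routing, streamflow, deep
groundwater, nitrogen cycling, or multi-species canopies. The stand is a
homogeneous evergreen conifer (parameter defaults describe montane
ponderosa pine). The scientific object is the non-structural carbohydrate
(NSC) pool: how storage allocation and canopy-restoration rules shape the
minimum reserve a stand carries through a multi-year drought, and hence a
carbon-starvation-style index of mortality risk.

## Forcing

Inputs are daily Tmax/Tmin (°C) and precipitation (mm) at a reference
station (default elevation 2262 m). Site series are produced by a linear
elevation adjustment: precipitation is multiplied by a per-site scalar
(1.27 / 1.03 / 0.85 for the high/mid/low presets at 2767 / 2308 / 2002 m)
and temperatures follow lapse rates of −5.7 (Tmax) and −5.3 (Tmin) °C/km.

Because only Tmax/Tmin/precip are observed, the remaining drivers are
estimated with standard empirical forms, chosen here as documented
substitutes (no claim is made that they match any particular station's
calibration):

* **Shortwave** = top-of-atmosphere radiation (standard solar-geometry
  formulae) × Bristow–Campbell transmissivity
  `τ = 0.75 (1 − exp(−0.005 ΔT^2.4))`, increasing with the diurnal range.
* **PAR** = 2.3 mol per MJ shortwave.
* **VPD** = `e_sat(T_day) − e_sat(T_min)`, with dewpoint taken as Tmin and
  `T_day = T_avg + 0.45 (T_max − T_avg)`; an isothermal day therefore has
  zero VPD.
* **Mean temperature** = (Tmax + Tmin)/2.

### Synthetic climate generator

The generator emulates a semi-arid continental mountain climate with the
bimodal precipitation regime typical of the southern Rockies: a winter
(Dec–Jan) peak and a stronger July–August monsoon peak. Monthly normals
(mm): 50, 35, 35, 20, 25, 25, 85, 90, 45, 30, 30, 55 (annual ≈ 525 mm at
the station). Wet-day occurrence is a first-order Markov chain with
monthly stationary wet probability (0.20–0.45, monsoon highest) and a
+0.20 wet-day persistence boost; wet-day amounts are gamma distributed
(shape 0.75). Temperature is a seasonal sine (annual mean 9 °C, amplitude
10 °C, warmest 20 July) plus AR(1) anomalies (σ = 2.5 °C, ρ = 0.65), with
a diurnal range of 14 °C on dry and 7 °C on wet days. Series start 1
October (water-year convention); everything is reproducible from a single
seed.

A drought block spans whole water years: daily precipitation is scaled by
a multiplier (default 0.5) and temperatures shifted (default +1 °C),
emulating a severe multi-year drought such as the 1999–2002 southwestern
event. The default protocol places a 3-year block in water years 15–17 of
a 23-year record, after a 7-year transient lead-in, giving a 16-year
evaluation window.

What the generator does *not* emulate: multi-year precipitation
persistence (beyond the imposed drought block), elevation-dependent storm
types, wind/humidity observations, and observed spell structure. Passing
tests therefore demonstrate the model's process behaviour under a
statistically plausible climate, not agreement with any measured record.

## Water balance

Daily order: phase partition → snowpack → interception → infiltration →
evaporation/transpiration → drainage. All stores in mm.

* Rain/snow: linear ramp on daily mean temperature between −2 and +2 °C.
* Snowmelt: `melt = min(SWE + snowfall, k_t max(0, T − T_melt) + k_r R ·
  [T > T_melt])` with k_t = 2 mm/°C/day, k_r = 0.25 mm/MJ — a hybrid
  temperature/radiation index standing in for a full energy budget.
* Interception: canopy capacity 0.3 mm per unit LAI; litter store 2 mm,
  first draw. Intercepted water evaporates at Priestley–Taylor potential.
* Soil: one plant-available bucket (depth 180 / 220 / 120 mm for
  high/mid/low, reflecting the survey ordering mid > high > low of water
  holding capacity). Tension follows Brooks–Corey,
  `ψ = ψ_ae S^(−1/λ)` (stored as a positive magnitude in m of water;
  capped at 10⁴ m when dry). Air-entry and pore-size values per site:
  (0.159, 0.16), (0.175, 0.168), (0.125, 0.139).
* Drainage: water above field capacity (tension 3.4 m) leaves the column
  with daily fraction `1 − exp(−ksat(z)/K₀)`, K₀ = 2000 m/day, where
  `ksat(z) = ksat_max e^(−z/m)` is evaluated at the water-table depth
  implied by a stationary saturation deficit (default 120 mm over
  effective porosity 0.4, z ≈ 0.3 m). Recharge is exported as baseflow
  the same day, so the deficit never moves; saturation excess joins
  drainage. At the default depth the coarse low-site soil
  (ksat_max 3667, m 0.38) sheds free water faster than the high site
  (764, 8.75), which is what lets the high site carry more plant-available
  water through a dry month.
* Transpiration: Penman–Monteith with aerodynamic conductance 0.02 m/s,
  canopy net radiation `max(0, 0.85 SW − 1.5) (1 − e^{−k·LAI})`, and the
  Jarvis conductance below; supply-capped by the bucket.
* Jarvis multipliers: hyperbolic PAR response (half-saturation
  200 µmol m⁻² s⁻¹), linear VPD closure 0.5→3.5 kPa, linear tension
  closure 80→300 m, trapezoidal temperature response (0/10/30/42 °C),
  weak linear CO₂ response about 390 ppm; g_s,max = 5 mm/s per leaf area,
  scaled by LAI.

No bare-soil evaporation is modelled (litter evaporation is the surface
loss term); this keeps the supply budget conservative in a closed-canopy
framing.

## Carbon cycle

* **GPP**: Farquhar kinetics with Bernacchi-style Arrhenius temperature
  responses (Vcmax25 = 55 µmol m⁻² s⁻¹, Jmax:Vcmax = 1.67, quantum yield
  0.24 mol e⁻/mol photons). Each leaf class solves
  `min(A_c, A_j)` jointly with diffusion `A = g (C_a − C_i)` (quadratics
  in `C_i`, taking each limitation separately). The canopy is a two-class
  big leaf: sunlit LAI `(1 − e^{−k·LAI})/k` (k = 0.5) receiving direct +
  diffuse PAR, shaded LAI receiving attenuated diffuse
  (`0.25 I₀ e^{−0.5 k LAI}`). Leaf conductance to CO₂ uses
  elevation-dependent barometric pressure.
* **Maintenance respiration**: per-tissue N (C:N 42 leaf, 58 fine root,
  50 wood; live fractions 8 % of stem, 20 % of coarse root) × 0.218 gC/gN
  at 20 °C, with Q10 that acclimates to a 30-day running-mean temperature
  (`Q10 = 2.0 − 0.046 (T_acc − 20)`, clipped to [1.3, 3.2]); warmer-grown
  stands respond more flatly. At exactly 20 °C respiration equals the base
  sum regardless of acclimation state, which the tests exploit.
* **Allocation**: available net photosynthesis pays a 30 % growth-cost on
  structure. The leaf fraction is `0.45 / (1 + 0.35 LAI)` — the
  declining-with-LAI shape of age/LAI-based allocation schemes — with fine
  roots matching leaves 1:1 and the woody remainder split 75:25
  stem:coarse-root. The specific coefficients are this package's own
  defaults (the shape, not the numbers, is the constraint) and are the
  main calibration surface together with SLA (4 m² per kgC leaf).
* **Turnover**: annual rates compounded daily as `e^{−rate/365}` so a year
  of daily steps is exactly `e^{−rate}` (the closed form the tests
  assert). Defaults: leaf 0.27/yr, fine root 0.5/yr, branch 0.01/yr,
  coarse root 0.01/yr. Stand mode adds a 5 %/yr background whole-tree
  turnover to leaf, stem and coarse root; tree mode instead zeroes
  stemwood turnover (tree-scale rather than stand-scale accounting).

## NSC dynamics

On a positive-NPP day, a fraction *NSC/NPP* of that day's NPP enters
storage until the pool reaches 20 % of plant structural carbon; applying
the annual fraction to each day's positive NPP makes it equal to the
annual fraction summed over positive days, avoiding an arbitrary annual
settlement date. Because growth respiration applies only to the
grown share, the accrual and NPP are solved jointly (a one-line linear
solve) so that stored carbon is exactly the stated fraction of realised
NPP. The cap is denominated against structural carbon only, per the
definition of the pool as a percentage of plant structural biomass.

On deficit days the pool pays respiration first; an empty pool leaves the
deficit unmet, which is flagged and counted as an energy-deficit day but
never drives pools negative — a deliberate model-limit signal rather than
a crash.

If leafC/AGC falls below *MinL/AGC* (valid range 0–0.25, an upper bound
grounded in observed leaf:aboveground ratios of mature stands), storage is
mobilised to rebuild foliage, with fine roots built 1:1 alongside and
growth respiration paid. At most 1/30 of the remaining leaf gap moves per
day, preventing single-day refoliation (the rate is otherwise
unconstrained by data); transfers never overshoot the target ratio.
*MinL/AGC* = 0 therefore means reserves fund respiration only — the
cumulative NSC-to-foliage flux is identically zero.

If turnover shrinks structural carbon under a full pool, the small excess
above the cap is re-allocated to structure the same day so the cap
invariant `0 ≤ NSC ≤ 0.2 × structural` holds at every step without
destroying carbon.

Mortality risk is a diagnostic overlay on the evaluation window: **high**
if the window-minimum NSC:AGC ratio is strictly below 0.5 %, **moderate**
in the closed band [0.5 %, 1.0 %] (the "near the threshold" zone; the
band width is configurable), **low** above. Classification never zeroes
LAI or halts the run, so the carbon-cycle trajectory through a predicted
mortality event remains visible.

## Experiment protocol and problem sizes

* **Spinup**: 100 years from seedling pools (leaf 30, stem 50, coarse root
  15, fine root 25, NSC 15 gC/m²), cycling the available record. The
  stabilisation diagnostic (relative biomass change over the final 20
  years) is below 5 % on the default synthetic gradient. Stand biomass
  orders high ≥ mid ≥ low.
* **Evaluation window**: 7-year lead-in (absorbing transients from
  switching NSC parameters) + 16-year window with the drought block;
  window statistics (min NSC, min NSC:AGC, min LAI, risk) exclude the
  lead-in.
* **Sensitivity grids**: full factorial over *NSC/NPP* × *MinL/AGC*, stand
  mode (per-site spinup states) or tree mode (mid-site state cloned across
  sites, no stem turnover, NSC comparisons normalised by biomass). The
  per-site threshold statistic is the smallest *NSC/NPP* (grid step 0.02)
  whose third-quartile minimum NSC across the *MinL/AGC* axis is positive;
  `inf` marks non-attainment within the sweep. On the default scenario the
  statistic orders low ≥ mid ≥ high — drier, warmer sites need more
  storage allocation to keep reserves positive — with the low site not
  attaining a positive third quartile within the 0.05–0.5 sweep.
* **Climate swaps**: tree-mode runs exchanging the site-adjusted
  precipitation series, temperature series, or both between the gradient
  endpoints, plus an all-rain scenario that disables the snow phase
  entirely. Directions on the default scenario: the low site gains mean
  NPP under high-site precipitation; all-rain zeroes SWE everywhere and
  steepens the high site's early-drought NSC drawdown (a small effect, as
  expected of a snow-timing signal).
* **Growth correlation**: Pearson r between per-water-year modeled growth
  (NPP plus storage drawn for regrowth) and an observed basal-area
  increment series, requiring ≥ 3 overlapping years and non-degenerate
  variance.

Test-suite problem sizes (30–100 years, 1–3 sites, ~0.02 s per simulated
decade) were chosen so the full protocol — including the 23 × 4 × 3
threshold grid — runs in about two minutes.

## Numerical choices and edge cases

* Daily closure (water and carbon) asserted at 1e−9 relative error every
  step; violations abort the run as internal bugs.
* Dry soil returns the configured tension cap (10⁴ m), never infinity;
  fully supply-limited melt and transpiration never drive stores negative.
* Risk boundary: exactly 0.5 % classifies as moderate (closed band).
* Turnover mode is an explicit argument; unknown modes and scenario
  labels raise immediately.
* All stochastic paths take explicit integer seeds; identical
  configuration and seed reproduce every output byte-for-byte.

## Known limitations

* A known sensitivity of stand-versus-tree comparisons: whether the
  spun-up (larger-biomass) stand shows a lower biomass-normalised minimum
  NSC than a mid-sized tree under the same climate depends on the storage
  fraction — larger stands carry both more respiring tissue *and* a larger
  storage cap, and below *NSC/NPP* ≈ 0.35 the cap effect dominates in this
  implementation.
* Constant low-intensity drizzle is almost fully intercepted by the litter
  store; realistic event-based rainfall (which the generator produces)
  does not show this artefact.
* The drainage formulation collapses saturated-zone dynamics to a
  stationary deficit; it preserves the cross-site conductivity contrast
  but cannot represent water-table rise.
* NPP is reported net of *paid* respiration; unmet respiration on
  energy-deficit days is flagged rather than forced onto the pools.
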