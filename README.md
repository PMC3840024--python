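# nscsim

A stand-level, daily-timestep simulator of coupled forest water and carbon
cycling with an explicit non-structural carbohydrate (NSC) pool, built to
study drought-induced tree mortality risk in semi-arid conifer forests —
the canonical case being ponderosa pine stands spread along a mountain
elevation gradient, where a multi-year drought kills the low, dry-edge
stand while higher stands survive.

It is aimed at ecohydrologists and forest ecophysiologists who want a
desk-scale, fully reproducible testbed for carbon-starvation-style
mortality indices: every experiment runs from synthetic or CSV daily
weather (Tmax, Tmin, precipitation) in seconds on one CPU.

## Model

Each day, for one 30 m stand cell:

* **Water** — precipitation is split rain/snow on mean temperature; a
  hybrid temperature/radiation index melts the snowpack; rain is
  intercepted by canopy (∝ LAI) and litter stores; a single Brooks–Corey
  soil bucket supplies transpiration, with free water draining at a rate
  set by the saturated conductivity profile `ksat(z) = ksat_max e^(−z/m)`.
  Transpiration demand is Penman–Monteith with a Jarvis multiplicative
  canopy conductance `g_c = g_s,max · LAI · f(PAR) f(VPD) f(ψ) f(T) f(CO₂)`.
* **Carbon** — GPP from Farquhar leaf biochemistry
  `A = min(A_c, A_j)` coupled to `g_c` through intercellular CO₂, scaled
  over sunlit/shaded canopy fractions; maintenance respiration from tissue
  nitrogen with a temperature-acclimating Q10; net growth allocated with a
  leaf fraction that declines as LAI builds (fine roots track leaves,
  stems and coarse roots take the remainder); fixed annual turnover
  compounded daily.
* **NSC** — two free parameters: *NSC/NPP*, the fraction of positive daily
  NPP stored (until the pool reaches 20 % of structural carbon), and
  *MinL/AGC*, a threshold leaf:above-ground-carbon ratio below which
  reserves are mobilised to rebuild foliage. Respiration deficits draw on
  the pool first. Mortality risk is classified from the window-minimum
  NSC:AGC ratio: **high** below 0.5 % of above-ground biomass, **moderate**
  near it, **low** above.

Water and carbon balances are closure-checked to 1e−9 relative error on
every simulated day.

## Worked example

Run the standard drought protocol — 100-year spinup per site, then a
7-year lead-in plus 16-year evaluation window whose water years 15–17 are
a severe drought (precipitation halved, +1 °C):

```bash
nscsim --config drought.yaml --out out run
```

with `drought.yaml`:

```yaml
forcing:
  years: 23
  seed: 2
  drought: {start_year: 15, duration_years: 3, precip_multiplier: 0.5, temp_offset_c: 1.0}
experiment:
  spinup_years: 100
  lead_in_years: 7
nsc: {nsc_npp_frac: 0.3, minl_agc: 0.05}
```

prints

```
INFO nscsim: spinup high: biomass 2272 gC/m2, 20-yr rel change 0.068
INFO nscsim: spinup mid: biomass 1878 gC/m2, 20-yr rel change 0.064
INFO nscsim: spinup low: biomass 1283 gC/m2, 20-yr rel change 0.068
high: min NSC 220.9 gC/m2 (14.21% of AGC) risk=low
mid: min NSC 0.0 gC/m2 (0.00% of AGC) risk=high
low: min NSC 0.0 gC/m2 (0.00% of AGC) risk=high
```

Reading this: spun-up biomass decreases downslope (the cooler, wetter high
site supports the densest stand); during the drought the high stand's
reserves never fall below 14 % of its above-ground carbon (low mortality
risk), while the mid and low stands exhaust their reserves entirely —
high risk of carbon-starvation mortality. `out/annual.csv` holds
per-water-year NPP, growth (NPP plus any storage drawn for regrowth),
minimum NSC and minimum LAI; `out/risk.csv` the risk report; and
`out/manifest.json` the config hash and seed that regenerate both
bit-identically.

Other subcommands: `synth-forcing`, `spinup`, `grid` (the two-parameter
sensitivity sweep and its per-site threshold statistic), `swap`
(precipitation/temperature exchange and all-rain attribution scenarios),
and `correlate` (Pearson correlation of modeled growth against an
observed basal-area-increment series).

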