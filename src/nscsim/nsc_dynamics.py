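"""Non-structural carbohydrate (NSC) pool dynamics and mortality risk.

The stand maintains a mobile carbohydrate pool alongside the structural
pools. Two free parameters control it:

* ``nsc_npp_frac`` -- the fraction of (positive) net primary production
  routed into storage each day, until the pool reaches a fixed cap of 20%
  of plant structural carbon;
* ``minl_agc`` -- a threshold minimum ratio of leaf carbon to above-ground
  structural carbon. When canopy loss drives the ratio below the threshold,
  stored carbon is mobilised (after respiration needs are met) to rebuild
  foliage, with fine roots tracking leaves.

On days when respiration exceeds assimilation the deficit is drawn from the
NSC pool first; an empty pool leaves the deficit unmet (an energy-deficit
day, counted but not allowed to drive pools negative). Mortality risk is a
diagnostic classification of the minimum NSC:AGC ratio over an evaluation
window: below 0.5% of above-ground biomass the risk is high, near the
threshold moderate, above it low. Classification never feeds back on the
simulation (no stand-killing trigger), so the carbon-cycle response remains
visible through a predicted mortality event.

The daily orchestrator wires the process modules in a fixed order:
derived met -> snow/interception/infiltration -> conductance -> GPP ->
maintenance respiration (assimilate first, then NSC draw) -> NSC accrual
and growth allocation (positive days) -> NSC-funded canopy restoration ->
turnover -> drainage, with water and carbon closure asserted every day.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp

import numpy as np

from .forcing import SiteConfig, ConfigurationError
from . import hydrology as hyd
from . import canopy_carbon as cc
from .canopy_carbon import CarbonState, SpeciesParams, DEFAULT_SPECIES

__all__ = [
    "NSCParams",
    "accrue_nsc",
    "draw_nsc_for_respiration",
    "restore_canopy_from_nsc",
    "classify_mortality_risk",
    "daily_step",
    "simulate",
    "SimResult",
]

CO2_PPM_DEFAULT = 390.0
GA_DEFAULT = 0.02            # aerodynamic conductance, m/s
RESTORE_DAYS = 30.0          # per-day NSC->leaf transfer cap: gap/RESTORE_DAYS
CLOSURE_RTOL = 1.0e-9

# net radiation from shortwave: albedo + mean net longwave loss (MJ m-2 d-1)
_RN_SW_COEF = 0.85
_RN_LW_LOSS = 1.5


class ClosureError(RuntimeError):
    """Daily mass balance violated beyond tolerance (internal bug trap)."""


@dataclass(frozen=True)
class NSCParams:
    """Free and fixed parameters of the NSC sub-model.

    nsc_npp_frac           fraction of positive daily NPP stored, [0, 1]
    minl_agc               minimum leaf:above-ground carbon ratio, [0, 0.25]
    nsc_cap_frac           storage ceiling as fraction of structural carbon
    mortality_threshold_frac  NSC:AGC ratio below which mortality risk is high
    moderate_band_frac     width of the moderate band above the threshold
    """

    nsc_npp_frac: float = 0.3
    minl_agc: float = 0.05
    nsc_cap_frac: float = 0.20
    mortality_threshold_frac: float = 0.005
    moderate_band_frac: float = 0.005

    def __post_init__(self) -> None:
        if not 0.0 <= self.nsc_npp_frac <= 1.0:
            raise ConfigurationError("nsc_npp_frac must be in [0, 1]")
        if not 0.0 <= self.minl_agc <= 0.25:
            raise ConfigurationError("minl_agc must be in [0, 0.25]")
        if self.nsc_cap_frac <= 0 or self.mortality_threshold_frac <= 0:
            raise ConfigurationError("cap and threshold must be > 0")
        if self.moderate_band_frac < 0:
            raise ConfigurationError("moderate_band_frac must be >= 0")


def accrue_nsc(positive_npp: float, state: CarbonState, params: NSCParams
               ) -> tuple[float, float]:
    """Split a positive daily NPP into (nsc_in, growth_share).

    Storage takes ``nsc_npp_frac`` of the day's NPP up to the headroom left
    under the cap (a fraction of *structural* carbon); the rest grows
    structure.
    """
    if positive_npp < 0:
        raise ValueError("positive_npp must be >= 0")
    headroom = max(0.0, params.nsc_cap_frac * state.structural - state.nsc)
    nsc_in = min(params.nsc_npp_frac * positive_npp, headroom)
    return nsc_in, positive_npp - nsc_in


def draw_nsc_for_respiration(deficit: float, state: CarbonState
                             ) -> tuple[float, float]:
    """Pay a respiration deficit from storage; returns (drawn, unmet).

    Mutates ``state.nsc``. The pool never goes negative; any unmet amount
    flags an energy-deficit day.
    """
    if deficit < 0:
        raise ValueError("deficit must be >= 0")
    drawn = min(deficit, state.nsc)
    state.nsc -= drawn
    return drawn, deficit - drawn


def restore_canopy_from_nsc(state: CarbonState, params: NSCParams,
                            sp: SpeciesParams = DEFAULT_SPECIES) -> float:
    """Mobilise NSC to rebuild foliage (and fine roots) after canopy loss.

    Triggers only when leafC/AGC < minl_agc. Transfers at most
    1/RESTORE_DAYS of the leaf gap per day, limited by the available pool,
    paying growth respiration on the new tissue; never overshoots the
    target ratio. Mutates ``state``; returns the carbon moved into tissue
    (leaf + fine root, excluding growth respiration), gC m-2.
    """
    agc = state.agc
    if agc <= 0.0 or params.minl_agc <= 0.0:
        return 0.0
    if state.leafC / agc >= params.minl_agc:
        return 0.0
    m = params.minl_agc
    gap = (m * agc - state.leafC) / (1.0 - m)   # leaf C needed to reach ratio
    dl = gap / RESTORE_DAYS
    cost_per_leaf = (1.0 + sp.froot_leaf_ratio) * (1.0 + sp.growth_cost)
    dl = min(dl, state.nsc / cost_per_leaf)
    if dl <= 0.0:
        return 0.0
    tissue = dl * (1.0 + sp.froot_leaf_ratio)
    state.leafC += dl
    state.frootC += dl * sp.froot_leaf_ratio
    state.nsc -= tissue * (1.0 + sp.growth_cost)
    return tissue


def classify_mortality_risk(nsc_series, agc_series, params: NSCParams) -> str:
    """Classify drought-mortality risk from the window-minimum NSC:AGC ratio.

    Returns 'high' strictly below the threshold, 'moderate' within the
    closed band [threshold, threshold + moderate_band], 'low' above.
    """
    nsc = np.asarray(nsc_series, dtype=float)
    agc = np.asarray(agc_series, dtype=float)
    if nsc.size == 0 or nsc.shape != agc.shape:
        raise ValueError("series must be non-empty and aligned")
    m = float(np.min(nsc / agc))
    thr = params.mortality_threshold_frac
    if m < thr:
        return "high"
    if m <= thr + params.moderate_band_frac:
        return "moderate"
    return "low"


# ---------------------------------------------------------------------------
# Daily orchestrator
# ---------------------------------------------------------------------------

def _site_constants(site: SiteConfig) -> dict:
    return {
        "soil": site.soil,
        "fc_mm": hyd.field_capacity_mm(site.soil),
        "pressure_kpa": site.pressure_kpa,
    }


def daily_step(water: hyd.WaterState, carbon: CarbonState, met: dict,
               site: SiteConfig, params: NSCParams,
               sp: SpeciesParams = DEFAULT_SPECIES, mode: str = "stand",
               t_acclim: float | None = None, co2: float = CO2_PPM_DEFAULT,
               all_rain: bool = False
               ) -> tuple[hyd.WaterState, CarbonState, dict]:
    """Advance one day. ``met`` holds scalars tmean, tday, vpd_kpa, sw_mj,
    par_mol, daylength_s, precip_mm. Returns (water', carbon', fluxes).

    Closure-checked: raises :class:`ClosureError` if the daily water or
    carbon balance drifts beyond tolerance.
    """
    w = water.copy()
    c = carbon.copy()
    ta = met["tmean"] if t_acclim is None else t_acclim
    fluxes = _step(w, c, met["tmean"], met["tday"], met["vpd_kpa"],
                   met["sw_mj"], met["par_mol"], met["daylength_s"],
                   met["precip_mm"], _site_constants(site), params, sp,
                   mode, ta, co2, all_rain)
    return w, c, fluxes


def _step(w: hyd.WaterState, c: CarbonState, tmean: float, tday: float,
          vpd: float, sw: float, par_mol: float, daylen: float,
          precip: float, sc: dict, params: NSCParams, sp: SpeciesParams,
          mode: str, t_acclim: float, co2: float, all_rain: bool) -> dict:
    """One closure-checked day; mutates ``w`` and ``c`` in place."""
    soil = sc["soil"]
    water0 = w.total()

    # --- water supply: phase, snow, interception, infiltration ---
    if all_rain:
        rain, snowfall = precip, 0.0
    else:
        rain, snowfall = hyd.partition_precip(precip, tmean)
    w.swe, melt = hyd.snowpack_step(w.swe, snowfall, tmean, sw)
    lai = cc.lai_of(c.leafC, sp)
    throughfall, w.canopy_store = hyd.canopy_interception(
        rain, lai, w.canopy_store)
    to_soil, w.litter_store = hyd.litter_step(throughfall + melt,
                                              w.litter_store)
    room = soil.storage_depth_mm - w.unsat_store
    infiltration = min(to_soil, room)
    w.unsat_store += infiltration
    sat_excess = to_soil - infiltration      # exported with drainage

    # --- evaporation of intercepted water (first draw on the day's energy)
    rn = max(0.0, _RN_SW_COEF * sw - _RN_LW_LOSS)
    e_pot = hyd.surface_evap_potential(rn, tmean)
    evap_can = min(w.canopy_store, e_pot)
    w.canopy_store -= evap_can
    evap_lit = min(w.litter_store, max(0.0, e_pot - evap_can))
    w.litter_store -= evap_lit
    evaporation = evap_can + evap_lit

    # --- transpiration: conductance -> demand -> supply limit ---
    psi = hyd.soil_psi(w.unsat_store, soil)
    ppfd = par_mol * 1.0e6 / daylen if daylen > 0 else 0.0
    gc = hyd.jarvis_conductance(ppfd, vpd, psi, tmean, co2, lai)
    rn_canopy = rn * (1.0 - exp(-sp.beer_k * lai)) if lai > 0 else 0.0
    demand = hyd.penman_monteith(rn_canopy, vpd, tmean, GA_DEFAULT, gc) \
        if gc > 0 else 0.0
    transp = min(demand, w.unsat_store)
    w.unsat_store -= transp

    # --- carbon: assimilation and maintenance respiration ---
    gpp = cc.farquhar_gpp(par_mol, daylen, tday, lai, gc, co2,
                          sc["pressure_kpa"], sp)
    rm = cc.maintenance_respiration(c, tmean, t_acclim, sp)
    nsc0 = c.nsc
    struct0 = c.structural

    nsc_in = drawn = unmet = 0.0
    rg_total = incr_total = 0.0
    available = gpp - rm
    if available >= 0.0:
        # positive day: NPP net of growth respiration, solved jointly with
        # the accrual split (rg applies only to the growth share)
        cshare = sp.growth_cost / (1.0 + sp.growth_cost)
        f = params.nsc_npp_frac
        npp_pos = available * (1.0 - cshare) / (1.0 - f * cshare) \
            if f * cshare < 1.0 else available
        nsc_in, _ = accrue_nsc(npp_pos, c, params)
        c.nsc += nsc_in
        growth_share = available - nsc_in
        alloc = cc.allocate_growth(growth_share, c, sp)
        c.leafC += alloc["to_leaf"]
        c.frootC += alloc["to_froot"]
        c.stemC += alloc["to_stem"]
        c.crootC += alloc["to_croot"]
        rg_total += alloc["rg"]
        incr_total += growth_share - alloc["rg"]
        rm_paid = rm
    else:
        drawn, unmet = draw_nsc_for_respiration(-available, c)
        rm_paid = gpp + drawn

    # --- NSC-funded canopy restoration ---
    tissue = restore_canopy_from_nsc(c, params, sp)
    rg_total += tissue * sp.growth_cost
    incr_total += tissue

    # --- turnover, then re-impose the storage cap against the smaller
    #     structural base by growing the excess into structure ---
    c2, litterfall = cc.turnover_step(c, sp, mode)
    c.leafC, c.stemC = c2.leafC, c2.stemC
    c.crootC, c.frootC = c2.crootC, c2.frootC
    overflow = max(0.0, c.nsc - params.nsc_cap_frac * c.structural)
    if overflow > 0.0:
        c.nsc -= overflow
        alloc = cc.allocate_growth(overflow, c, sp)
        c.leafC += alloc["to_leaf"]
        c.frootC += alloc["to_froot"]
        c.stemC += alloc["to_stem"]
        c.crootC += alloc["to_croot"]
        rg_total += alloc["rg"]
        incr_total += overflow - alloc["rg"]
    c.age += 1.0 / 365.0

    # --- drainage closes the water day ---
    drainage, w.unsat_store, w.sat_deficit = hyd.drainage_step(
        w.unsat_store, w.sat_deficit, soil)
    drainage += sat_excess

    # --- closure checks (bug traps) ---
    water_flux = drainage + evaporation + transp
    water_err = precip - (w.total() - water0) - water_flux
    scale = max(1.0, abs(precip) + water0 + water_flux)
    if abs(water_err) > CLOSURE_RTOL * scale:
        raise ClosureError(f"water balance error {water_err:.3e} mm")

    d_nsc = c.nsc - nsc0
    carbon_err = gpp - rm_paid - rg_total - incr_total - d_nsc
    cscale = max(1.0, gpp + rm_paid + rg_total + incr_total + abs(d_nsc))
    if abs(carbon_err) > CLOSURE_RTOL * cscale:
        raise ClosureError(f"carbon balance error {carbon_err:.3e} gC")

    npp = gpp - rm_paid - rg_total
    return {
        "rain": rain, "snowfall": snowfall, "melt": melt,
        "throughfall": throughfall, "infiltration": infiltration,
        "drainage": drainage, "transpiration": transp,
        "evaporation": evaporation,
        "gpp": gpp, "rm": rm, "rm_paid": rm_paid, "rg": rg_total,
        "npp": npp, "litterfall": litterfall,
        "nsc_in": nsc_in, "nsc_out_resp": drawn, "nsc_out_leaf": tissue,
        "unmet_resp": unmet, "psi_m": psi, "gc_ms": gc, "lai": lai,
        "water_err": water_err, "carbon_err": carbon_err,
    }


# ---------------------------------------------------------------------------
# Multi-year simulation driver
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """Daily trajectories plus final state of one simulation."""

    water: hyd.WaterState
    carbon: CarbonState
    daily: dict            # name -> np.ndarray over days
    energy_deficit_days: int

    def nsc_frac_of_agc(self) -> np.ndarray:
        return self.daily["nsc"] / self.daily["agc"]


_RECORD = ("gpp", "npp", "rm", "rg", "nsc_in", "nsc_out_resp",
           "nsc_out_leaf", "unmet_resp", "litterfall", "transpiration",
           "evaporation", "drainage", "melt", "rain", "snowfall",
           "water_err", "carbon_err")


def simulate(site: SiteConfig, derived: dict, water: hyd.WaterState,
             carbon: CarbonState, params: NSCParams,
             sp: SpeciesParams = DEFAULT_SPECIES, mode: str = "stand",
             co2: float = CO2_PPM_DEFAULT, all_rain: bool = False,
             t_acclim0: float | None = None) -> SimResult:
    """Run the daily model over a derived forcing dict (see
    :func:`nscsim.forcing.derive_met_series`).

    The respiration-acclimation temperature is an exponential running mean
    of daily mean temperature (30-day timescale), carried across the run.
    """
    n = len(derived["tmean"])
    w = water.copy()
    c = carbon.copy()
    sc = _site_constants(site)
    tmean = derived["tmean"]
    tday = derived["tday"]
    vpd = derived["vpd_kpa"]
    sw = derived["sw_mj"]
    par = derived["par_mol"]
    daylen = derived["daylength_s"]
    precip = derived["precip_mm"]

    out = {k: np.empty(n) for k in _RECORD}
    for k in ("nsc", "agc", "structural", "lai", "swe", "unsat", "leafC"):
        out[k] = np.empty(n)
    out["dates"] = derived["dates"]
    out["water_year"] = derived["water_year"]

    t_acc = float(tmean[:30].mean()) if t_acclim0 is None else t_acclim0
    deficit_days = 0
    for i in range(n):
        fl = _step(w, c, tmean[i], tday[i], vpd[i], sw[i], par[i],
                   daylen[i], precip[i], sc, params, sp, mode, t_acc,
                   co2, all_rain)
        t_acc += (tmean[i] - t_acc) / 30.0
        if fl["unmet_resp"] > 0.0:
            deficit_days += 1
        for k in _RECORD:
            out[k][i] = fl[k]
        out["nsc"][i] = c.nsc
        out["agc"][i] = c.agc
        out["structural"][i] = c.structural
        out["lai"][i] = fl["lai"]
        out["swe"][i] = w.swe
        out["unsat"][i] = w.unsat_store
        out["leafC"][i] = c.leafC
        if not np.isfinite(c.nsc) or not np.isfinite(c.structural):
            raise ClosureError(f"non-finite carbon state at day {i}")
    return SimResult(w, c, out, deficit_days)
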