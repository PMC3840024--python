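"""Daily stand water balance processes.

One 30 m grid cell, one soil column, no lateral inflow. Stores are snowpack
(SWE), canopy interception, litter interception, and a single unsaturated
plant-available bucket; saturated-zone accounting is reduced to a fixed
saturation deficit whose implied water-table depth sets the hydraulic
conductivity at which free water leaves the column (recharge is exported as
baseflow the same day, so the deficit is stationary).

Sign convention: soil water tension is stored as a positive magnitude in
metres of water (a *tension*, not a matric potential), so drier soil means a
larger psi.

Intra-day ordering used by the orchestrator: melt -> interception ->
infiltration -> evaporation/transpiration -> drainage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forcing import SoilParams, ConfigurationError

__all__ = [
    "WaterState",
    "partition_precip",
    "snowpack_step",
    "canopy_interception",
    "litter_step",
    "soil_psi",
    "drainage_step",
    "penman_monteith",
    "surface_evap_potential",
    "jarvis_conductance",
    "StomatalParams",
]

# rain/snow linear transition band on daily mean temperature (degC)
T_ALL_SNOW = -2.0
T_ALL_RAIN = 2.0

# hybrid temperature-index / radiation-index snowmelt
T_MELT = 0.0          # degC
MELT_K_T = 2.0        # mm degC-1 day-1
MELT_K_R = 0.25       # mm per MJ m-2 day-1, active only above T_MELT

CANOPY_CAP_PER_LAI = 0.3   # mm of interception storage per unit LAI
LITTER_CAP_MM = 2.0        # first-draw litter store capacity, mm

PSI_DRY_LIMIT_M = 1.0e4    # returned tension for a fully dry bucket
PSI_FIELD_CAP_M = 3.4      # tension defining field capacity (~ -33 kPa)

SAT_DEFICIT_MM_DEFAULT = 120.0
EFFECTIVE_POROSITY = 0.4
DRAIN_KSAT_SCALE = 2000.0  # m/day; converts ksat(z) to a daily drainage fraction

# Penman-Monteith constants
_PSYCHROMETRIC = 0.066     # kPa/degC
_AIR_DENSITY = 1.20        # kg m-3
_CP_AIR = 1.013e-3         # MJ kg-1 degC-1
_LAMBDA_V = 2.45           # MJ kg-1
_PT_ALPHA = 1.26           # Priestley-Taylor coefficient for wet surfaces


@dataclass
class WaterState:
    """Water stores for one stand (all mm of water)."""

    swe: float = 0.0
    canopy_store: float = 0.0
    litter_store: float = 0.0
    unsat_store: float = 60.0
    sat_deficit: float = SAT_DEFICIT_MM_DEFAULT

    def copy(self) -> "WaterState":
        return WaterState(self.swe, self.canopy_store, self.litter_store,
                          self.unsat_store, self.sat_deficit)

    def total(self) -> float:
        return self.swe + self.canopy_store + self.litter_store + self.unsat_store


def partition_precip(precip: float, tmean: float) -> tuple[float, float]:
    """Split precipitation into (rain, snow) by a linear ramp on tmean."""
    if precip < 0:
        raise ValueError("precip must be >= 0")
    if tmean <= T_ALL_SNOW:
        frac_rain = 0.0
    elif tmean >= T_ALL_RAIN:
        frac_rain = 1.0
    else:
        frac_rain = (tmean - T_ALL_SNOW) / (T_ALL_RAIN - T_ALL_SNOW)
    rain = precip * frac_rain
    return rain, precip - rain


def snowpack_step(swe: float, snowfall: float, tmean: float,
                  radiation: float, k_t: float = MELT_K_T,
                  k_r: float = MELT_K_R,
                  t_melt: float = T_MELT) -> tuple[float, float]:
    """Hybrid temperature/radiation index melt; returns (swe', melt)."""
    if k_t < 0 or k_r < 0:
        raise ConfigurationError("melt coefficients must be >= 0")
    demand = max(0.0, k_t * (tmean - t_melt))
    if tmean > t_melt:
        demand += k_r * max(0.0, radiation)
    melt = min(swe + snowfall, demand)
    return swe + snowfall - melt, melt


def canopy_interception(rain: float, lai: float, store: float,
                        cap_per_lai: float = CANOPY_CAP_PER_LAI
                        ) -> tuple[float, float]:
    """Intercept rain into the canopy store; returns (throughfall, store').

    Storage capacity is proportional to LAI; overflow becomes throughfall.
    The new store is the evaporable water held on the canopy.
    """
    if lai < 0:
        raise ValueError("lai must be >= 0")
    capacity = cap_per_lai * lai
    room = max(0.0, capacity - store)
    intercepted = min(rain, room)
    return rain - intercepted, store + intercepted


def litter_step(water_in: float, store: float,
                capacity: float = LITTER_CAP_MM) -> tuple[float, float]:
    """Fill the litter store from incoming water; returns (to_soil, store')."""
    room = max(0.0, capacity - store)
    held = min(water_in, room)
    return water_in - held, store + held


def soil_psi(unsat_store: float, soil: SoilParams,
             dry_limit: float = PSI_DRY_LIMIT_M) -> float:
    """Brooks-Corey soil water tension (positive, m of water).

    |psi| = psi_air_entry * S**(-1/pore_size_index) with S the relative
    saturation of the plant-available bucket; equals psi_air_entry at
    saturation and is capped at ``dry_limit`` as S -> 0.
    """
    if unsat_store < 0 or unsat_store > soil.storage_depth_mm * (1 + 1e-9):
        raise ValueError("unsat_store outside [0, storage depth]")
    s = unsat_store / soil.storage_depth_mm
    if s <= 0.0:
        return dry_limit
    psi = soil.psi_air_entry * s ** (-1.0 / soil.pore_size_index)
    return min(psi, dry_limit)


def field_capacity_mm(soil: SoilParams) -> float:
    """Bucket content (mm) at field-capacity tension."""
    s_fc = (soil.psi_air_entry / PSI_FIELD_CAP_M) ** soil.pore_size_index
    return min(1.0, s_fc) * soil.storage_depth_mm


def drainage_step(unsat_store: float, sat_deficit: float, soil: SoilParams
                  ) -> tuple[float, float, float]:
    """Drain free water (above field capacity) out of the column.

    The daily drainable fraction follows the saturated conductivity
    evaluated at the water-table depth implied by the saturation deficit,
    ksat(z) = ksat_max * exp(-z / ksat_decay); recharge is exported as
    baseflow, so the saturation deficit is returned unchanged.
    Returns (drainage, unsat', sat_deficit').
    """
    free = max(0.0, unsat_store - field_capacity_mm(soil))
    if free <= 0.0:
        return 0.0, unsat_store, sat_deficit
    z_wt = max(0.0, sat_deficit) / 1000.0 / EFFECTIVE_POROSITY
    ksat_z = soil.ksat_max * np.exp(-z_wt / soil.ksat_decay)
    frac = 1.0 - np.exp(-ksat_z / DRAIN_KSAT_SCALE)
    drainage = free * frac
    return drainage, unsat_store - drainage, sat_deficit


def _slope_svp(t_c: float) -> float:
    """Slope of the saturation vapour pressure curve (kPa/degC)."""
    es = 0.6108 * np.exp(17.27 * t_c / (t_c + 237.3))
    return 4098.0 * es / (t_c + 237.3) ** 2


def penman_monteith(rn: float, vpd: float, tmean: float, ga: float,
                    gc: float | None) -> float:
    """Penman-Monteith evaporation demand (mm/day).

    rn : net radiation, MJ m-2 day-1 (negative values clipped to 0)
    vpd : vapour pressure deficit, kPa
    ga : aerodynamic conductance, m/s
    gc : canopy (surface) conductance, m/s; ``None`` means a wet surface
         with no surface resistance; 0 returns 0.
    """
    if ga <= 0:
        raise ValueError("aerodynamic conductance must be > 0")
    if gc is not None and gc < 0:
        raise ValueError("canopy conductance must be >= 0")
    if gc is not None and gc == 0.0:
        return 0.0
    rn = max(0.0, rn)
    delta = _slope_svp(tmean)
    aero = _AIR_DENSITY * _CP_AIR * vpd * ga * 86400.0
    surf = 1.0 if gc is None else (1.0 + ga / gc)
    lam_e = (delta * rn + aero) / (delta + _PSYCHROMETRIC * surf)
    return max(0.0, lam_e / _LAMBDA_V)


def surface_evap_potential(rn: float, tmean: float) -> float:
    """Priestley-Taylor potential evaporation for wet surfaces (mm/day)."""
    delta = _slope_svp(tmean)
    return max(0.0, _PT_ALPHA * delta / (delta + _PSYCHROMETRIC)
               * max(0.0, rn) / _LAMBDA_V)


# ---------------------------------------------------------------------------
# Stomatal conductance (multiplicative environmental down-regulation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StomatalParams:
    """Jarvis-type multipliers for a conifer canopy.

    gs_max is the maximum stomatal conductance per unit leaf area (m/s);
    canopy conductance scales with LAI. psi limits are tensions in m of
    water (psi_open fully open, psi_close fully closed).
    """

    gs_max: float = 0.005
    ppfd_half: float = 200.0      # umol m-2 s-1 at which f_rad = 0.5
    vpd_open_kpa: float = 0.5
    vpd_close_kpa: float = 3.5
    psi_open_m: float = 80.0      # ~ -0.8 MPa
    psi_close_m: float = 300.0    # ~ -3.0 MPa
    t_min_c: float = 0.0
    t_opt_lo_c: float = 10.0
    t_opt_hi_c: float = 30.0
    t_max_c: float = 42.0
    co2_ref_ppm: float = 390.0
    co2_slope: float = 5.0e-4     # fractional gs decline per ppm above ref


def _ramp(x: float, lo: float, hi: float) -> float:
    if x <= lo:
        return 0.0
    if x >= hi:
        return 1.0
    return (x - lo) / (hi - lo)


def jarvis_conductance(ppfd: float, vpd: float, psi: float, tmean: float,
                       co2: float, lai: float,
                       sp: StomatalParams = StomatalParams()) -> float:
    """Canopy conductance gc (m/s) = gs_max * LAI * product of multipliers.

    ppfd is daytime photon flux (umol m-2 s-1), psi a positive tension (m).
    Each multiplier lies in [0, 1]; any zero multiplier closes the canopy.
    """
    if lai <= 0 or ppfd <= 0:
        return 0.0
    f_rad = ppfd / (ppfd + sp.ppfd_half)
    f_vpd = 1.0 - _ramp(vpd, sp.vpd_open_kpa, sp.vpd_close_kpa)
    f_psi = 1.0 - _ramp(psi, sp.psi_open_m, sp.psi_close_m)
    if tmean <= sp.t_min_c or tmean >= sp.t_max_c:
        f_t = 0.0
    else:
        f_t = min(_ramp(tmean, sp.t_min_c, sp.t_opt_lo_c),
                  1.0 - _ramp(tmean, sp.t_opt_hi_c, sp.t_max_c))
    f_co2 = float(np.clip(1.0 - sp.co2_slope * (co2 - sp.co2_ref_ppm), 0.2, 1.2))
    return sp.gs_max * lai * f_rad * f_vpd * f_psi * f_t * f_co2
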