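"""Daily stand carbon processes: photosynthesis, respiration, allocation,
turnover.

Gross primary production uses enzyme-kinetic leaf photosynthesis (minimum of
Rubisco- and electron-transport-limited assimilation) coupled to stomatal
conductance through intercellular CO2, scaled to the canopy with a two-class
sunlit/shaded split of PAR (Beer's-law extinction). Maintenance respiration
scales with tissue nitrogen and responds to temperature via a Q10 that
acclimates to the running-mean growth temperature. Net photosynthesis is
allocated with a leaf fraction that declines as LAI builds (fine roots track
leaves, the remainder goes to stems and coarse roots), paying a fixed growth
respiration cost. Turnover removes fixed annual proportions of leaves, fine
roots and branches compounded daily; stand mode adds a background whole-tree
turnover while tree mode removes stemwood turnover entirely.

All pools are gC per m2 ground.  Species defaults describe a montane
ponderosa pine canopy and are the calibration surface of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import exp, sqrt

__all__ = [
    "SpeciesParams",
    "CarbonState",
    "lai_of",
    "farquhar_gpp",
    "leaf_assimilation",
    "maintenance_respiration",
    "allocate_growth",
    "turnover_step",
    "DEFAULT_SPECIES",
]

_R_GAS = 8.314462  # J mol-1 K-1


@dataclass(frozen=True)
class SpeciesParams:
    """Species-level physiology and allometry (ponderosa pine defaults).

    sla_m2_kgc       specific leaf area, m2 leaf per kgC leaf
    vcmax25          maximum carboxylation rate at 25 degC, umol m-2 s-1
    jmax_ratio       Jmax:Vcmax at 25 degC
    quantum_yield    mol electrons per mol absorbed photons
    beer_k           canopy PAR extinction coefficient
    mr_per_n         maintenance respiration, gC per gN per day at 20 degC
    cn_*             tissue C:N mass ratios; live_*_frac = respiring fraction
                     of the woody pools
    q10_*            baseline Q10 and its acclimation slope per degC of the
                     running-mean temperature (warmer growth -> flatter Q10)
    growth_cost      growth respiration per unit structural carbon built
    alloc_leaf_0     leaf allocation fraction of net growth at LAI = 0,
                     declining as 1/(1 + alloc_k * LAI)
    froot_leaf_ratio fine-root allocation per unit leaf allocation
    croot_wood_frac  coarse-root share of the woody remainder
    turnover_*       annual turnover fractions (compounded daily)
    """

    sla_m2_kgc: float = 4.0
    vcmax25: float = 55.0
    jmax_ratio: float = 1.67
    quantum_yield: float = 0.24
    beer_k: float = 0.5
    mr_per_n: float = 0.218
    cn_leaf: float = 42.0
    cn_froot: float = 58.0
    cn_wood: float = 50.0
    live_stem_frac: float = 0.08
    live_croot_frac: float = 0.20
    q10_base: float = 2.0
    q10_acclim_slope: float = 0.046
    q10_acclim_ref_c: float = 20.0
    t_ref_resp_c: float = 20.0
    growth_cost: float = 0.3
    alloc_leaf_0: float = 0.45
    alloc_k: float = 0.35
    froot_leaf_ratio: float = 1.0
    croot_wood_frac: float = 0.25
    turnover_leaf: float = 0.27
    turnover_froot: float = 0.50
    turnover_branch: float = 0.01
    turnover_croot: float = 0.01
    turnover_whole_tree_stand: float = 0.05


DEFAULT_SPECIES = SpeciesParams()


@dataclass
class CarbonState:
    """Structural pools + NSC for one stand (gC m-2 ground)."""

    leafC: float
    stemC: float
    crootC: float
    frootC: float
    nsc: float
    age: float = 0.0

    def copy(self) -> "CarbonState":
        return CarbonState(self.leafC, self.stemC, self.crootC,
                           self.frootC, self.nsc, self.age)

    @property
    def structural(self) -> float:
        return self.leafC + self.stemC + self.crootC + self.frootC

    @property
    def agc(self) -> float:
        """Above-ground structural carbon."""
        return self.leafC + self.stemC


def lai_of(leafC: float, sp: SpeciesParams = DEFAULT_SPECIES) -> float:
    """Leaf area index from leaf carbon (gC m-2) and SLA."""
    return leafC * sp.sla_m2_kgc / 1000.0


# ---------------------------------------------------------------------------
# Photosynthesis
# ---------------------------------------------------------------------------

def _arrhenius(k25: float, ea: float, t_c: float) -> float:
    tk = t_c + 273.15
    return k25 * exp(ea * (tk - 298.15) / (_R_GAS * 298.15 * tk))


def leaf_assimilation(ppfd: float, t_c: float, g_co2_mol: float,
                      ca_ppm: float, sp: SpeciesParams = DEFAULT_SPECIES,
                      o2_mmol: float = 210.0) -> float:
    """Gross leaf assimilation (umol CO2 m-2 leaf s-1).

    Solves min(Rubisco-limited, light-limited) assimilation jointly with
    CO2 diffusion A = g (Ca - Ci); each limitation gives a quadratic in Ci
    with a single admissible root. ``g_co2_mol`` is the leaf conductance to
    CO2 in mol m-2 s-1.
    """
    if ca_ppm <= 0:
        raise ValueError("ambient CO2 must be > 0")
    if ppfd <= 0 or g_co2_mol <= 0:
        return 0.0
    vm = _arrhenius(sp.vcmax25, 65330.0, t_c)
    jm = _arrhenius(sp.vcmax25 * sp.jmax_ratio, 43540.0, t_c)
    kc = _arrhenius(404.9, 79430.0, t_c)
    ko = _arrhenius(278.4, 36380.0, t_c)
    gstar = _arrhenius(42.75, 37830.0, t_c)
    km = kc * (1.0 + o2_mmol / ko)
    g = g_co2_mol
    ca = ca_ppm

    # Rubisco-limited: Vm (Ci - G*) / (Ci + Km) = g (Ca - Ci)
    b = vm + g * km - g * ca
    ci_c = (-b + sqrt(b * b + 4.0 * g * (g * ca * km + vm * gstar))) / (2.0 * g)
    a_c = g * (ca - ci_c)

    # light-limited: J (Ci - G*) / (4 Ci + 8 G*) = g (Ca - Ci)
    j = sp.quantum_yield * ppfd * jm / (sp.quantum_yield * ppfd + jm)
    b = j + 8.0 * g * gstar - 4.0 * g * ca
    ci_j = (-b + sqrt(b * b + 16.0 * g * (8.0 * g * ca * gstar + j * gstar))) \
        / (8.0 * g)
    a_j = g * (ca - ci_j)

    return max(0.0, min(a_c, a_j))


def farquhar_gpp(par_mol: float, daylength_s: float, tday: float,
                 lai: float, gc: float, co2_ppm: float,
                 pressure_kpa: float = 101.325,
                 sp: SpeciesParams = DEFAULT_SPECIES) -> float:
    """Canopy gross primary production (gC m-2 ground day-1).

    par_mol is daily PAR (mol m-2 ground), spread over ``daylength_s`` of
    daylight; gc is canopy conductance to water vapour (m/s per ground
    area). The canopy is split into a sunlit class (direct + diffuse PAR)
    and a shaded class (attenuated diffuse) by Beer's-law extinction.
    """
    if lai < 0:
        raise ValueError("lai must be >= 0")
    if co2_ppm <= 0:
        raise ValueError("ambient CO2 must be > 0")
    if lai == 0.0 or gc <= 0.0 or par_mol <= 0.0 or daylength_s <= 0.0:
        return 0.0
    k = sp.beer_k
    ppfd0 = par_mol * 1.0e6 / daylength_s          # umol m-2 ground s-1
    lai_sun = (1.0 - exp(-k * lai)) / k
    lai_sh = max(0.0, lai - lai_sun)
    ppfd_sh = 0.25 * ppfd0 * exp(-0.5 * k * lai)   # attenuated diffuse
    ppfd_sun = k * ppfd0 + ppfd_sh

    # leaf-level conductance to CO2, mol m-2 leaf s-1
    tk = tday + 273.15
    g_mol = (gc / lai) * pressure_kpa * 1000.0 / (_R_GAS * tk) / 1.6

    a_sun = leaf_assimilation(ppfd_sun, tday, g_mol, co2_ppm, sp)
    a_sh = leaf_assimilation(ppfd_sh, tday, g_mol, co2_ppm, sp) \
        if lai_sh > 0 else 0.0
    a_canopy = a_sun * lai_sun + a_sh * lai_sh      # umol m-2 ground s-1
    return a_canopy * daylength_s * 12.0e-6         # gC m-2 day-1


# ---------------------------------------------------------------------------
# Respiration
# ---------------------------------------------------------------------------

def effective_q10(t_acclim_c: float, sp: SpeciesParams = DEFAULT_SPECIES
                  ) -> float:
    """Temperature-acclimated Q10: declines with warmer growth conditions."""
    q10 = sp.q10_base - sp.q10_acclim_slope * (t_acclim_c - sp.q10_acclim_ref_c)
    return min(max(q10, 1.3), 3.2)


def maintenance_respiration(state: CarbonState, tmean: float,
                            t_acclim_c: float,
                            sp: SpeciesParams = DEFAULT_SPECIES) -> float:
    """Maintenance respiration demand (gC m-2 day-1).

    Sum over tissues of respiring carbon x N content x base rate, with a
    Q10 temperature response whose sensitivity acclimates to the running
    mean temperature. Equals the base-rate sum exactly at the reference
    temperature.
    """
    n_mass = (state.leafC / sp.cn_leaf
              + state.frootC / sp.cn_froot
              + state.stemC * sp.live_stem_frac / sp.cn_wood
              + state.crootC * sp.live_croot_frac / sp.cn_wood)
    base = n_mass * sp.mr_per_n
    q10 = effective_q10(t_acclim_c, sp)
    return base * q10 ** ((tmean - sp.t_ref_resp_c) / 10.0)


# ---------------------------------------------------------------------------
# Allocation and turnover
# ---------------------------------------------------------------------------

def allocate_growth(available: float, state: CarbonState,
                    sp: SpeciesParams = DEFAULT_SPECIES) -> dict:
    """Split net growth carbon into structural increments + growth respiration.

    The leaf fraction declines with current LAI (young sparse canopies
    build leaves, closed canopies build wood); fine-root allocation tracks
    leaf allocation; stems and coarse roots take the remainder. Growth
    respiration is a fixed cost per unit structure, so
    increments + rg == available exactly.
    """
    if available < 0:
        raise ValueError("available must be >= 0")
    lai = lai_of(state.leafC, sp)
    f_leaf = sp.alloc_leaf_0 / (1.0 + sp.alloc_k * lai)
    f_froot = min(f_leaf * sp.froot_leaf_ratio, 0.9 - f_leaf)
    f_wood = 1.0 - f_leaf - f_froot
    incr = available / (1.0 + sp.growth_cost)
    rg = available - incr
    wood = incr * f_wood
    return {
        "to_leaf": incr * f_leaf,
        "to_froot": incr * f_froot,
        "to_stem": wood * (1.0 - sp.croot_wood_frac),
        "to_croot": wood * sp.croot_wood_frac,
        "rg": rg,
    }


def turnover_step(state: CarbonState, sp: SpeciesParams = DEFAULT_SPECIES,
                  mode: str = "stand") -> tuple[CarbonState, float]:
    """One day of tissue turnover; returns (state', litterfall gC m-2).

    Annual rates are compounded continuously: each pool is multiplied by
    exp(-annual_rate / 365) per day, so a year of daily steps gives exactly
    exp(-annual_rate). Stand mode adds a background whole-tree turnover to
    leaves, stems and coarse roots; tree mode zeroes stemwood turnover.
    """
    if mode not in ("stand", "tree"):
        raise ValueError(f"unknown turnover mode {mode!r}")
    extra = sp.turnover_whole_tree_stand if mode == "stand" else 0.0
    r_leaf = sp.turnover_leaf + extra
    r_froot = sp.turnover_froot
    r_stem = (sp.turnover_branch + extra) if mode == "stand" else 0.0
    r_croot = sp.turnover_croot + extra

    new = state.copy()
    loss = 0.0
    for pool, rate in (("leafC", r_leaf), ("frootC", r_froot),
                       ("stemC", r_stem), ("crootC", r_croot)):
        c = getattr(new, pool)
        kept = c * exp(-rate / 365.0)
        loss += c - kept
        setattr(new, pool, kept)
    return new, loss
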