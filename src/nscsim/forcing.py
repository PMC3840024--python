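"""Daily meteorological forcing: reading, elevation adjustment, derived
variables, and a stochastic weather generator.

The simulator is driven only by daily maximum/minimum air temperature (degC)
and precipitation (mm) at a reference station. Everything else the process
modules need -- shortwave radiation, photosynthetically active radiation,
vapor pressure deficit, day length -- is estimated here with standard
empirical functions for Tmax/Tmin-only records:

* shortwave = top-of-atmosphere radiation x Bristow-Campbell transmissivity,
  where transmissivity increases with the diurnal temperature range;
* dewpoint is taken equal to Tmin, so VPD = e_sat(T_day) - e_sat(Tmin),
  with T_day the daytime mean temperature (Tavg + 0.45 (Tmax - Tavg));
* mean temperature = (Tmax + Tmin) / 2.

The synthetic generator emulates a semi-arid continental mountain climate
with a bimodal precipitation regime (winter frontal peak and a July-August
monsoon peak): a first-order Markov chain for wet-day occurrence and
gamma-distributed wet-day amounts, both with monthly parameters, plus a
seasonal sine temperature cycle with AR(1) anomalies and a wet/dry diurnal
range.  A multi-year drought block can be imposed by scaling precipitation
and shifting temperature over a span of water years.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SoilParams",
    "SiteConfig",
    "DroughtSpec",
    "SyntheticClimate",
    "MET_COLUMNS",
    "HIGH_SITE",
    "MID_SITE",
    "LOW_SITE",
    "STATION_ELEV_M",
    "read_met_csv",
    "write_met_csv",
    "validate_met",
    "adjust_to_site",
    "derive_met",
    "derive_met_series",
    "generate_synthetic_forcing",
    "water_year",
]

MET_COLUMNS = ("date", "tmax_c", "tmin_c", "precip_mm")

#: Reference-station elevation (m) for the default elevation gradient.
STATION_ELEV_M = 2262.0


class MetFormatError(ValueError):
    """Malformed meteorology file (missing/renamed columns)."""


class MetValidationError(ValueError):
    """Meteorology violates invariants (gaps, duplicates, negative precip...)."""


class ConfigurationError(ValueError):
    """Invalid site / generator configuration."""


# ---------------------------------------------------------------------------
# Site configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SoilParams:
    """Single-column soil hydraulic parameters.

    ksat_max
        Saturated hydraulic conductivity at the surface (m/day).
    ksat_decay
        e-folding depth (m) of the exponential decline of conductivity
        with depth.
    psi_air_entry
        Brooks-Corey air-entry tension (m of water, stored positive).
    pore_size_index
        Brooks-Corey pore-size distribution index (dimensionless).
    storage_depth_mm
        Plant-available water storage capacity of the rooted column (mm).
    """

    ksat_max: float
    ksat_decay: float
    psi_air_entry: float
    pore_size_index: float
    storage_depth_mm: float

    def __post_init__(self) -> None:
        for name in ("ksat_max", "ksat_decay", "psi_air_entry",
                     "pore_size_index", "storage_depth_mm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"soil parameter {name} must be > 0")


@dataclass(frozen=True)
class SiteConfig:
    """One stand: location, elevation adjustment, and soil column."""

    name: str
    elevation_m: float
    precip_scalar: float
    soil: SoilParams
    lapse_tmax: float = -5.7   # degC per km of elevation gain
    lapse_tmin: float = -5.3
    latitude_deg: float = 35.8

    def __post_init__(self) -> None:
        if self.precip_scalar <= 0:
            raise ConfigurationError("precip_scalar must be > 0")
        if not -90.0 <= self.latitude_deg <= 90.0:
            raise ConfigurationError("latitude outside [-90, 90]")

    @property
    def pressure_kpa(self) -> float:
        """Barometric pressure from elevation (standard-atmosphere profile)."""
        return 101.325 * ((293.0 - 0.0065 * self.elevation_m) / 293.0) ** 5.26


# Elevation-gradient presets (ponderosa pine transect; soil hydraulic values
# from the site soil survey, storage depths reflect the mid > high > low
# ordering of water holding capacity).
HIGH_SITE = SiteConfig(
    "high", 2767.0, 1.27,
    SoilParams(ksat_max=764.0, ksat_decay=8.75, psi_air_entry=0.159,
               pore_size_index=0.16, storage_depth_mm=180.0))
MID_SITE = SiteConfig(
    "mid", 2308.0, 1.03,
    SoilParams(ksat_max=1500.0, ksat_decay=4.0, psi_air_entry=0.175,
               pore_size_index=0.168, storage_depth_mm=220.0))
LOW_SITE = SiteConfig(
    "low", 2002.0, 0.85,
    SoilParams(ksat_max=3667.0, ksat_decay=0.38, psi_air_entry=0.125,
               pore_size_index=0.139, storage_depth_mm=120.0))


# ---------------------------------------------------------------------------
# Met series I/O and validation
# ---------------------------------------------------------------------------

def validate_met(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a daily met series.

    Returns a date-sorted copy. Raises :class:`MetFormatError` for missing
    columns and :class:`MetValidationError` for invariant violations
    (duplicate or gapped dates, negative precipitation, tmax < tmin).
    """
    missing = [c for c in MET_COLUMNS if c not in df.columns]
    if missing:
        raise MetFormatError(f"missing met columns: {missing}")
    out = df.loc[:, list(MET_COLUMNS)].copy()
    out["date"] = pd.to_datetime(out["date"])
    out = out.sort_values("date").reset_index(drop=True)
    d = out["date"]
    if d.duplicated().any():
        raise MetValidationError("duplicated dates in met series")
    if len(out) > 1:
        steps = d.diff().dropna()
        if (steps != pd.Timedelta(days=1)).any():
            raise MetValidationError("met series has date gaps")
    for c in ("tmax_c", "tmin_c", "precip_mm"):
        if not np.isfinite(out[c].to_numpy(dtype=float)).all():
            raise MetValidationError(f"non-finite values in {c}")
    if (out["precip_mm"] < 0).any():
        raise MetValidationError("negative precipitation")
    if (out["tmax_c"] < out["tmin_c"]).any():
        raise MetValidationError("tmax < tmin")
    return out


def read_met_csv(path) -> pd.DataFrame:
    """Read a daily meteorology CSV (columns date, tmax_c, tmin_c, precip_mm)."""
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise MetFormatError(f"cannot parse met CSV {path}: {exc}") from exc
    return validate_met(df)


def write_met_csv(df: pd.DataFrame, path) -> None:
    """Write the met series in the same dialect :func:`read_met_csv` accepts."""
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.6g")


def adjust_to_site(series: pd.DataFrame, station_elev_m: float,
                   site: SiteConfig) -> pd.DataFrame:
    """Elevation-adjust a station record to a site.

    Precipitation is multiplied by the site precipitation scalar;
    temperatures follow the (negative) lapse rates in degC/km applied to the
    elevation difference. Linear and invertible.
    """
    if station_elev_m <= 0:
        raise ConfigurationError("station elevation must be > 0")
    dz_km = (site.elevation_m - station_elev_m) / 1000.0
    out = series.copy()
    out["precip_mm"] = out["precip_mm"] * site.precip_scalar
    out["tmax_c"] = out["tmax_c"] + site.lapse_tmax * dz_km
    out["tmin_c"] = out["tmin_c"] + site.lapse_tmin * dz_km
    return out


def water_year(dates: pd.Series) -> np.ndarray:
    """Water year (1 Oct - 30 Sep) labelled by its ending calendar year."""
    d = pd.to_datetime(dates)
    return (d.dt.year + (d.dt.month >= 10).astype(int)).to_numpy()


# ---------------------------------------------------------------------------
# Derived met: radiation, PAR, VPD
# ---------------------------------------------------------------------------

_SOLAR_MJ_MIN = 0.0820          # solar constant, MJ m-2 min-1
_BC_A = 0.75                    # Bristow-Campbell clear-sky transmissivity
_BC_B = 0.005
_BC_C = 2.4
_PAR_MOL_PER_MJ = 2.3           # mol PAR per MJ total shortwave


def _sat_vp_kpa(t_c):
    """Saturation vapour pressure (kPa) at air temperature t (degC)."""
    return 0.6108 * np.exp(17.27 * t_c / (t_c + 237.3))


def _extraterrestrial(lat_deg: float, doy):
    """Top-of-atmosphere radiation (MJ m-2 day-1) and day length (s)."""
    phi = np.deg2rad(lat_deg)
    ang = 2.0 * np.pi * np.asarray(doy, dtype=float) / 365.0
    dr = 1.0 + 0.033 * np.cos(ang)
    decl = 0.409 * np.sin(ang - 1.39)
    cos_ws = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    ws = np.arccos(cos_ws)
    ra = (24.0 * 60.0 / np.pi) * _SOLAR_MJ_MIN * dr * (
        ws * np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.sin(ws))
    ra = np.maximum(ra, 0.0)
    daylength_s = 24.0 * 3600.0 * ws / np.pi
    return ra, daylength_s


def derive_met_series(series: pd.DataFrame, site: SiteConfig) -> dict:
    """Vectorised derived forcing for a whole series.

    Returns a dict of numpy arrays: tmean, tday, vpd_kpa, sw_mj, par_mol,
    daylength_s, doy, precip_mm, plus the raw tmax/tmin and dates.
    """
    if not -90.0 <= site.latitude_deg <= 90.0:
        raise ConfigurationError("latitude outside [-90, 90]")
    dates = pd.to_datetime(series["date"])
    doy = dates.dt.dayofyear.to_numpy()
    tmax = series["tmax_c"].to_numpy(dtype=float)
    tmin = series["tmin_c"].to_numpy(dtype=float)
    precip = series["precip_mm"].to_numpy(dtype=float)
    tmean = 0.5 * (tmax + tmin)
    tday = tmean + 0.45 * (tmax - tmean)
    vpd = np.maximum(0.0, _sat_vp_kpa(tday) - _sat_vp_kpa(tmin))
    ra, daylength_s = _extraterrestrial(site.latitude_deg, doy)
    dtr = np.maximum(tmax - tmin, 0.0)
    tau = _BC_A * (1.0 - np.exp(-_BC_B * dtr ** _BC_C))
    sw = ra * tau
    par = sw * _PAR_MOL_PER_MJ
    return {
        "dates": dates.to_numpy(),
        "doy": doy,
        "tmax": tmax,
        "tmin": tmin,
        "precip_mm": precip,
        "tmean": tmean,
        "tday": tday,
        "vpd_kpa": vpd,
        "sw_mj": sw,
        "par_mol": par,
        "daylength_s": daylength_s,
        "water_year": water_year(series["date"]),
    }


def derive_met(tmax_c: float, tmin_c: float, site: SiteConfig,
               day_of_year: int) -> dict:
    """Pointwise derived met for one record (no cross-day state).

    Returns dict with sw_mj, par_mol, vpd_kpa, tmean, tday, daylength_s.
    """
    one = pd.DataFrame({
        "date": [pd.Timestamp("2001-01-01") + pd.Timedelta(days=int(day_of_year) - 1)],
        "tmax_c": [tmax_c], "tmin_c": [tmin_c], "precip_mm": [0.0]})
    d = derive_met_series(one, site)
    return {k: float(d[k][0]) for k in
            ("sw_mj", "par_mol", "vpd_kpa", "tmean", "tday", "daylength_s")}


# ---------------------------------------------------------------------------
# Synthetic forcing generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DroughtSpec:
    """Multi-year drought block, indexed in water years from series start.

    start_year
        0-based index of the first water year of the drought within the
        generated series.
    duration_years
        Number of consecutive water years affected.
    precip_multiplier
        Factor in [0, 1] applied to every daily precipitation amount in the
        block (expected annual precipitation scales by the same factor).
    temp_offset_c
        Added to tmax and tmin throughout the block.
    """

    start_year: int
    duration_years: int = 3
    precip_multiplier: float = 0.5
    temp_offset_c: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.precip_multiplier <= 1.0:
            raise ConfigurationError("precip_multiplier must be in [0, 1]")
        if self.start_year < 0 or self.duration_years < 1:
            raise ConfigurationError("invalid drought window")


@dataclass(frozen=True)
class SyntheticClimate:
    """Station-scale climate normals for the weather generator.

    Monthly precipitation totals carry the bimodal regime: a winter
    (Dec-Jan) peak and a stronger July-August monsoon peak. Temperatures are
    a seasonal sine (annual mean + amplitude, warmest near 20 July) with
    AR(1) daily anomalies; the diurnal range is narrower on wet days.
    """

    monthly_precip_mm: tuple = (50., 35., 35., 20., 25., 25.,
                                85., 90., 45., 30., 30., 55.)
    monthly_wet_prob: tuple = (0.30, 0.28, 0.28, 0.20, 0.20, 0.22,
                               0.45, 0.45, 0.30, 0.22, 0.25, 0.30)
    gamma_shape: float = 0.75
    wet_persistence_boost: float = 0.20   # p11 = p_wet + boost (capped)
    t_annual_mean_c: float = 9.0
    t_amplitude_c: float = 10.0
    t_peak_doy: int = 201                 # warmest day (20 July)
    t_anom_sd_c: float = 2.5
    t_anom_rho: float = 0.65
    dtr_dry_c: float = 14.0
    dtr_wet_c: float = 7.0
    #: acceptable coefficient of variation of annual precipitation totals
    annual_cv_bounds: tuple = (0.05, 0.35)


def generate_synthetic_forcing(years: int, seed: int,
                               site: SiteConfig | None = None,
                               drought: DroughtSpec | None = None,
                               climate: SyntheticClimate | None = None,
                               start_year: int = 1975) -> pd.DataFrame:
    """Generate a daily station-scale met series of ``years`` water years.

    The series starts on 1 October ``start_year`` (water-year convention).
    If ``site`` is given the station record is elevation-adjusted to it via
    :func:`adjust_to_site`. Reproducible for a given seed.
    """
    if years < 1:
        raise ConfigurationError("years must be >= 1")
    clim = climate or SyntheticClimate()
    if drought is not None and drought.start_year + drought.duration_years > years:
        raise ConfigurationError("drought window extends past the series")

    rng = np.random.default_rng(seed)
    dates = pd.date_range(start=f"{start_year}-10-01",
                          end=f"{start_year + years}-09-30", freq="D")
    n = len(dates)
    month = dates.month.to_numpy()
    doy = dates.dayofyear.to_numpy()

    # --- precipitation: monthly Markov occurrence + gamma amounts ---
    pw = np.asarray(clim.monthly_wet_prob)[month - 1]
    p11 = np.minimum(pw + clim.wet_persistence_boost, 0.95)
    p01 = np.clip(pw * (1.0 - p11) / (1.0 - pw), 0.0, 1.0)
    u = rng.random(n)
    wet = np.zeros(n, dtype=bool)
    prev = False
    for i in range(n):
        p = p11[i] if prev else p01[i]
        prev = u[i] < p
        wet[i] = prev
    days_in_month = np.array([calendar.monthrange(y, m)[1]
                              for y, m in zip(dates.year, month)])
    mean_wet_amt = (np.asarray(clim.monthly_precip_mm)[month - 1]
                    / (np.asarray(clim.monthly_wet_prob)[month - 1] * days_in_month))
    amounts = rng.gamma(clim.gamma_shape,
                        mean_wet_amt / clim.gamma_shape, size=n)
    precip = np.where(wet, amounts, 0.0)

    # --- temperature: seasonal sine + AR(1) anomalies ---
    seasonal = clim.t_annual_mean_c + clim.t_amplitude_c * np.cos(
        2.0 * np.pi * (doy - clim.t_peak_doy) / 365.25)
    eps = rng.normal(0.0, clim.t_anom_sd_c * np.sqrt(1 - clim.t_anom_rho ** 2), n)
    anom = np.empty(n)
    a = 0.0
    rho = clim.t_anom_rho
    for i in range(n):
        a = rho * a + eps[i]
        anom[i] = a
    tmean = seasonal + anom
    dtr = np.where(wet, clim.dtr_wet_c, clim.dtr_dry_c)
    tmax = tmean + 0.5 * dtr
    tmin = tmean - 0.5 * dtr

    # --- drought block over water years ---
    if drought is not None:
        wy = (dates.year + (month >= 10).astype(int)).to_numpy()
        wy0 = wy.min() + drought.start_year
        mask = (wy >= wy0) & (wy < wy0 + drought.duration_years)
        precip = np.where(mask, precip * drought.precip_multiplier, precip)
        tmax = np.where(mask, tmax + drought.temp_offset_c, tmax)
        tmin = np.where(mask, tmin + drought.temp_offset_c, tmin)

    out = pd.DataFrame({"date": dates, "tmax_c": tmax, "tmin_c": tmin,
                        "precip_mm": precip})
    if site is not None:
        out = adjust_to_site(out, STATION_ELEV_M, site)
    return out
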