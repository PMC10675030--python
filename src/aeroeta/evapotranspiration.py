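"""Reference and potential evapotranspiration (Penman–Monteith).

Daily reference ET0 follows the FAO-56 methodology for a clipped-grass
reference surface (height 0.12 m, bulk surface resistance 70 s·m⁻¹, albedo
0.23).  Potential ET of the actual wheat canopy uses the same combination
equation with canopy-dependent resistances: the bulk surface resistance
scales with the active (sunlit) leaf area, ``rs = rl / (0.5·LAI)`` with a
stomatal resistance of well-watered leaves ``rl = 100 s·m⁻¹``, and the
aerodynamic resistance comes from the logarithmic wind profile over a crop
of the actual height.  Both routes share one resistance-explicit
Penman–Monteith implementation, so ET0 is exactly the special case
``potential_et(LAI = 100/(0.5·70), PH = 0.12)``.

All daily radiation terms follow the FAO-56 procedure (extraterrestrial
radiation from latitude and day of year, clear-sky envelope, net longwave
from vapour pressure and relative shortwave).  An hourly formulation of the
reference ET0 is provided for upscaling instantaneous latent-heat fluxes
(ET0-ratio method).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WeatherDaily",
    "Site",
    "reference_et0",
    "potential_et",
    "hourly_reference_et0",
    "daily_eta_from_instantaneous",
    "penman_monteith_le",
    "aerodynamic_resistance",
    "saturation_vapor_pressure",
    "slope_saturation_vapor_pressure",
    "psychrometric_constant",
    "pressure_from_elevation",
    "latent_heat_of_vaporization",
    "extraterrestrial_radiation",
    "clear_sky_radiation",
    "daily_net_radiation",
]

# physical constants
VON_KARMAN = 0.41
SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1
SOLAR_CONSTANT_W = 1367.0  # W m-2
STEFAN_BOLTZMANN_DAY = 4.903e-9  # MJ K-4 m-2 day-1
STEFAN_BOLTZMANN_W = 5.670e-8  # W m-2 K-4
CP_AIR = 1013.0  # J kg-1 K-1
LAMBDA_FAO = 2.45  # MJ kg-1, FAO-56 fixed latent heat for daily ET0

GRASS_HEIGHT = 0.12  # m
GRASS_RS = 70.0  # s m-1
GRASS_ALBEDO = 0.23
LEAF_RESISTANCE = 100.0  # s m-1, well-watered stomatal resistance
LAI_FLOOR = 0.1
WIND_FLOOR = 0.5  # m s-1, resistance stability


@dataclass(frozen=True)
class Site:
    """Trial-site geography needed for the radiation terms."""

    latitude_deg: float = 41.7
    elevation_m: float = 250.0
    sowing_doy: int = 343  # early-December sowing

    def doy(self, das: int) -> int:
        """Calendar day of year for a given day after sowing."""
        return (self.sowing_doy - 1 + int(das)) % 365 + 1


@dataclass
class WeatherDaily:
    """One day of weather-station records.

    Temperatures in °C, relative humidity in %, wind speed at 2 m in
    m·s⁻¹, incoming solar radiation in MJ·m⁻²·day⁻¹, rainfall in mm.
    """

    das: int
    t_min: float
    t_max: float
    rh_mean: float
    wind_2m: float
    solar_rad: float
    rainfall: float = 0.0
    et0: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.t_min > self.t_max:
            raise ValueError(f"t_min {self.t_min} > t_max {self.t_max}")
        if not 0.0 <= self.rh_mean <= 100.0:
            raise ValueError(f"RH outside [0, 100]: {self.rh_mean}")
        if self.rainfall < 0:
            raise ValueError("negative rainfall")
        for name in ("t_min", "t_max", "rh_mean", "wind_2m", "solar_rad"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite {name}")

    @property
    def t_mean(self) -> float:
        return 0.5 * (self.t_min + self.t_max)

    @property
    def ea(self) -> float:
        """Actual vapour pressure (kPa) from mean RH and the Tmin/Tmax es mean."""
        es = 0.5 * (
            saturation_vapor_pressure(self.t_min)
            + saturation_vapor_pressure(self.t_max)
        )
        return self.rh_mean / 100.0 * es

    @property
    def es(self) -> float:
        return 0.5 * (
            saturation_vapor_pressure(self.t_min)
            + saturation_vapor_pressure(self.t_max)
        )


def saturation_vapor_pressure(t_c: float) -> float:
    """Saturation vapour pressure (kPa) at air temperature t_c (°C)."""
    return 0.6108 * math.exp(17.27 * t_c / (t_c + 237.3))


def slope_saturation_vapor_pressure(t_c: float) -> float:
    """Slope of the saturation vapour pressure curve (kPa·°C⁻¹)."""
    return 4098.0 * saturation_vapor_pressure(t_c) / (t_c + 237.3) ** 2


def pressure_from_elevation(elevation_m: float) -> float:
    """Standard-atmosphere air pressure (kPa)."""
    return 101.3 * ((293.0 - 0.0065 * elevation_m) / 293.0) ** 5.26


def psychrometric_constant(pressure_kpa: float) -> float:
    """Psychrometric constant (kPa·°C⁻¹)."""
    return 0.000665 * pressure_kpa


def latent_heat_of_vaporization(t_c: float) -> float:
    """Temperature-dependent latent heat of vaporization (MJ·kg⁻¹)."""
    return 2.501 - 2.361e-3 * t_c


def air_density(t_c: float, pressure_kpa: float) -> float:
    """Moist-air density (kg·m⁻³), FAO-56 virtual-temperature form."""
    return pressure_kpa / (1.01 * (t_c + 273.0) * 0.287)


# ---------------------------------------------------------------------------
# solar geometry / radiation (FAO-56 procedure)
# ---------------------------------------------------------------------------

def solar_declination(doy: int) -> float:
    return 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)


def inverse_relative_distance(doy: int) -> float:
    return 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)


def sunset_hour_angle(latitude_deg: float, doy: int) -> float:
    phi = math.radians(latitude_deg)
    delta = solar_declination(doy)
    x = -math.tan(phi) * math.tan(delta)
    return math.acos(min(1.0, max(-1.0, x)))


def extraterrestrial_radiation(latitude_deg: float, doy: int) -> float:
    """Daily extraterrestrial radiation Ra (MJ·m⁻²·day⁻¹)."""
    phi = math.radians(latitude_deg)
    delta = solar_declination(doy)
    ws = sunset_hour_angle(latitude_deg, doy)
    dr = inverse_relative_distance(doy)
    return (
        24.0 * 60.0 / math.pi
        * SOLAR_CONSTANT * dr
        * (ws * math.sin(phi) * math.sin(delta)
           + math.cos(phi) * math.cos(delta) * math.sin(ws))
    )


def clear_sky_radiation(ra: float, elevation_m: float) -> float:
    """Clear-sky shortwave envelope Rso (MJ·m⁻²·day⁻¹)."""
    return (0.75 + 2e-5 * elevation_m) * ra


def daily_net_radiation(
    day: WeatherDaily, site: Site, albedo: float = GRASS_ALBEDO
) -> float:
    """Daily net radiation Rn (MJ·m⁻²·day⁻¹) from measured shortwave."""
    doy = site.doy(day.das)
    ra = extraterrestrial_radiation(site.latitude_deg, doy)
    rso = clear_sky_radiation(ra, site.elevation_m)
    rns = (1.0 - albedo) * day.solar_rad
    # relative shortwave bounded to [0.3, 1]: overcast skies still lose
    # longwave, and Rs may not exceed the clear-sky envelope
    rel = 1.0 if rso <= 0 else min(max(day.solar_rad / rso, 0.3), 1.0)
    ea = day.ea
    rnl = (
        STEFAN_BOLTZMANN_DAY
        * 0.5 * ((day.t_max + 273.16) ** 4 + (day.t_min + 273.16) ** 4)
        * (0.34 - 0.14 * math.sqrt(max(ea, 0.0)))
        * (1.35 * rel - 0.35)
    )
    return rns - rnl


# ---------------------------------------------------------------------------
# resistances and the combination equation
# ---------------------------------------------------------------------------

def aerodynamic_resistance(
    wind: float,
    canopy_height: float,
    z_u: float = 2.0,
    z_t: float = 2.0,
    min_margin: float = 0.5,
) -> float:
    """Neutral-profile aerodynamic resistance (s·m⁻¹).

    FAO-56 log-profile: zero-plane displacement d = 2/3·h, roughness
    lengths z_om = 0.123·h and z_oh = 0.1·z_om.  The measurement height is
    raised above tall canopies so that z - d stays positive (minimum
    margin above the canopy top).
    """
    h = max(canopy_height, 0.05)
    u = max(wind, WIND_FLOOR)
    z_u = max(z_u, h + min_margin)
    z_t = max(z_t, h + min_margin)
    d = 2.0 / 3.0 * h
    z_om = 0.123 * h
    z_oh = 0.1 * z_om
    return (
        math.log((z_u - d) / z_om)
        * math.log((z_t - d) / z_oh)
        / (VON_KARMAN ** 2 * u)
    )


def penman_monteith_le(
    rn_w: float,
    g_w: float,
    t_c: float,
    vpd_kpa: float,
    ra: float,
    rs: float,
    pressure_kpa: float,
) -> float:
    """Latent heat flux (W·m⁻²) from the Penman–Monteith combination equation.

    ``rn_w`` and ``g_w`` in W·m⁻²; ``vpd_kpa`` the vapour pressure deficit.
    """
    delta = slope_saturation_vapor_pressure(t_c)  # kPa/K
    gamma = psychrometric_constant(pressure_kpa)  # kPa/K
    rho = air_density(t_c, pressure_kpa)
    # numerator terms carry (kPa/K)·(W/m²); dividing by (Δ+γ(1+rs/ra)) in
    # kPa/K leaves W/m²
    aero = rho * CP_AIR * vpd_kpa / ra
    return (delta * (rn_w - g_w) + aero) / (delta + gamma * (1.0 + rs / ra))


def _daily_pm_mm(
    day: WeatherDaily, site: Site, rs: float, canopy_height: float,
    albedo: float = GRASS_ALBEDO,
) -> float:
    rn = daily_net_radiation(day, site, albedo=albedo)  # MJ m-2 day-1
    rn_w = rn * 1e6 / 86400.0
    ra = aerodynamic_resistance(day.wind_2m, canopy_height)
    vpd = max(day.es - day.ea, 0.0)
    le_w = penman_monteith_le(
        rn_w, 0.0, day.t_mean, vpd, ra, rs,
        pressure_from_elevation(site.elevation_m),
    )
    mm = le_w * 86400.0 / (LAMBDA_FAO * 1e6)
    return max(mm, 0.0)


def reference_et0(day: WeatherDaily, site: Site = Site()) -> float:
    """FAO-56 daily reference evapotranspiration ET0 (mm·day⁻¹).

    Grass reference surface: height 0.12 m, rs = 70 s·m⁻¹, albedo 0.23.
    Negative combination-equation results are floored at zero.
    """
    return _daily_pm_mm(day, site, GRASS_RS, GRASS_HEIGHT)


def potential_et(
    day: WeatherDaily,
    lai: float,
    canopy_height: float,
    site: Site = Site(),
    leaf_resistance: float = LEAF_RESISTANCE,
    albedo: float = GRASS_ALBEDO,
) -> float:
    """Daily potential ET of the actual canopy (mm·day⁻¹).

    The bulk surface resistance decreases with leaf area,
    ``rs = rl / (0.5·max(LAI, 0.1))``, and the aerodynamic resistance uses
    the actual crop height in the log profile, so ETp grows with both LAI
    and height under the same weather.
    """
    if lai < 0:
        raise ValueError("LAI must be >= 0")
    if canopy_height < 0:
        raise ValueError("canopy height must be >= 0")
    lai_eff = max(lai, LAI_FLOOR)
    rs = leaf_resistance / (0.5 * lai_eff)
    return _daily_pm_mm(day, site, rs, canopy_height, albedo=albedo)


# ---------------------------------------------------------------------------
# hourly reference ET0 and daily upscaling of instantaneous fluxes
# ---------------------------------------------------------------------------

def hourly_reference_et0(
    t_air: float,
    ea_kpa: float,
    wind: float,
    sw_in: float,
    zenith_deg: float,
    doy: int,
    site: Site = Site(),
) -> float:
    """Hourly-formulation FAO-56 reference ET0 (mm·h⁻¹) at an instant.

    Daytime form: grass surface (rs = 70 s·m⁻¹), soil heat flux 0.1·Rn,
    instantaneous clear-sky envelope from the solar zenith angle.
    """
    cos_z = math.cos(math.radians(zenith_deg))
    if cos_z <= 0:
        raise ValueError("sun below horizon: hourly ET0 undefined")
    ra_w = SOLAR_CONSTANT_W * inverse_relative_distance(doy) * cos_z
    rso_w = (0.75 + 2e-5 * site.elevation_m) * ra_w
    rel = min(max(sw_in / rso_w, 0.3), 1.0) if rso_w > 0 else 1.0
    rns = (1.0 - GRASS_ALBEDO) * sw_in
    rnl = (
        STEFAN_BOLTZMANN_W
        * (t_air + 273.16) ** 4
        * (0.34 - 0.14 * math.sqrt(max(ea_kpa, 0.0)))
        * (1.35 * rel - 0.35)
    )
    rn = rns - rnl
    g = 0.1 * rn
    ra = aerodynamic_resistance(wind, GRASS_HEIGHT)
    vpd = max(saturation_vapor_pressure(t_air) - ea_kpa, 0.0)
    le_w = penman_monteith_le(
        rn, g, t_air, vpd, ra, GRASS_RS,
        pressure_from_elevation(site.elevation_m),
    )
    lam = latent_heat_of_vaporization(t_air) * 1e6  # J/kg
    return max(le_w, 0.0) * 3600.0 / lam


def daily_eta_from_instantaneous(
    le_inst: float,
    et0_hourly: float,
    et0_daily: float,
    t_air: float,
) -> float:
    """Upscale an instantaneous latent-heat flux to a daily ETa (mm·day⁻¹).

    ET0-ratio method: the instantaneous flux is converted to an hourly
    water depth with the temperature-dependent latent heat and multiplied
    by the ratio of the daily to hourly reference ET0, assuming the
    crop/reference ratio is preserved over the day.  Negative fluxes
    (condensation artefacts) are floored at zero before upscaling.
    """
    if not math.isfinite(le_inst):
        raise ValueError("non-finite instantaneous latent heat flux")
    if et0_hourly <= 0:
        raise ValueError("hourly reference ET0 must be positive at flight time")
    lam = latent_heat_of_vaporization(t_air) * 1e6
    mm_per_h = max(le_inst, 0.0) * 3600.0 / lam
    return mm_per_h * et0_daily / et0_hourly


def et0_series(days: list[WeatherDaily], site: Site = Site()) -> np.ndarray:
    """Vector of daily ET0 for a weather series (mm·day⁻¹)."""
    return np.array([reference_et0(d, site) for d in days])
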