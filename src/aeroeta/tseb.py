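"""Two-source (soil + canopy) energy balance with measured component temperatures.

The TSEB-2T scheme: high-resolution thermal imagery yields separate soil
(T_S) and canopy (T_C) temperatures per plot, so no Priestley–Taylor
initial transpiration guess is needed.  Net radiation is split between the
canopy and the soil by exponential extinction through the canopy; the
sensible heat of each source is driven by its temperature through a series
resistance network (within-canopy air node at the aerodynamic temperature
T_AC); latent heat of each source is the energy-balance residual.
Atmospheric stability is handled by Monin–Obukhov iteration with
Businger–Dyer correction functions.

Default coefficients (shortwave extinction κ = 0.45, soil-heat fraction
c_G = 0.35, Norman-style rx and soil-surface resistances) follow the TSEB
literature and are all exposed through :class:`TsebParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .evapotranspiration import (
    CP_AIR,
    STEFAN_BOLTZMANN_W,
    VON_KARMAN,
    WIND_FLOOR,
    air_density,
    pressure_from_elevation,
    saturation_vapor_pressure,
)

__all__ = [
    "InstantWeather",
    "TsebParams",
    "EnergyFluxes",
    "MissingComponentTemperature",
    "tseb_component_fluxes",
    "single_source_fluxes",
    "net_radiation_instant",
]

GRAVITY = 9.81


class MissingComponentTemperature(ValueError):
    """Raised when a component temperature required by TSEB-2T is absent."""


@dataclass(frozen=True)
class InstantWeather:
    """Meteorological state at image-acquisition time.

    ``sw_in`` is incoming shortwave (W·m⁻²); ``lw_in`` may be None, in
    which case clear-sky downwelling longwave is estimated from air
    temperature and vapour pressure (Brutsaert).  ``zenith_deg`` is the
    solar zenith angle. Wind is floored at 0.5 m·s⁻¹ for resistance
    stability.
    """

    t_air: float
    ea_kpa: float
    wind: float
    sw_in: float
    zenith_deg: float
    doy: int
    pressure_kpa: float = field(default=pressure_from_elevation(250.0))
    lw_in: float | None = None

    def __post_init__(self) -> None:
        if self.pressure_kpa <= 0:
            raise ValueError("pressure must be positive")
        if self.wind < 0:
            raise ValueError("wind must be >= 0")
        if self.ea_kpa < 0:
            raise ValueError("vapour pressure must be >= 0")

    @property
    def rh(self) -> float:
        return 100.0 * self.ea_kpa / saturation_vapor_pressure(self.t_air)

    def longwave_in(self) -> float:
        if self.lw_in is not None:
            return self.lw_in
        t_k = self.t_air + 273.16
        ea_hpa = self.ea_kpa * 10.0
        emis = 1.24 * (ea_hpa / t_k) ** (1.0 / 7.0)
        return emis * STEFAN_BOLTZMANN_W * t_k ** 4


@dataclass(frozen=True)
class TsebParams:
    """Tunable coefficients of the two-source scheme."""

    kappa: float = 0.45              # shortwave extinction coefficient
    c_g: float = 0.35                # G = c_g * Rn_soil
    albedo: float = 0.20             # composite surface shortwave albedo
    emissivity: float = 0.98         # composite surface emissivity
    leaf_width: float = 0.03         # m, wheat leaf dimension for rx
    rx_coeff: float = 90.0           # s^1/2 m^-1, Norman-style C'
    rss_a: float = 0.004             # soil resistance 1/(a + b*u_s)
    rss_b: float = 0.012
    max_iterations: int = 50
    obukhov_tol: float = 1e-3
    z_u: float = 2.0                 # wind measurement height, m
    z_t: float = 2.0                 # temperature measurement height, m
    floor_negative_le: bool = True
    stability: bool = True


@dataclass
class EnergyFluxes:
    """Two-source flux partition (all W·m⁻²)."""

    rn_c: float
    rn_s: float
    g: float
    h_c: float
    h_s: float
    le_c: float
    le_s: float
    converged: bool
    iterations: int
    obukhov_length: float = math.inf

    @property
    def rn(self) -> float:
        return self.rn_c + self.rn_s

    @property
    def h(self) -> float:
        return self.h_c + self.h_s

    @property
    def le(self) -> float:
        return self.le_c + self.le_s

    @property
    def closure_residual(self) -> float:
        return (self.rn_c + self.rn_s) - (
            self.h_c + self.h_s + self.le_c + self.le_s + self.g
        )


def net_radiation_instant(
    t_c: float,
    t_s: float,
    fc: float,
    weather: InstantWeather,
    params: TsebParams = TsebParams(),
) -> float:
    """Instantaneous net radiation over the composite surface (W·m⁻²).

    Single-Rn simplification: longwave exchange uses the composite
    radiometric temperature (4th-power mixture of canopy and soil weighted
    by fractional cover) rather than a full multi-stream canopy radiation
    model.
    """
    fc = min(max(fc, 0.0), 1.0)
    t_rad4 = fc * (t_c + 273.16) ** 4 + (1.0 - fc) * (t_s + 273.16) ** 4
    lw_net = params.emissivity * (
        weather.longwave_in() - STEFAN_BOLTZMANN_W * t_rad4
    )
    return (1.0 - params.albedo) * weather.sw_in + lw_net


def _psi_m(zeta: float) -> float:
    if zeta >= 0:
        return -5.0 * min(zeta, 2.0)
    x = (1.0 - 16.0 * zeta) ** 0.25
    return (
        2.0 * math.log((1.0 + x) / 2.0)
        + math.log((1.0 + x * x) / 2.0)
        - 2.0 * math.atan(x)
        + math.pi / 2.0
    )


def _psi_h(zeta: float) -> float:
    if zeta >= 0:
        return -5.0 * min(zeta, 2.0)
    x = (1.0 - 16.0 * zeta) ** 0.25
    return 2.0 * math.log((1.0 + x * x) / 2.0)


def _resistances(
    u: float,
    ph: float,
    lai: float,
    obukhov: float,
    params: TsebParams,
) -> tuple[float, float, float, float]:
    """(ra, rx, rss, u_star) for the series network at Obukhov length L."""
    h = max(ph, 0.1)
    d = 2.0 / 3.0 * h
    z_om = 0.123 * h
    z_oh = 0.1 * z_om
    z_u = max(params.z_u, h + 0.5)
    z_t = max(params.z_t, h + 0.5)

    if math.isfinite(obukhov) and obukhov != 0.0 and params.stability:
        psim = _psi_m((z_u - d) / obukhov) - _psi_m(z_om / obukhov)
        psih = _psi_h((z_t - d) / obukhov) - _psi_h(z_oh / obukhov)
    else:
        psim = psih = 0.0

    log_m = math.log((z_u - d) / z_om)
    log_h = math.log((z_t - d) / z_oh)
    u_star = VON_KARMAN * u / max(log_m - psim, 0.5)
    ra = max(log_h - psih, 0.5) / (VON_KARMAN * u_star)

    # wind at canopy top and exponential attenuation inside the canopy
    u_h = u_star / VON_KARMAN * math.log((h - d) / z_om)
    u_h = max(u_h, 0.1)
    atten = 0.28 * lai ** (2.0 / 3.0) * h ** (1.0 / 3.0) * params.leaf_width ** (
        -1.0 / 3.0
    )
    atten = min(max(atten, 0.5), 4.0)
    u_dz = u_h * math.exp(-atten * (1.0 - (d + z_om) / h))
    rx = params.rx_coeff / max(lai, 0.1) * math.sqrt(params.leaf_width / u_dz)

    u_soil = u_h * math.exp(-atten * (1.0 - 0.05 / h))
    rss = 1.0 / (params.rss_a + params.rss_b * max(u_soil, 0.01))
    return ra, rx, rss, u_star


def tseb_component_fluxes(
    t_c: float,
    t_s: float,
    lai: float,
    fc: float,
    ph: float,
    weather: InstantWeather,
    params: TsebParams = TsebParams(),
) -> EnergyFluxes:
    """Solve the TSEB-2T flux partition for one plot snapshot.

    Returns component net radiation, soil heat flux, sensible and latent
    heat for canopy and soil.  Latent heats are energy-balance residuals;
    negative residuals are floored at zero with the excess returned to the
    corresponding sensible flux, preserving closure exactly.
    """
    if t_c is None or not math.isfinite(t_c):
        raise MissingComponentTemperature("canopy temperature unavailable")
    if t_s is None or not math.isfinite(t_s):
        raise MissingComponentTemperature("soil temperature unavailable")
    if lai <= 0:
        raise ValueError("TSEB-2T requires LAI > 0")

    u = max(weather.wind, WIND_FLOOR)
    rho = air_density(weather.t_air, weather.pressure_kpa)
    rho_cp = rho * CP_AIR

    rn = net_radiation_instant(t_c, t_s, fc, weather, params)
    cos_z = max(math.cos(math.radians(weather.zenith_deg)), 0.05)
    rn_s = rn * math.exp(-params.kappa * lai / math.sqrt(2.0 * cos_z))
    rn_c = rn - rn_s
    g = params.c_g * rn_s

    obukhov = math.inf
    converged = False
    iterations = 0
    h_c = h_s = 0.0
    ra = rx = rss = u_star = 0.0
    for iterations in range(1, params.max_iterations + 1):
        ra, rx, rss, u_star = _resistances(u, ph, lai, obukhov, params)
        # series network: within-canopy air temperature from the three nodes
        t_ac = (
            weather.t_air / ra + t_c / rx + t_s / rss
        ) / (1.0 / ra + 1.0 / rx + 1.0 / rss)
        h_c = rho_cp * (t_c - t_ac) / rx
        h_s = rho_cp * (t_s - t_ac) / rss
        h_tot = h_c + h_s

        if not params.stability:
            converged = True
            break
        if abs(h_tot) < 1e-6:
            new_l = math.inf
        else:
            t_k = weather.t_air + 273.16
            new_l = (
                -rho_cp * u_star ** 3 * t_k
                / (VON_KARMAN * GRAVITY * h_tot)
            )
        if math.isinf(new_l) and math.isinf(obukhov):
            converged = True
            break
        if math.isfinite(new_l) and math.isfinite(obukhov):
            if abs(new_l - obukhov) < params.obukhov_tol:
                obukhov = new_l
                converged = True
                break
            obukhov = 0.5 * obukhov + 0.5 * new_l
        else:
            obukhov = new_l

    le_c = rn_c - h_c
    le_s = rn_s - g - h_s
    if params.floor_negative_le:
        if le_c < 0.0:
            h_c += le_c
            le_c = 0.0
        if le_s < 0.0:
            h_s += le_s
            le_s = 0.0

    return EnergyFluxes(
        rn_c=rn_c,
        rn_s=rn_s,
        g=g,
        h_c=h_c,
        h_s=h_s,
        le_c=le_c,
        le_s=le_s,
        converged=converged,
        iterations=iterations,
        obukhov_length=obukhov,
    )


def single_source_fluxes(
    t_rad: float,
    lai: float,
    fc: float,
    ph: float,
    weather: InstantWeather,
    params: TsebParams = TsebParams(),
) -> EnergyFluxes:
    """One-source residual fallback when a component temperature is missing.

    The whole surface is treated as a single source at the radiometric
    temperature; LE = Rn − G − H.  Returned with the canopy slots holding
    the bulk fluxes so downstream code can treat it uniformly (flagged by
    zero soil components apart from Rn_s/G).
    """
    u = max(weather.wind, WIND_FLOOR)
    rho_cp = air_density(weather.t_air, weather.pressure_kpa) * CP_AIR
    rn = net_radiation_instant(t_rad, t_rad, fc, weather, params)
    cos_z = max(math.cos(math.radians(weather.zenith_deg)), 0.05)
    rn_s = rn * math.exp(-params.kappa * max(lai, 0.1) / math.sqrt(2.0 * cos_z))
    g = params.c_g * rn_s
    obukhov = math.inf
    h = 0.0
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        ra, _, _, u_star = _resistances(u, ph, max(lai, 0.1), obukhov, params)
        h = rho_cp * (t_rad - weather.t_air) / ra
        if not params.stability or abs(h) < 1e-6:
            break
        t_k = weather.t_air + 273.16
        new_l = -rho_cp * u_star ** 3 * t_k / (VON_KARMAN * GRAVITY * h)
        if math.isfinite(obukhov) and abs(new_l - obukhov) < params.obukhov_tol:
            obukhov = new_l
            break
        obukhov = new_l if math.isinf(obukhov) else 0.5 * (obukhov + new_l)
    le = rn - g - h
    if params.floor_negative_le and le < 0:
        h += le
        le = 0.0
    return EnergyFluxes(
        rn_c=rn - rn_s,
        rn_s=rn_s,
        g=g,
        h_c=h,
        h_s=0.0,
        le_c=le,
        le_s=0.0,
        converged=True,
        iterations=iterations,
        obukhov_length=obukhov,
    )
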