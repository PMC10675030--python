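"""Synthetic wheat-trial generator with known ground truth.

Emulates the study design the pipeline targets: ~22 varieties × 2 water
regimes (full irrigation, rainfed) × blocks, a Mediterranean winter-wheat
season (December sowing, ~460 mm annual rainfall climate), sigmoid LAI
trajectories per variety, stress (Ks) trajectories that stay at 1 through
DAS 100 and decline post-anthesis under rainfed, flight snapshots (VARI,
plant height, fractional cover, component temperatures) consistent with
the truth, and yields with an asymptotic response to grain-filling ETa.

Canopy temperatures can be generated two ways (``TrialConfig.tc_mode``):

* ``"linear"`` — a minimal stress-to-temperature model, T_C rises by a
  configurable gain (default 5 °C) per unit (1 − Ks) above the unstressed
  canopy temperature; convenient for arithmetic checks.
* ``"energy_balance"`` — numerically inverts the TSEB + daily-upscaling
  chain so that the temperatures encode exactly the true stress
  coefficient; this is the mode under which the full pipeline can recover
  the true cumulative ETa.

Everything is deterministic given the seed; all constants live in
:class:`TrialConfig`, not in code.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .evapotranspiration import (
    Site,
    WeatherDaily,
    extraterrestrial_radiation,
    hourly_reference_et0,
    latent_heat_of_vaporization,
    potential_et,
    pressure_from_elevation,
    reference_et0,
    solar_declination,
    sunset_hour_angle,
)
from .seasonal import KS_UNITY_UNTIL_DAS
from .tseb import InstantWeather, TsebParams, tseb_component_fluxes

__all__ = [
    "TrialConfig",
    "TrueVarietyState",
    "TrialData",
    "generate_weather",
    "generate_varieties",
    "generate_flight_observations",
    "generate_yield",
    "irrigation_schedule",
    "generate_trial",
    "true_daily_series",
]

FULL_IRRIGATION = "full_irrigation"
RAINFED = "rainfed"


@dataclass(frozen=True)
class TrialConfig:
    """All knobs of the synthetic trial (defaults emulate the target study)."""

    n_varieties: int = 22
    n_blocks: int = 3
    treatments: tuple[str, ...] = (FULL_IRRIGATION, RAINFED)
    season_length: int = 175
    flight_das: tuple[int, ...] = (118, 138, 155)   # thermal + RGB
    rgb_flight_das: tuple[int, ...] = (61, 81)      # RGB-only, for LAI curves
    site: Site = field(default_factory=Site)

    # observation noise (standard deviations)
    vari_sd: float = 0.02
    ph_sd: float = 0.02        # m
    fc_sd: float = 0.03
    temp_sd: float = 0.5       # °C on T_C and T_S
    lai_sd: float = 0.3        # ground-truth LAI measurement noise

    # weather generator
    t_annual_mean: float = 14.5
    t_amplitude: float = 9.5
    coldest_doy: int = 15
    diurnal_range: float = 10.0
    temp_noise_sd: float = 2.0
    temp_noise_ar1: float = 0.7
    rainfall_total_mm: float = 130.0
    rainfall_tolerance: float = 0.15   # relative, for validation
    wet_day_prob: float = 0.18
    mean_wind: float = 2.2
    wind_sd: float = 0.8
    rh_base: float = 68.0
    rh_sd: float = 6.0

    # linear map from (PH, VARI, fc) to LAI used to invert observations
    lai_map_intercept: float = -1.071
    lai_map_ph: float = 5.063
    lai_map_vari: float = 5.451
    lai_map_fc: float = -1.661

    # canopy/soil temperature generation
    tc_mode: str = "linear"            # or "energy_balance"
    tc_unstressed: float | None = None  # °C; None -> flight air temperature
    tc_stress_gain: float = 5.0        # °C per unit (1 - Ks)
    ts_offset: float = 6.0             # soil minus canopy, unstressed
    ts_stress_gain: float = 4.0
    tseb: TsebParams = field(default_factory=TsebParams)

    # phenology: heading varies by variety; physiological maturity is
    # synchronous (terminal drought/heat compresses maturity differences),
    # a few days after the final flight
    heading_das_min: int = 127
    heading_das_max: int = 133
    maturity_das: int = 162

    # stress truth (piecewise linear in DAS): rainfed Ks starts declining at
    # anthesis (heading + offset) and reaches ks_end at maturity
    stress_onset_offset_das: int = 0
    ks_end_min: float = 0.35
    ks_end_max: float = 0.60

    # asymptotic yield response to grain-filling ETa
    ymax: float = 11000.0              # kg/ha
    yield_rate_k: float = 0.012        # per mm
    yield_offset_mm: float = 50.0
    variety_effect_sd: float = 0.05
    yield_noise_sd: float = 300.0      # kg/ha
    tkw_base: float = 28.0             # g
    tkw_range: float = 26.0
    tkw_noise_sd: float = 1.5

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_varieties < 2:
            raise ValueError("need >= 2 varieties")
        if self.season_length < 1:
            raise ValueError("season length must be >= 1 day")
        d = self.flight_das
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("flight DAS must be strictly increasing")
        if d and min(d) <= KS_UNITY_UNTIL_DAS:
            raise ValueError("thermal flights must all be after DAS 100")
        if max(d, default=0) > self.season_length:
            raise ValueError("flight after season end")
        for name in ("vari_sd", "ph_sd", "fc_sd", "temp_sd", "lai_sd",
                     "temp_noise_sd", "yield_noise_sd", "tkw_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ymax < 0:
            raise ValueError("Ymax must be >= 0")
        if self.maturity_das > self.season_length:
            raise ValueError("maturity beyond season end")
        if d and self.maturity_das <= max(d):
            raise ValueError("maturity must follow the final thermal flight")
        if not KS_UNITY_UNTIL_DAS < self.heading_das_min <= self.heading_das_max:
            raise ValueError("heading range must lie after DAS 100, min <= max")
        if self.tc_mode not in ("linear", "energy_balance"):
            raise ValueError(f"unknown tc_mode {self.tc_mode!r}")

    def zero_noise(self) -> "TrialConfig":
        """Copy with every observation noise set to zero (truth recovery)."""
        return replace(
            self, vari_sd=0.0, ph_sd=0.0, fc_sd=0.0, temp_sd=0.0,
            lai_sd=0.0, yield_noise_sd=0.0, tkw_noise_sd=0.0,
        )


@dataclass(frozen=True)
class TrueVarietyState:
    """Ground truth for one variety."""

    name: str
    a: float                 # sigmoid slope, per day
    b: float                 # sigmoid midpoint, DAS
    c: float                 # LAI asymptote
    ph_max: float            # m, height asymptote (same sigmoid shape)
    heading_das: int
    maturity_das: int
    ks_end_rainfed: float    # Ks at maturity under rainfed
    stress_onset_das: int
    variety_effect: float    # multiplicative yield effect

    def __post_init__(self) -> None:
        if not 0 < self.heading_das < self.maturity_das:
            raise ValueError("need 0 < heading < maturity")

    def lai(self, das) -> np.ndarray | float:
        das = np.asarray(das, dtype=float)
        out = self.c / (1.0 + np.exp(-self.a * (das - self.b)))
        return float(out) if out.ndim == 0 else out

    def ph(self, das) -> np.ndarray | float:
        das = np.asarray(das, dtype=float)
        out = self.ph_max / (1.0 + np.exp(-self.a * (das - self.b)))
        return float(out) if out.ndim == 0 else out

    def fc(self, das) -> np.ndarray | float:
        """Fractional cover tied to LAI by Beer's-law gap fraction."""
        out = 1.0 - np.exp(-0.6 * np.asarray(self.lai(das), dtype=float))
        out = np.clip(out, 0.0, 0.98)
        return float(out) if out.ndim == 0 else out

    def ks(self, das, treatment: str) -> np.ndarray | float:
        """Piecewise-linear stress trajectory: 1 until onset, then a linear
        decline to ``ks_end_rainfed`` at maturity (rainfed only)."""
        das = np.asarray(das, dtype=float)
        if treatment == FULL_IRRIGATION:
            out = np.ones_like(das)
        else:
            frac = (das - self.stress_onset_das) / max(
                self.maturity_das - self.stress_onset_das, 1
            )
            frac = np.clip(frac, 0.0, 1.0)
            out = 1.0 - (1.0 - self.ks_end_rainfed) * frac
        return float(out) if out.ndim == 0 else out


@dataclass
class TrialData:
    """Complete synthetic trial: inputs for the pipeline plus the truth."""

    config: TrialConfig
    varieties: list[TrueVarietyState]
    weather: list[WeatherDaily]
    snapshots: pd.DataFrame
    ground_truth_lai: pd.DataFrame
    phenology: pd.DataFrame
    agronomy: pd.DataFrame
    truth_series: dict[tuple[str, str], pd.DataFrame]

    @property
    def weather_frame(self) -> pd.DataFrame:
        site = self.config.site
        return pd.DataFrame(
            {
                "das": [w.das for w in self.weather],
                "doy": [site.doy(w.das) for w in self.weather],
                "t_min": [w.t_min for w in self.weather],
                "t_max": [w.t_max for w in self.weather],
                "rh_mean": [w.rh_mean for w in self.weather],
                "wind_2m": [w.wind_2m for w in self.weather],
                "solar_rad": [w.solar_rad for w in self.weather],
                "rainfall": [w.rainfall for w in self.weather],
                "et0": [w.et0 for w in self.weather],
            }
        )

    def write_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.weather_frame.to_csv(out / "weather.csv", index=False)
        self.snapshots.to_csv(out / "snapshots.csv", index=False)
        self.ground_truth_lai.to_csv(out / "lai_ground_truth.csv", index=False)
        self.phenology.to_csv(out / "phenology.csv", index=False)
        self.agronomy.to_csv(out / "agronomy.csv", index=False)
        (out / "trial_config.json").write_text(
            json.dumps(
                {k: v for k, v in asdict(self.config).items()
                 if isinstance(v, (int, float, str, list, tuple, type(None)))},
                indent=2, default=list,
            )
        )


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

def generate_weather(config: TrialConfig, seed: int | None = None
                     ) -> list[WeatherDaily]:
    """Daily weather for the season: sinusoidal seasonal temperature with
    AR(1) noise, radiation below the clear-sky envelope, sparse rainfall
    events rescaled to the configured season total, and FAO-56 ET0."""
    if config.season_length < 1:
        raise ValueError("season length must be >= 1 day")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.season_length + 1
    site = config.site
    days = np.arange(n)
    doy = np.array([site.doy(d) for d in days])

    t_season = config.t_annual_mean - config.t_amplitude * np.cos(
        2.0 * math.pi * (doy - config.coldest_doy) / 365.0
    )
    noise = np.zeros(n)
    if config.temp_noise_sd > 0:
        eps = rng.normal(0.0, config.temp_noise_sd, size=n)
        for i in range(1, n):
            noise[i] = config.temp_noise_ar1 * noise[i - 1] + eps[i]
    t_mean = t_season + noise
    half_range = 0.5 * config.diurnal_range
    t_min = t_mean - half_range
    t_max = t_mean + half_range

    wet = rng.random(n) < config.wet_day_prob
    amounts = np.where(wet, rng.gamma(1.2, 6.0, size=n), 0.0)
    if amounts.sum() == 0:
        amounts[rng.integers(0, n)] = 1.0
    amounts *= config.rainfall_total_mm / amounts.sum()

    clearness = np.where(
        amounts > 0, rng.uniform(0.25, 0.45, size=n),
        rng.uniform(0.55, 0.75, size=n),
    )
    if config.temp_noise_sd == 0:
        clearness = np.full(n, 0.65)
    ra = np.array([
        extraterrestrial_radiation(site.latitude_deg, int(d)) for d in doy
    ])
    solar = clearness * ra

    rh = np.clip(
        config.rh_base
        - 0.8 * (t_mean - config.t_annual_mean)
        + (rng.normal(0.0, config.rh_sd, size=n)
           if config.temp_noise_sd > 0 else 0.0)
        + np.where(amounts > 0, 12.0, 0.0),
        25.0, 98.0,
    )
    wind = np.clip(
        rng.normal(config.mean_wind, config.wind_sd, size=n)
        if config.temp_noise_sd > 0 else np.full(n, config.mean_wind),
        0.5, None,
    )

    out = []
    for i in range(n):
        day = WeatherDaily(
            das=int(days[i]),
            t_min=float(t_min[i]),
            t_max=float(t_max[i]),
            rh_mean=float(rh[i]),
            wind_2m=float(wind[i]),
            solar_rad=float(solar[i]),
            rainfall=float(amounts[i]),
        )
        day.et0 = reference_et0(day, site)
        out.append(day)
    return out


# ---------------------------------------------------------------------------
# varieties / truth
# ---------------------------------------------------------------------------

def generate_varieties(config: TrialConfig, seed: int | None = None
                       ) -> list[TrueVarietyState]:
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 1_000_003
    )
    out = []
    for i in range(config.n_varieties):
        a = rng.uniform(0.08, 0.13)
        b = rng.uniform(108.0, 124.0)
        c = rng.uniform(4.8, 7.4)
        # heading (≈ anthesis, the second flight's target stage) late April;
        # grain fill ~29-35 days to the synchronous maturity
        maturity = config.maturity_das
        heading = int(
            rng.integers(config.heading_das_min, config.heading_das_max + 1)
        )
        onset = int(
            np.clip(heading + config.stress_onset_offset_das,
                    KS_UNITY_UNTIL_DAS + 1, maturity - 1)
        )
        out.append(
            TrueVarietyState(
                name=f"Variety {i + 1}",
                a=float(a),
                b=float(b),
                c=float(c),
                ph_max=float(rng.uniform(0.75, 1.05)),
                heading_das=heading,
                maturity_das=maturity,
                ks_end_rainfed=float(
                    rng.uniform(config.ks_end_min, config.ks_end_max)
                ),
                stress_onset_das=onset,
                variety_effect=float(
                    rng.normal(1.0, config.variety_effect_sd)
                ),
            )
        )
    return out


def true_daily_series(
    variety: TrueVarietyState,
    treatment: str,
    weather: list[WeatherDaily],
    config: TrialConfig,
) -> pd.DataFrame:
    """Ground-truth daily LAI/ETp/Ks/ETa table over [0, maturity]."""
    das = np.arange(0, variety.maturity_das + 1)
    lai = np.asarray(variety.lai(das))
    ph = np.asarray(variety.ph(das))
    etp = np.array([
        potential_et(weather[d], float(lai[d]), float(ph[d]), config.site)
        for d in das
    ])
    ks = np.asarray(variety.ks(das, treatment))
    eta = ks * etp
    return pd.DataFrame(
        {"das": das, "lai": lai, "ph": ph, "etp": etp, "ks": ks,
         "eta": eta, "cum_eta": np.cumsum(eta)}
    )


# ---------------------------------------------------------------------------
# flight observations
# ---------------------------------------------------------------------------

def _noon_geometry(site: Site, das: int, solar_mj: float
                   ) -> tuple[float, float]:
    """(solar zenith angle deg, instantaneous shortwave W/m²) at solar noon,
    assuming a sinusoidal diurnal irradiance course."""
    doy = site.doy(das)
    phi = math.radians(site.latitude_deg)
    delta = solar_declination(doy)
    cos_z = math.sin(phi) * math.sin(delta) + math.cos(phi) * math.cos(delta)
    zenith = math.degrees(math.acos(min(max(cos_z, -1.0), 1.0)))
    daylight_s = sunset_hour_angle(site.latitude_deg, doy) / math.pi * 86400.0
    sw_noon = solar_mj * 1e6 * math.pi / (2.0 * daylight_s)
    return zenith, sw_noon


def _invert_vari(config: TrialConfig, lai: float, ph: float, fc: float) -> float:
    """VARI such that the configured linear LAI map returns ``lai`` exactly."""
    return (
        lai
        - config.lai_map_ph * ph
        - config.lai_map_fc * fc
        - config.lai_map_intercept
    ) / config.lai_map_vari


def _target_canopy_temperature(
    variety: TrueVarietyState,
    treatment: str,
    das: int,
    weather: list[WeatherDaily],
    inst: InstantWeather,
    config: TrialConfig,
) -> tuple[float, float]:
    """(T_C, T_S) encoding the true Ks under the configured mode."""
    ks = float(variety.ks(das, treatment))
    delta_soil = config.ts_offset + config.ts_stress_gain * (1.0 - ks)
    if config.tc_mode == "linear":
        base = (
            inst.t_air if config.tc_unstressed is None else config.tc_unstressed
        )
        t_c = base + config.tc_stress_gain * (1.0 - ks)
        return t_c, t_c + delta_soil

    # energy-balance mode: invert TSEB + upscaling for the flux whose daily
    # upscaled ETa equals ks * ETp(true LAI) on the flight day
    lai = float(variety.lai(das))
    ph = float(variety.ph(das))
    fc = float(variety.fc(das))
    day = weather[das]
    etp = potential_et(day, lai, ph, config.site)
    eta_daily = ks * etp
    et0_daily = day.et0 if day.et0 is not None else reference_et0(day, config.site)
    et0_h = hourly_reference_et0(
        inst.t_air, inst.ea_kpa, inst.wind, inst.sw_in, inst.zenith_deg,
        inst.doy, config.site,
    )
    mm_h = eta_daily * et0_h / et0_daily
    le_target = mm_h * latent_heat_of_vaporization(inst.t_air) * 1e6 / 3600.0

    def gap(t_c: float) -> float:
        fluxes = tseb_component_fluxes(
            t_c, t_c + delta_soil, lai, fc, ph, inst, config.tseb
        )
        return fluxes.le - le_target

    lo, hi = inst.t_air - 20.0, inst.t_air + 40.0
    if gap(lo) * gap(hi) > 0:
        lo, hi = inst.t_air - 35.0, inst.t_air + 60.0
        if gap(lo) * gap(hi) > 0:
            raise RuntimeError(
                f"cannot bracket canopy temperature for {variety.name} "
                f"{treatment} DAS {das}"
            )
    t_c = brentq(gap, lo, hi, xtol=1e-10)
    return float(t_c), float(t_c) + delta_soil


def generate_flight_observations(
    varieties: list[TrueVarietyState],
    weather: list[WeatherDaily],
    config: TrialConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """One snapshot row per plot × flight (thermal and RGB-only flights).

    At zero noise the linear LAI map applied to the generated (PH, VARI,
    fc) returns the true LAI exactly, and (in energy-balance mode) the
    component temperatures reproduce the true stress coefficient through
    the TSEB chain.
    """
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 2_000_033
    )
    site = config.site
    all_flights = sorted(
        [(d, True) for d in config.flight_das]
        + [(d, False) for d in config.rgb_flight_das]
    )
    if all_flights and all_flights[0][0] < 0:
        raise ValueError("flight before sowing")
    if all_flights and all_flights[-1][0] > config.season_length:
        raise ValueError("flight after season end")

    pressure = pressure_from_elevation(site.elevation_m)
    rows = []
    for das, has_thermal in all_flights:
        day = weather[das]
        t_air = day.t_max - 1.0
        zenith, sw_noon = _noon_geometry(site, das, day.solar_rad)
        inst = InstantWeather(
            t_air=t_air, ea_kpa=day.ea, wind=day.wind_2m, sw_in=sw_noon,
            zenith_deg=zenith, doy=site.doy(das), pressure_kpa=pressure,
        )
        for variety in varieties:
            for treatment in config.treatments:
                lai = float(variety.lai(das))
                ph_true = float(variety.ph(das))
                fc_true = float(variety.fc(das))
                if has_thermal:
                    t_c0, t_s0 = _target_canopy_temperature(
                        variety, treatment, das, weather, inst, config
                    )
                for block in range(1, config.n_blocks + 1):
                    ph = ph_true + rng.normal(0.0, config.ph_sd) \
                        if config.ph_sd else ph_true
                    fc = fc_true + rng.normal(0.0, config.fc_sd) \
                        if config.fc_sd else fc_true
                    fc = float(np.clip(fc, 0.0, 1.0))
                    vari = _invert_vari(config, lai, ph_true, fc_true)
                    if config.vari_sd:
                        vari += rng.normal(0.0, config.vari_sd)
                    row = {
                        "plot_id": f"{variety.name}|{treatment}|b{block}",
                        "variety": variety.name,
                        "treatment": treatment,
                        "block": block,
                        "das": das,
                        "doy": site.doy(das),
                        "has_thermal": has_thermal,
                        "PH": ph,
                        "VARI": vari,
                        "fc": fc,
                        "t_air": t_air,
                        "ea_kpa": day.ea,
                        "wind": day.wind_2m,
                        "sw_in": sw_noon,
                        "zenith_deg": zenith,
                        "pressure_kpa": pressure,
                        "t_c": np.nan,
                        "t_s": np.nan,
                    }
                    if has_thermal:
                        row["t_c"] = t_c0 + (
                            rng.normal(0.0, config.temp_sd)
                            if config.temp_sd else 0.0
                        )
                        row["t_s"] = t_s0 + (
                            rng.normal(0.0, config.temp_sd)
                            if config.temp_sd else 0.0
                        )
                    rows.append(row)
    return pd.DataFrame(rows)


def generate_lai_ground_truth(
    varieties: list[TrueVarietyState],
    config: TrialConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Ceptometer-style LAI calibration measurements (block 1, all flights)."""
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 3_000_017
    )
    rows = []
    for das in sorted((*config.flight_das, *config.rgb_flight_das)):
        for variety in varieties:
            for treatment in config.treatments:
                lai = float(variety.lai(das))
                if config.lai_sd:
                    lai += rng.normal(0.0, config.lai_sd)
                rows.append(
                    {
                        "plot_id": f"{variety.name}|{treatment}|b1",
                        "variety": variety.name,
                        "treatment": treatment,
                        "block": 1,
                        "das": das,
                        "LAI": lai,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# yield and irrigation
# ---------------------------------------------------------------------------

def generate_yield(
    varieties: list[TrueVarietyState],
    eta_gf: pd.DataFrame,
    config: TrialConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-plot yield traits from grain-filling ETa.

    Asymptotic response GY = Ymax·(1 − exp(−k·max(0, ETa_GF − offset)))
    scaled by the variety effect, plus Gaussian noise; TKW and grain
    number share the monotone dependence.  ``eta_gf`` needs columns
    variety, treatment, block, eta_gf.
    """
    if config.ymax < 0:
        raise ValueError("Ymax must be >= 0")
    if (eta_gf["eta_gf"] < 0).any():
        raise ValueError("ETa_GF must be >= 0")
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 4_000_037
    )
    effects = {v.name: v.variety_effect for v in varieties}
    rows = []
    for rec in eta_gf.itertuples(index=False):
        x = max(0.0, rec.eta_gf - config.yield_offset_mm)
        response = 1.0 - math.exp(-config.yield_rate_k * x)
        gy = config.ymax * response * effects[rec.variety]
        if config.yield_noise_sd:
            gy += rng.normal(0.0, config.yield_noise_sd)
        tkw = config.tkw_base + config.tkw_range * response
        if config.tkw_noise_sd:
            tkw += rng.normal(0.0, config.tkw_noise_sd)
        gy = max(gy, 0.0)
        tkw = max(tkw, 1.0)
        rows.append(
            {
                "plot_id": f"{rec.variety}|{rec.treatment}|b{rec.block}",
                "variety": rec.variety,
                "treatment": rec.treatment,
                "block": rec.block,
                "GY": gy,
                "TKW": tkw,
                "grain_number": 100.0 * gy / tkw,
            }
        )
    return pd.DataFrame(rows)


def irrigation_schedule(
    et0: np.ndarray,
    kc: np.ndarray,
    rainfall: np.ndarray,
    treatment: str = FULL_IRRIGATION,
) -> np.ndarray:
    """Weekly irrigation doses (mm) from a crop-coefficient water balance.

    Each week's dose replaces the crop ET (Kc·ET0) not met by rain:
    max(0, Σ Kc·ET0 − Σ rain).  The rainfed treatment receives nothing.
    """
    et0 = np.asarray(et0, dtype=float)
    kc = np.asarray(kc, dtype=float)
    rain = np.asarray(rainfall, dtype=float)
    if not (len(et0) == len(kc) == len(rain)):
        raise ValueError("ET0, Kc and rainfall series lengths differ")
    if (kc < 0).any():
        raise ValueError("Kc must be >= 0")
    n_weeks = math.ceil(len(et0) / 7)
    if treatment == RAINFED:
        return np.zeros(n_weeks)
    doses = np.empty(n_weeks)
    for w in range(n_weeks):
        sl = slice(7 * w, 7 * (w + 1))
        doses[w] = max(0.0, (kc[sl] * et0[sl]).sum() - rain[sl].sum())
    return doses


# ---------------------------------------------------------------------------
# full trial
# ---------------------------------------------------------------------------

def generate_trial(config: TrialConfig | None = None,
                   seed: int | None = None) -> TrialData:
    """Generate a complete, internally consistent synthetic trial."""
    config = config or TrialConfig()
    base = config.seed if seed is None else seed
    weather = generate_weather(config, base)
    varieties = generate_varieties(config, base)
    snapshots = generate_flight_observations(varieties, weather, config, base)
    lai_truth = generate_lai_ground_truth(varieties, config, base)

    phenology = pd.DataFrame(
        {
            "variety": [v.name for v in varieties],
            "heading_das": [v.heading_das for v in varieties],
            "maturity_das": [v.maturity_das for v in varieties],
        }
    )

    truth_series: dict[tuple[str, str], pd.DataFrame] = {}
    eta_gf_rows = []
    for v in varieties:
        for treatment in config.treatments:
            series = true_daily_series(v, treatment, weather, config)
            truth_series[(v.name, treatment)] = series
            gf = float(
                series.loc[series["das"] > v.heading_das, "eta"].sum()
            )
            for block in range(1, config.n_blocks + 1):
                eta_gf_rows.append(
                    {"variety": v.name, "treatment": treatment,
                     "block": block, "eta_gf": gf}
                )
    agronomy = generate_yield(
        varieties, pd.DataFrame(eta_gf_rows), config, base
    )
    return TrialData(
        config=config,
        varieties=varieties,
        weather=weather,
        snapshots=snapshots,
        ground_truth_lai=lai_truth,
        phenology=phenology,
        agronomy=agronomy,
        truth_series=truth_series,
    )
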