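"""End-to-end pipeline: flight snapshots → daily cumulative ETa integrals.

Chains the pieces the way the field campaign is processed:

1. calibrate (or accept) the LAI regression on ground-truthed plots and
   predict LAI for every snapshot;
2. fit per variety × treatment sigmoid trajectories for LAI and plant
   height, giving daily biophysical inputs;
3. compute daily potential ET (Penman–Monteith with canopy-dependent
   resistances) over the season;
4. per thermal flight, solve the two-source energy balance from the
   component temperatures, upscale the instantaneous latent heat to a
   daily ETa (ET0-ratio method) and form the stress coefficient
   Ks = ETa/ETp;
5. interpolate Ks across the season (step scheme, Ks = 1 through DAS
   100), integrate daily ETa, split at heading, and derive per-plot water
   productivity from grain yield.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .canopy import (
    LaiRegression,
    SigmoidGrowth,
    daily_lai_series,
    fit_lai_regression,
)
from .evapotranspiration import (
    Site,
    WeatherDaily,
    daily_eta_from_instantaneous,
    hourly_reference_et0,
    potential_et,
    reference_et0,
)
from .seasonal import (
    KsPoint,
    Phenology,
    crop_stress_coefficient,
    daily_eta_series,
    interpolate_ks,
    stage_integrals,
    water_productivity,
)
from .tseb import InstantWeather, TsebParams, tseb_component_fluxes

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "weather_from_frame"]


@dataclass(frozen=True)
class PipelineConfig:
    site: Site = field(default_factory=Site)
    tseb: TsebParams = field(default_factory=TsebParams)
    ks_cap: float | None = None
    interpolation: str = "step"
    floor_lai_at_zero: bool = True   # guard sigmoid fits against noise dips


@dataclass
class PipelineResult:
    """Outputs of one pipeline run."""

    lai_model: LaiRegression
    sigmoid_params: pd.DataFrame     # variety, treatment, a, b, c (LAI + PH)
    fluxes: pd.DataFrame             # per plot × thermal flight
    et_series: pd.DataFrame          # long daily table per variety × treatment
    performance: pd.DataFrame        # per variety × treatment agronomic summary


def weather_from_frame(frame: pd.DataFrame, site: Site) -> list[WeatherDaily]:
    """Build the daily weather list (with ET0) from a weather table."""
    frame = frame.sort_values("das").reset_index(drop=True)
    out = []
    for rec in frame.itertuples(index=False):
        day = WeatherDaily(
            das=int(rec.das),
            t_min=float(rec.t_min),
            t_max=float(rec.t_max),
            rh_mean=float(rec.rh_mean),
            wind_2m=float(rec.wind_2m),
            solar_rad=float(rec.solar_rad),
            rainfall=float(getattr(rec, "rainfall", 0.0)),
        )
        day.et0 = (
            float(rec.et0)
            if hasattr(rec, "et0") and np.isfinite(rec.et0)
            else reference_et0(day, site)
        )
        out.append(day)
    if [d.das for d in out] != list(range(len(out))):
        raise ValueError("weather table must cover consecutive DAS from 0")
    return out


def _flight_instant(rec, site: Site) -> InstantWeather:
    return InstantWeather(
        t_air=float(rec.t_air),
        ea_kpa=float(rec.ea_kpa),
        wind=float(rec.wind),
        sw_in=float(rec.sw_in),
        zenith_deg=float(rec.zenith_deg),
        doy=int(rec.doy),
        pressure_kpa=float(rec.pressure_kpa),
    )


def run_pipeline(
    snapshots: pd.DataFrame,
    weather: pd.DataFrame | list[WeatherDaily],
    phenology: pd.DataFrame,
    agronomy: pd.DataFrame | None = None,
    ground_truth_lai: pd.DataFrame | None = None,
    lai_model: LaiRegression | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the snapshot-to-season pipeline.

    ``snapshots`` needs one row per plot × flight with columns
    plot_id/variety/treatment/block/das/doy/has_thermal, the RGB
    observables PH/VARI/fc, the flight weather
    (t_air/ea_kpa/wind/sw_in/zenith_deg/pressure_kpa) and, for thermal
    flights, t_c/t_s.  Either a fitted ``lai_model`` or a
    ``ground_truth_lai`` calibration table must be supplied.
    """
    config = config or PipelineConfig()
    site = config.site
    days = (
        weather
        if isinstance(weather, list)
        else weather_from_frame(weather, site)
    )
    et0_daily = np.array([d.et0 for d in days])

    if lai_model is None:
        if ground_truth_lai is None:
            raise ValueError("need a fitted lai_model or a ground-truth table")
        calib = ground_truth_lai.merge(
            snapshots[["plot_id", "das", "PH", "VARI", "fc"]],
            on=["plot_id", "das"],
            how="inner",
        )
        lai_model = fit_lai_regression(calib)

    snaps = snapshots.copy()
    snaps["lai_pred"] = lai_model.predict(snaps[["PH", "VARI", "fc"]])
    if config.floor_lai_at_zero:
        snaps["lai_pred"] = snaps["lai_pred"].clip(lower=0.0)

    phen = {
        rec.variety: Phenology(
            variety=rec.variety,
            heading_das=int(rec.heading_das),
            maturity_das=int(rec.maturity_das),
        )
        for rec in phenology.itertuples(index=False)
    }

    sig_rows = []
    flux_rows = []
    series_rows = []
    perf_rows = []

    for (variety, treatment), group in snaps.groupby(
        ["variety", "treatment"], sort=True
    ):
        ph_obj = phen[variety]
        if ph_obj.maturity_das >= len(days):
            raise ValueError(
                f"weather series ends before maturity of {variety}"
            )

        lai_fit = SigmoidGrowth().fit(group["das"], group["lai_pred"])
        height_fit = SigmoidGrowth().fit(group["das"], group["PH"])
        sig_rows.append(
            {
                "variety": variety, "treatment": treatment,
                "a": lai_fit.a_, "b": lai_fit.b_, "c": lai_fit.c_,
                "ph_a": height_fit.a_, "ph_b": height_fit.b_,
                "ph_c": height_fit.c_, "lai_rmse": lai_fit.rmse_,
            }
        )

        das_grid = np.arange(0, ph_obj.maturity_das + 1)
        lai_daily = daily_lai_series(lai_fit.params_, ph_obj.maturity_das)
        ph_daily = height_fit.predict(das_grid)
        etp_daily = np.array(
            [
                potential_et(
                    days[d], float(lai_daily[d]), float(ph_daily[d]), site
                )
                for d in das_grid
            ]
        )

        # per-flight Ks from the two-source energy balance, block-averaged
        ks_points = []
        thermal = group[group["has_thermal"].astype(bool)]
        for das_flight, fgroup in thermal.groupby("das"):
            if das_flight > ph_obj.maturity_das:
                continue
            ks_values = []
            for rec in fgroup.itertuples(index=False):
                inst = _flight_instant(rec, site)
                fluxes = tseb_component_fluxes(
                    float(rec.t_c), float(rec.t_s),
                    max(float(rec.lai_pred), 0.1), float(rec.fc),
                    float(rec.PH), inst, config.tseb,
                )
                et0_h = hourly_reference_et0(
                    inst.t_air, inst.ea_kpa, inst.wind, inst.sw_in,
                    inst.zenith_deg, inst.doy, site,
                )
                eta_day = daily_eta_from_instantaneous(
                    fluxes.le, et0_h, float(et0_daily[das_flight]), inst.t_air
                )
                ks = crop_stress_coefficient(
                    eta_day, float(etp_daily[das_flight]), cap=config.ks_cap
                )
                ks_values.append(ks)
                flux_rows.append(
                    {
                        "plot_id": rec.plot_id, "variety": variety,
                        "treatment": treatment, "block": rec.block,
                        "das": das_flight,
                        "rn_c": fluxes.rn_c, "rn_s": fluxes.rn_s,
                        "g": fluxes.g, "h_c": fluxes.h_c, "h_s": fluxes.h_s,
                        "le_c": fluxes.le_c, "le_s": fluxes.le_s,
                        "converged": fluxes.converged,
                        "iterations": fluxes.iterations,
                        "eta_daily": eta_day, "ks": ks,
                    }
                )
            ks_points.append(
                KsPoint(das=int(das_flight), ks=float(np.mean(ks_values)))
            )

        ks_daily = interpolate_ks(
            ks_points, ph_obj.maturity_das, scheme=config.interpolation
        )
        eta_daily_arr, cum_eta = daily_eta_series(ks_daily, etp_daily)
        stages = stage_integrals(eta_daily_arr, ph_obj)

        series_rows.append(
            pd.DataFrame(
                {
                    "variety": variety,
                    "treatment": treatment,
                    "das": das_grid,
                    "lai": lai_daily,
                    "etp": etp_daily,
                    "ks": ks_daily,
                    "eta": eta_daily_arr,
                    "cum_eta": cum_eta,
                }
            )
        )

        perf = {
            "variety": variety,
            "treatment": treatment,
            "heading_das": ph_obj.heading_das,
            "maturity_das": ph_obj.maturity_das,
            "max_lai": float(lai_daily.max()),
            "eta_total": stages.eta_total,
            "eta_veg": stages.eta_veg,
            "eta_gf": stages.eta_gf,
        }
        if agronomy is not None:
            plots = agronomy[
                (agronomy["variety"] == variety)
                & (agronomy["treatment"] == treatment)
            ]
            if len(plots):
                # WP per plot, then averaged (not the ratio of means)
                wp = [
                    water_productivity(float(gy), stages.eta_total)
                    for gy in plots["GY"]
                ]
                perf.update(
                    {
                        "GY": float(plots["GY"].mean()),
                        "TKW": float(plots["TKW"].mean()),
                        "grain_number": float(plots["grain_number"].mean()),
                        "WP": float(np.mean(wp)),
                    }
                )
        perf_rows.append(perf)

    return PipelineResult(
        lai_model=lai_model,
        sigmoid_params=pd.DataFrame(sig_rows),
        fluxes=pd.DataFrame(flux_rows),
        et_series=pd.concat(series_rows, ignore_index=True),
        performance=pd.DataFrame(perf_rows),
    )
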