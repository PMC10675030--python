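import pytest

from aeroeta.evapotranspiration import Site, WeatherDaily
from aeroeta.pipeline import PipelineConfig, run_pipeline
from aeroeta.synthetic import TrialConfig, generate_trial


@pytest.fixture(scope="session")
def site() -> Site:
    return Site(latitude_deg=41.7, elevation_m=250.0, sowing_doy=343)


@pytest.fixture(scope="session")
def benchmark_day() -> WeatherDaily:
    """A mid-summer reference day with complete records."""
    return WeatherDaily(
        das=50, t_min=12.3, t_max=21.5, rh_mean=63.5,
        wind_2m=2.78, solar_rad=22.07,
    )


@pytest.fixture(scope="session")
def zero_noise_trial():
    """Small noise-free synthetic trial in energy-balance temperature mode."""
    config = TrialConfig(
        n_varieties=4, n_blocks=1, tc_mode="energy_balance", seed=5
    ).zero_noise()
    return generate_trial(config)


@pytest.fixture(scope="session")
def zero_noise_result(zero_noise_trial):
    trial = zero_noise_trial
    return run_pipeline(
        trial.snapshots,
        trial.weather,
        trial.phenology,
        agronomy=trial.agronomy,
        ground_truth_lai=trial.ground_truth_lai,
        config=PipelineConfig(site=trial.config.site, tseb=trial.config.tseb),
    )


@pytest.fixture(scope="session")
def noisy_trial():
    """Default-noise trial in the linear temperature mode."""
    return generate_trial(TrialConfig(n_varieties=6, n_blocks=2, seed=11))
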