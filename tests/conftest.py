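import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from loligosdm import GridSpec, NicheSpec, generate_env_stack, simulate_survey
from loligosdm.synthetic import GaussianResponse

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_stack():
    return generate_env_stack(GridSpec(), season="autumn", seed=1)


@pytest.fixture(scope="session")
def sbt_niche():
    """Gaussian niche on sea-bottom temperature: optimum 20 C, breadth 2 C."""
    return NicheSpec(responses={"sbt": GaussianResponse(optimum=20.0, breadth=2.0)})


@pytest.fixture(scope="session")
def survey_table(default_stack, sbt_niche):
    tbl = simulate_survey(default_stack, sbt_niche, n_stations=150, seed=7)
    tbl = tbl.copy()
    tbl["presence"] = (tbl["count"] > 0).astype(int)
    return tbl


@pytest.fixture(scope="session")
def occurrence_table(survey_table):
    return survey_table[["presence", "sst", "sbt", "sss", "sbs"]].reset_index(drop=True)


def random_survey(seed: int, n: int = 20) -> pd.DataFrame:
    """Small random survey table spanning all four seasons."""
    rng = np.random.default_rng(seed)
    seasons = rng.choice(["spring", "summer", "autumn", "winter"], size=n)
    count = rng.poisson(3, size=n)
    weight = np.where(count > 0, count * rng.lognormal(3.2, 0.6, size=n), 0.0)
    return pd.DataFrame({
        "station_id": np.arange(n),
        "lat": rng.uniform(26.5, 35.0, n),
        "lon": rng.uniform(120.0, 127.0, n),
        "season": seasons,
        "tow_duration": rng.choice([0.5, 1.0, 2.0], size=n),
        "count": count,
        "weight": weight,
        "sst": rng.uniform(8, 29, n),
        "sbt": rng.uniform(8, 27, n),
        "sss": rng.uniform(28, 35, n),
        "sbs": rng.uniform(28, 35, n),
        "depth": rng.uniform(10, 140, n),
    })
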