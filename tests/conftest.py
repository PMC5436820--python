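import datetime as dt

import numpy as np
import pandas as pd
import pytest

from lobstat import default_config, simulate_season
from lobstat.simulate import MonthSpec, SimConfig
from lobstat.types import SPECIES


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """A two-month, 12-boat season that simulates in milliseconds."""
    months = [
        MonthSpec(2015, 6, 30, False, 0.5, 15_000),
        MonthSpec(2015, 7, 31, True, 0.8, 20_000),
    ]
    mix = {
        m.key: {
            "P_homarus": 0.55,
            "P_longipes": 0.35,
            "P_ornatus": 0.05,
            "S_squammosus": 0.05,
        }
        for m in months
    }
    berried = {m.key: {sp: 0.3 for sp in SPECIES} for m in months}
    tl = {sp: (190.0, 30.0) for sp in SPECIES}
    cl = {sp: {"male": (0.3226, 0.0, 2.0), "female": (0.3226, 0.0, 2.0)}
          for sp in SPECIES}
    cfg = SimConfig(
        n_boats_main=10,
        n_boats_lodge=2,
        n_upstream_boats=0,
        months=months,
        hurdle_coefs_zero=(-0.3, 0.6, 0.03, 0.01),
        hurdle_coefs_count=(0.2, 0.3, 0.025, 0.005),
        species_mix_by_month=mix,
        berried_prob_by_month_species=berried,
        tl_distribution=tl,
        cl_from_tl=cl,
        weight_from_tl=(1.1e-7, 2.85),
        survey_days_per_month=10,
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@pytest.fixture(scope="session")
def default_season():
    """One full default season, shared across the suite (seed 5)."""
    cfg = default_config(seed=5)
    surveys, lobsters, truth = simulate_season(cfg)
    records = [r for s in surveys for r in s.records]
    return cfg, surveys, records, lobsters, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def nb_pots(rng, n, mean=22.0, sd=13.5):
    var = sd * sd
    k = mean * mean / (var - mean)
    return np.maximum(1, rng.negative_binomial(k, k / (k + mean), n)).astype(float)


def hurdle_frame(rng, n, p_open=0.5):
    ntz = (rng.random(n) < p_open).astype(float)
    pots = nb_pots(rng, n)
    return pd.DataFrame({"ntz_open": ntz, "pots": pots})
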