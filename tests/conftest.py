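import numpy as np
import pandas as pd
import pytest

from sheia import SimulationConfig, generate_cohort, generate_survival
from sheia.metrics import INTAKE_PREFIX
from sheia.tables import DEFAULT_FOOD_GROUPS, generate_reference_tables


@pytest.fixture(scope="session")
def ref_tables():
    return generate_reference_tables()


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimulationConfig(
        n_subjects=600, seed=11, beta_score=-0.15, exclusion_violation_rate=0.0
    )
    cohort = generate_cohort(cfg)
    survival = generate_survival(cohort, cfg)
    return cohort, survival, cfg


def random_intake_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Uncorrelated log-normal intakes over the default food groups."""
    data = {
        INTAKE_PREFIX + g: np.exp(rng.normal(np.log(80.0), 0.6, n))
        for g in DEFAULT_FOOD_GROUPS
    }
    return pd.DataFrame(data)


def random_profile_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random energy-adjusted-style nutrient profiles spanning the score range."""
    return pd.DataFrame(
        {
            "energy": np.full(n, 2000.0),
            "veg_fruit": rng.uniform(0, 1200, n),
            "seafood": rng.uniform(0, 120, n),
            "wholegrain": rng.uniform(0, 250, n),
            "fibre": rng.uniform(0, 80, n),
            "mufa_e": rng.uniform(0, 25, n),
            "pufa_e": rng.uniform(0, 15, n),
            "sfa_e": rng.uniform(0, 25, n),
            "added_sugar_e": rng.uniform(0, 25, n),
            "red_processed_meat": rng.uniform(0, 300, n),
        }
    )
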