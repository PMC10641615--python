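"""Synthetic FFQ-cohort generator.

Emulates the statistical structure of a Swedish health-screening cohort of
35-65-year-olds recruited 1990-2016: right-skewed, correlated food-group
intakes (log-normal margins, Gaussian copula), energy and nutrients derived
from the intakes through a composition table (so energy standardisation has a
real signal to remove), widespread energy under-reporting (roughly 45 % of
subjects with a food intake level below 1.2), and all-cause mortality with a
configurable log-hazard in the true diet-quality score, administratively
censored at the end of 2016.

Under-reporting multiplies the *reported* energy and intakes by a constant
factor; true values are kept alongside (``true_`` columns) so oracle checks
can compare against the generating truth.  A small configurable fraction of
records is corrupted to violate each cohort-exclusion rule, giving the
filtering stage something to catch.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .tables import DEFAULT_FOOD_GROUPS, generate_reference_tables

DAYS_PER_MONTH = 30.4375


class ConfigurationError(ValueError):
    pass


# Median reported intakes, g/day, before the sex multiplier.  Chosen so that
# derived energy and the food-intake-level distribution land in the realistic
# FFQ range (median FIL ~1.4-1.5 among plausible reporters).
DEFAULT_INTAKE_MEANS: dict[str, float] = {
    "vegetables": 140.0,
    "fruit": 150.0,
    "wholegrain_products": 100.0,
    "refined_grains": 140.0,
    "potatoes": 140.0,
    "dairy": 400.0,
    "red_processed_meat": 110.0,
    "poultry": 45.0,
    "seafood": 45.0,
    "eggs": 28.0,
    "sweets_sugar": 75.0,
    "added_fats": 35.0,
}

#: Log-scale standard deviations of the intakes.
DEFAULT_INTAKE_DISPERSIONS: dict[str, float] = {g: 0.45 for g in DEFAULT_FOOD_GROUPS}

# Sparse diet-pattern correlation structure on the log scale; unlisted pairs
# default to a weak common factor of 0.10.
_CORRELATION_OVERRIDES: dict[tuple[str, str], float] = {
    ("vegetables", "fruit"): 0.45,
    ("vegetables", "wholegrain_products"): 0.25,
    ("vegetables", "seafood"): 0.20,
    ("fruit", "wholegrain_products"): 0.20,
    ("red_processed_meat", "vegetables"): -0.25,
    ("red_processed_meat", "fruit"): -0.20,
    ("red_processed_meat", "potatoes"): 0.30,
    ("red_processed_meat", "added_fats"): 0.25,
    ("red_processed_meat", "refined_grains"): 0.20,
    ("sweets_sugar", "vegetables"): -0.20,
    ("sweets_sugar", "fruit"): -0.10,
    ("sweets_sugar", "refined_grains"): 0.25,
    ("red_processed_meat", "sweets_sugar"): 0.15,
    ("red_processed_meat", "seafood"): -0.10,
    ("red_processed_meat", "wholegrain_products"): -0.15,
}


def default_intake_correlations(food_groups=DEFAULT_FOOD_GROUPS) -> pd.DataFrame:
    k = len(food_groups)
    r = np.full((k, k), 0.10)
    np.fill_diagonal(r, 1.0)
    idx = {g: i for i, g in enumerate(food_groups)}
    for (a, b), v in _CORRELATION_OVERRIDES.items():
        if a in idx and b in idx:
            r[idx[a], idx[b]] = r[idx[b], idx[a]] = v
    return pd.DataFrame(r, index=list(food_groups), columns=list(food_groups))


#: Log-hazard coefficients for non-dietary covariates (numeric covariates are
#: centred before multiplying).  Categorical covariates map level -> log HR.
DEFAULT_BETA_COVARIATES: dict[str, object] = {
    "age": 0.090,   # per year
    "bmi": 0.020,   # per kg/m2
    "smoking": {"current": 0.50, "former": 0.15, "never": 0.0},
    "education": {"basic": 0.0, "high_school": -0.10, "university": -0.25},
    "physical_activity": {
        "inactive": 0.0,
        "moderately_inactive": -0.05,
        "moderately_active": -0.12,
        "active": -0.18,
    },
}

_CATEGORY_PROBS = {
    "education": (("basic", 0.35), ("high_school", 0.40), ("university", 0.25)),
    "physical_activity": (
        ("inactive", 0.20),
        ("moderately_inactive", 0.30),
        ("moderately_active", 0.30),
        ("active", 0.20),
    ),
    "smoking": (("current", 0.22), ("former", 0.28), ("never", 0.50)),
}


@dataclass
class SimulationConfig:
    n_subjects: int = 1000
    sex_ratio: float = 0.5  # fraction female
    recruitment_years: tuple[int, int] = (1990, 2016)
    age_range: tuple[int, int] = (35, 65)
    intake_means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_INTAKE_MEANS))
    intake_dispersions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTAKE_DISPERSIONS)
    )
    intake_correlations: pd.DataFrame | None = None
    sex_intake_multiplier: Mapping[str, float] = field(
        default_factory=lambda: {"female": 0.88, "male": 1.13}
    )
    underreport_prob: float = 0.45
    underreport_factor: float = 0.70
    beta_score: float = 0.0
    beta_covariates: Mapping[str, object] = field(
        default_factory=lambda: dict(DEFAULT_BETA_COVARIATES)
    )
    baseline_hazard: float = 3.0e-4  # events per person-month
    weibull_shape: float = 1.0  # 1.0 = exponential
    admin_censor_date: dt.date = dt.date(2016, 12, 31)
    exclusion_violation_rate: float = 0.002  # per criterion i-v
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ConfigurationError("sex_ratio must lie in [0, 1]")
        if not (0.0 <= self.underreport_prob <= 1.0):
            raise ConfigurationError("underreport_prob must lie in [0, 1]")
        if not (0.0 < self.underreport_factor <= 1.0):
            raise ConfigurationError("underreport_factor must lie in (0, 1]")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if self.weibull_shape <= 0:
            raise ConfigurationError("weibull_shape must be > 0")
        if any(d <= 0 for d in self.intake_dispersions.values()):
            raise ConfigurationError("all intake dispersions must be > 0")

    @property
    def food_groups(self) -> list[str]:
        return list(self.intake_means)

    def correlation_matrix(self) -> np.ndarray:
        groups = self.food_groups
        if self.intake_correlations is None:
            corr = default_intake_correlations(groups)
        else:
            corr = self.intake_correlations
        r = (
            corr.loc[groups, groups].to_numpy(dtype=float)
            if isinstance(corr, pd.DataFrame)
            else np.asarray(corr, dtype=float)
        )
        if not np.allclose(r, r.T):
            raise ConfigurationError("intake_correlations is not symmetric")
        try:
            np.linalg.cholesky(r)
        except np.linalg.LinAlgError as e:
            raise ConfigurationError(
                "intake_correlations is not positive definite"
            ) from e
        return r


def _rngs(seed: int, n_streams: int = 3) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n_streams)]


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw one cohort of FFQ records; deterministic under a fixed seed.

    Columns: identifiers, demographics, reported ``intake_<group>`` (g/day),
    the derived reported nutrient profile, data-quality fields, and hidden
    truth columns ``true_energy``, ``true_score``, ``underreporter_true``.
    """
    from . import index as index_mod
    from . import metrics as metrics_mod

    rng = _rngs(config.seed)[0]
    n = config.n_subjects
    groups = config.food_groups

    sex = np.where(rng.random(n) < config.sex_ratio, "female", "male")
    lo_a, hi_a = config.age_range
    age = rng.integers(lo_a, hi_a + 1, size=n)
    height = np.where(sex == "female", rng.normal(165.0, 6.0, n), rng.normal(178.0, 7.0, n))
    bmi = np.exp(rng.normal(np.log(25.5), 0.15, n))
    weight = bmi * (height / 100.0) ** 2

    y0, y1 = config.recruitment_years
    start = dt.date(y0, 1, 1).toordinal()
    end = dt.date(y1, 12, 31).toordinal()
    visit_ord = rng.integers(start, end + 1, size=n)
    visit_date = pd.to_datetime([dt.date.fromordinal(int(o)) for o in visit_ord])

    cats = {}
    for name, levels in _CATEGORY_PROBS.items():
        labels = [l for l, _ in levels]
        probs = [p for _, p in levels]
        cats[name] = rng.choice(labels, size=n, p=probs)

    # Correlated log-normal intakes (Gaussian copula = MVN on the log scale).
    r = config.correlation_matrix()
    sigma = np.array([config.intake_dispersions[g] for g in groups])
    cov = r * np.outer(sigma, sigma)
    mult = np.where(
        sex == "female",
        config.sex_intake_multiplier["female"],
        config.sex_intake_multiplier["male"],
    )
    mu = np.log([config.intake_means[g] for g in groups])
    z = rng.multivariate_normal(np.zeros(len(groups)), cov, size=n, method="cholesky")
    true_intakes = np.exp(mu + z) * mult[:, None]

    underreporter = rng.random(n) < config.underreport_prob
    factor = np.where(underreporter, config.underreport_factor, 1.0)
    reported_intakes = true_intakes * factor[:, None]

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(n)],
            "visit_date": visit_date,
            "sex": sex,
            "age": age.astype(float),
            "height": height,
            "weight": weight,
            "bmi": weight / (height / 100.0) ** 2,
            "education": cats["education"],
            "physical_activity": cats["physical_activity"],
            "smoking": cats["smoking"],
        }
    )
    for j, g in enumerate(groups):
        df[metrics_mod.INTAKE_PREFIX + g] = reported_intakes[:, j]

    composition, _ = generate_reference_tables(groups)
    profile = metrics_mod.nutrient_profile(df, composition)
    for c in profile.columns:
        df[c] = profile[c]

    # Hidden truth: energy and index score from the uncorrupted intakes.
    true_df = pd.DataFrame(
        {metrics_mod.INTAKE_PREFIX + g: true_intakes[:, j] for j, g in enumerate(groups)}
    )
    true_profile = metrics_mod.nutrient_profile(true_df, composition)
    true_adj = metrics_mod.energy_adjust(true_profile, sex)
    df["true_energy"] = true_profile["energy"].to_numpy()
    df["true_score"] = index_mod.total_score(true_adj, sex).to_numpy()
    df["underreporter_true"] = underreporter

    df["missing_item_fraction"] = rng.uniform(0.0, 0.05, n)
    df["portion_size_missing"] = False

    # Corrupt a small disjoint fraction per exclusion criterion i-v.
    rate = config.exclusion_violation_rate
    if rate > 0 and n >= 5:
        n_bad = max(1, int(round(rate * n)))
        bad = rng.choice(n, size=min(5 * n_bad, n), replace=False)
        chunks = np.array_split(bad, 5)
        df.loc[df.index[chunks[0]], "missing_item_fraction"] = rng.uniform(
            0.10, 0.5, len(chunks[0])
        )
        bad_h = df.index[chunks[1]]
        df.loc[bad_h, "height"] = rng.choice([120.0, 215.0], size=len(chunks[1]))
        df.loc[bad_h, "bmi"] = df.loc[bad_h, "weight"] / (df.loc[bad_h, "height"] / 100.0) ** 2
        bad_w = df.index[chunks[2]]
        df.loc[bad_w, "weight"] = 30.0
        df.loc[bad_w, "bmi"] = 30.0 / (df.loc[bad_w, "height"] / 100.0) ** 2
        df.loc[df.index[chunks[3]], "bmi"] = np.nan
        df.loc[df.index[chunks[4]], "age"] = rng.choice([30.0, 70.0], size=len(chunks[4]))

    return df


def _covariate_lp(records: pd.DataFrame, beta_covariates: Mapping[str, object]) -> np.ndarray:
    lp = np.zeros(len(records))
    for name, beta in beta_covariates.items():
        if name not in records.columns:
            raise ConfigurationError(f"beta_covariates names absent covariate {name!r}")
        col = records[name]
        if isinstance(beta, Mapping):
            unknown = set(col.dropna().unique()) - set(beta)
            if unknown:
                raise ConfigurationError(
                    f"covariate {name!r} has level(s) {sorted(unknown)} without a coefficient"
                )
            lp += col.map(beta).fillna(0.0).to_numpy(dtype=float)
        else:
            x = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            x = np.nan_to_num(x, nan=np.nanmean(x))
            lp += float(beta) * (x - x.mean())
    return lp


def generate_survival(records: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Event times under h(t) = h0 k t^(k-1) exp(beta'x + beta_score * true score).

    Default shape k = 1 (exponential).  Follow-up is the smaller of the event
    time and the months from visit_date to the administrative censoring date;
    the event flag marks deaths inside the study window.  Follow-up is always
    > 0 (administrative intervals are floored at one day).
    """
    rng = _rngs(config.seed)[1]
    n = len(records)
    visit = pd.to_datetime(records["visit_date"])
    censor = pd.Timestamp(config.admin_censor_date)
    if (visit > censor).any():
        raise ConfigurationError("visit_date after admin_censor_date")

    lp = _covariate_lp(records, config.beta_covariates)
    score = records["true_score"].to_numpy(dtype=float)
    lp = lp + config.beta_score * (score - score.mean())

    k = config.weibull_shape
    e = rng.exponential(1.0, size=n)
    t_event = (e / (config.baseline_hazard * np.exp(lp))) ** (1.0 / k)

    admin_months = np.maximum((censor - visit).dt.days.to_numpy() / DAYS_PER_MONTH,
                              1.0 / DAYS_PER_MONTH)
    follow_up = np.minimum(t_event, admin_months)
    event = t_event <= admin_months
    return pd.DataFrame(
        {
            "subject_id": records["subject_id"].to_numpy(),
            "follow_up_months": follow_up,
            "event": event.astype(int),
        },
        index=records.index,
    )
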