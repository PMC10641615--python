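"""Cohort exclusion filters and the one-observation-per-subject rule.

Six exclusion criteria are applied, mirroring standard FFQ-cohort cleaning:

i.   incomplete food reporting (>= 10 % missing intake items and/or missing
     portion-size recording);
ii.  height outside 130-210 cm;
iii. body weight below 35 kg;
iv.  BMI below 15 kg/m2 or missing;
v.   age outside 35-65 years;
vi.  food intake level (FIL = reported energy / predicted BMR) outside the
     1st-99th percentiles, computed per sex on the records surviving i-v.

Every excluded record is logged with the criteria it triggered.  A FIL below
1.2 additionally flags probable energy under-reporting; the flag is
descriptive and never excludes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KCAL_PER_MJ = 239.006

# Schofield predictive BMR equations (weight only), MJ/day, by sex and age
# band.  Bands: 18-29, 30-59, >= 60 years.
SCHOFIELD_MJ = {
    "female": [(30, 0.062, 2.036), (60, 0.034, 3.538), (np.inf, 0.038, 2.755)],
    "male": [(30, 0.063, 2.896), (60, 0.048, 3.653), (np.inf, 0.049, 2.459)],
}

UNDERREPORT_FIL_CUTOFF = 1.2

CRITERIA = ("i", "ii", "iii", "iv", "v", "vi")
CRITERIA_LABELS = {
    "i": "incomplete food reporting",
    "ii": "height outside range",
    "iii": "weight below minimum",
    "iv": "BMI below minimum or missing",
    "v": "age outside range",
    "vi": "food intake level outside percentile bounds",
}


@dataclass
class ExclusionConfig:
    max_missing_item_fraction: float = 0.10
    height_range_cm: tuple[float, float] = (130.0, 210.0)
    min_weight_kg: float = 35.0
    min_bmi: float = 15.0
    age_range_years: tuple[float, float] = (35.0, 65.0)
    fil_percentile_bounds: tuple[float, float] = (1.0, 99.0)
    fil_per_sex: bool = True
    # Precomputed FIL bounds ({sex: (lo, hi)} or {"all": (lo, hi)}); when set
    # they are used as-is instead of re-estimating percentiles, which makes
    # repeated application of the filter exactly idempotent.
    fil_bounds: dict[str, tuple[float, float]] | None = None
    bmr_equation: str = "schofield"

    def __post_init__(self) -> None:
        lo, hi = self.fil_percentile_bounds
        if not (0 < lo < hi < 100):
            raise ValueError("FIL percentile bounds must satisfy 0 < lo < hi < 100")
        for pair in (self.height_range_cm, self.age_range_years):
            if pair[0] >= pair[1]:
                raise ValueError(f"range bounds must be ordered, got {pair}")


@dataclass
class ExclusionLog:
    """Audit trail of one filtering pass."""

    n_before: int
    n_after: int
    per_criterion: dict[str, int]
    per_record: pd.DataFrame  # columns: subject_id, criteria (semicolon-joined)
    fil_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return self.n_before - self.n_after

    def summary(self) -> str:
        lines = [f"records in: {self.n_before}"]
        for c in CRITERIA:
            lines.append(
                f"  criterion {c} ({CRITERIA_LABELS[c]}): {self.per_criterion.get(c, 0)} flagged"
            )
        lines.append(f"records excluded: {self.n_excluded}")
        lines.append(f"records retained: {self.n_after}")
        return "\n".join(lines)


def schofield_bmr_kcal(sex, age, weight) -> np.ndarray:
    """Predicted basal metabolic rate, kcal/day (Schofield, weight only)."""
    sex = np.asarray(sex)
    age = np.asarray(age, dtype=float)
    weight = np.asarray(weight, dtype=float)
    out = np.full(sex.shape, np.nan)
    for s, bands in SCHOFIELD_MJ.items():
        lo_age = -np.inf
        for hi_age, slope, intercept in bands:
            m = (sex == s) & (age >= lo_age) & (age < hi_age)
            out[m] = (slope * weight[m] + intercept) * KCAL_PER_MJ
            lo_age = hi_age
    return out


def food_intake_level(df: pd.DataFrame, bmr_equation: str = "schofield") -> pd.Series:
    """FIL = reported energy intake / predicted BMR (dimensionless).

    NaN where weight, age or energy is missing (record unevaluable for the
    FIL criterion; it is not excluded on that account).
    """
    if bmr_equation != "schofield":
        raise ValueError(f"unknown BMR equation {bmr_equation!r}")
    bmr = schofield_bmr_kcal(df["sex"], df["age"], df["weight"])
    with np.errstate(invalid="ignore", divide="ignore"):
        fil = df["energy"].to_numpy(dtype=float) / bmr
    return pd.Series(fil, index=df.index, name="fil")


def apply_exclusions(
    df: pd.DataFrame, config: ExclusionConfig | None = None
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply criteria i-vi; return (retained records, audit log).

    The retained frame gains ``fil`` and ``underreporter`` (FIL < 1.2)
    columns.  Empty input yields an empty output and a zero-count log.
    """
    config = config or ExclusionConfig()
    n = len(df)
    flags: dict[str, pd.Series] = {}
    false = pd.Series(False, index=df.index)

    intake_cols = [c for c in df.columns if c.startswith("intake_")]
    missing_frac = pd.to_numeric(df.get("missing_item_fraction", false * 0.0), errors="coerce")
    portion_missing = df.get("portion_size_missing", false).fillna(False).astype(bool)
    intake_missing = (
        df[intake_cols].isna().any(axis=1) if intake_cols else false
    )
    flags["i"] = (
        (missing_frac >= config.max_missing_item_fraction).fillna(False)
        | portion_missing
        | intake_missing
    )

    height = pd.to_numeric(df.get("height", pd.Series(np.nan, index=df.index)), errors="coerce")
    flags["ii"] = ((height < config.height_range_cm[0]) | (height > config.height_range_cm[1])).fillna(False)

    weight = pd.to_numeric(df.get("weight", pd.Series(np.nan, index=df.index)), errors="coerce")
    flags["iii"] = (weight < config.min_weight_kg).fillna(False)

    bmi = pd.to_numeric(df.get("bmi", pd.Series(np.nan, index=df.index)), errors="coerce")
    flags["iv"] = (bmi < config.min_bmi) | bmi.isna()

    age = pd.to_numeric(df.get("age", pd.Series(np.nan, index=df.index)), errors="coerce")
    lo_a, hi_a = config.age_range_years
    flags["v"] = ((age < lo_a) | (age > hi_a)).fillna(False)

    # FIL percentile cut on survivors of i-v.
    fil = food_intake_level(df, config.bmr_equation) if n else pd.Series(dtype=float)
    survivors_iv = ~(flags["i"] | flags["ii"] | flags["iii"] | flags["iv"] | flags["v"])
    flags["vi"] = false.copy()
    bounds: dict[str, tuple[float, float]] = {}
    if n:
        lo_q, hi_q = config.fil_percentile_bounds
        strata = df["sex"].astype(str) if (config.fil_per_sex and "sex" in df) else pd.Series("all", index=df.index)
        for s in strata.unique():
            in_stratum = strata == s
            base = fil[in_stratum & survivors_iv].dropna()
            if config.fil_bounds is not None and s in config.fil_bounds:
                lo, hi = config.fil_bounds[s]
            elif len(base):
                lo = float(np.percentile(base, lo_q))
                hi = float(np.percentile(base, hi_q))
            else:
                continue
            bounds[s] = (lo, hi)
            flags["vi"] |= in_stratum & ((fil < lo) | (fil > hi)).fillna(False)

    any_flag = false.copy()
    for c in CRITERIA:
        any_flag |= flags[c]
    retained = df.loc[~any_flag].copy()
    if n:
        retained["fil"] = fil.loc[retained.index]
        retained["underreporter"] = retained["fil"] < UNDERREPORT_FIL_CUTOFF

    excluded_idx = df.index[any_flag]
    crit_strings = [
        ";".join(c for c in CRITERIA if bool(flags[c].loc[i])) for i in excluded_idx
    ]
    per_record = pd.DataFrame(
        {
            "subject_id": df.loc[excluded_idx, "subject_id"].to_numpy()
            if "subject_id" in df
            else excluded_idx.to_numpy(),
            "criteria": crit_strings,
        }
    )
    log = ExclusionLog(
        n_before=n,
        n_after=len(retained),
        per_criterion={c: int(flags[c].sum()) for c in CRITERIA},
        per_record=per_record,
        fil_bounds=bounds,
    )
    return retained, log


def select_one_observation(df: pd.DataFrame, keep: str = "earliest") -> pd.DataFrame:
    """Keep one record per subject_id.

    ``keep='earliest'`` (default) retains the earliest visit_date — baseline
    semantics; ``'latest'`` the most recent.  Same-date ties are broken by the
    first-read record (lowest input ordinal), which makes the result
    deterministic across runs.
    """
    if keep not in ("earliest", "latest"):
        raise ValueError(f"keep must be 'earliest' or 'latest', got {keep!r}")
    if df.empty or "subject_id" not in df.columns:
        return df.copy()
    work = df.reset_index(drop=True)
    order = work["visit_date"] if "visit_date" in work else pd.Series(0, index=work.index)
    asc = keep == "earliest"
    pos = (
        work.assign(_ord=np.arange(len(work)), _vd=pd.to_datetime(order))
        .sort_values(["_vd", "_ord"], ascending=[asc, True], kind="stable")
        .drop_duplicates("subject_id", keep="first")["_ord"]
        .sort_values()
    )
    return work.loc[pos].drop(columns=[], errors="ignore").reset_index(drop=True)
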