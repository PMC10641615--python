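"""End-to-end orchestration: simulate/load -> filter -> metrics -> score ->
stratify -> survival -> rank tests -> sensitivity, with delimited-text
outputs and a reproducibility manifest.

Stage outputs mirror the standard reporting of a diet-quality mortality
study: a baseline-characteristics table split by case status, per-quintile
hazard ratios (basic and fully adjusted Cox models), per-quintile GHGE
medians with omnibus/pairwise/trend tests, and leave-one-component-out
sensitivity tables for both the survival and the GHGE contrasts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cox as cox_mod
from . import filters as filters_mod
from . import index as index_mod
from . import metrics as metrics_mod
from . import ranktests as rank_mod
from . import strata as strata_mod
from .simulate import SimulationConfig, generate_cohort, generate_survival
from .tables import generate_reference_tables

log = logging.getLogger("sheia")


@dataclasses.dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    cohort_path: str | None = None
    survival_path: str | None = None
    simulation: SimulationConfig | None = None
    exclusion: filters_mod.ExclusionConfig | None = None
    ties: str = "breslow"
    run_sensitivity: bool = True

    def __post_init__(self) -> None:
        has_path = self.cohort_path is not None
        has_sim = self.simulation is not None
        if has_path == has_sim:
            raise ValueError("provide exactly one of cohort_path or simulation config")


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (pd.DataFrame, pd.Series)):
            return o.to_dict()
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def prepare_cohort(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Stages simulate/load -> filter -> metrics -> score -> stratify.

    Returns the analysis-ready cohort (scores, quintiles, GHGE, survival
    columns), the exclusion audit, and stage record counts.
    """
    counts: dict[str, int] = {}
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        cohort = generate_cohort(sim)
        survival = generate_survival(cohort, sim)
        groups = sim.food_groups
    else:
        cohort = pd.read_csv(config.cohort_path, parse_dates=["visit_date"])
        survival = pd.read_csv(config.survival_path) if config.survival_path else None
        groups = metrics_mod.food_groups_of(cohort)
    counts["input"] = len(cohort)

    cohort = filters_mod.select_one_observation(cohort)
    counts["one_per_subject"] = len(cohort)
    cohort, exclusion_log = filters_mod.apply_exclusions(cohort, config.exclusion)
    counts["after_exclusions"] = len(cohort)
    log.info("exclusions:\n%s", exclusion_log.summary())

    composition, emission = generate_reference_tables(groups)
    profile = metrics_mod.nutrient_profile(cohort, composition)
    adjusted = metrics_mod.energy_adjust(profile, cohort["sex"])
    scores = index_mod.score_profiles(adjusted, cohort["sex"])
    ghge = metrics_mod.diet_ghge(
        cohort, emission, scale_factor=adjusted["scale_factor"].to_numpy()
    )
    cohort = pd.concat(
        [cohort.drop(columns=[c for c in adjusted.columns if c in cohort], errors="ignore"),
         adjusted, scores, ghge],
        axis=1,
    )
    cohort["age_group"] = strata_mod.age_group(cohort["age"]).to_numpy()
    cohort["quintile"] = strata_mod.assign_quintiles(cohort)
    cohort["year"] = pd.to_datetime(cohort["visit_date"]).dt.year

    if survival is not None:
        surv = survival.set_index("subject_id")
        cohort = cohort.join(
            surv[["follow_up_months", "event"]], on="subject_id", how="inner"
        )
    counts["analysis"] = len(cohort)
    return cohort, exclusion_log.per_record, counts


def baseline_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics per sex x case status.

    Mean/sd for approximately normal variables (age, BMI), median and
    quartiles for follow-up, category percentages for education, smoking and
    physical activity.  Percentages are raw (not age-standardised).
    """
    rows = []
    for (sex, case), sub in cohort.groupby(["sex", "event"]):
        row: dict[str, object] = {
            "sex": sex,
            "status": "case" if case else "non-case",
            "n": len(sub),
        }
        for var in ("age", "bmi", "sheia15", "ghge_adjusted"):
            if var in sub:
                row[f"{var}_mean"] = sub[var].mean()
                row[f"{var}_sd"] = sub[var].std(ddof=1)
        fu = sub["follow_up_months"]
        row["follow_up_median"] = fu.median()
        row["follow_up_q1"] = fu.quantile(0.25)
        row["follow_up_q3"] = fu.quantile(0.75)
        for var in ("education", "smoking", "physical_activity"):
            pct = sub[var].value_counts(normalize=True) * 100.0
            for level, v in pct.items():
                row[f"{var}_{level}_pct"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def ghge_quintile_table(cohort: pd.DataFrame, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sex, per-quintile GHGE medians with omnibus, pairwise and trend tests."""
    med_rows, test_rows = [], []
    for sex, sub in cohort.groupby("sex"):
        groups = [
            sub.loc[sub["quintile"] == q, "ghge_adjusted"].to_numpy()
            for q in sorted(sub["quintile"].unique())
        ]
        for qi, g in enumerate(groups, start=1):
            med_rows.append(
                {
                    "sex": sex, "quintile": qi, "n": len(g),
                    "ghge_median": float(np.median(g)),
                    "ghge_q1": float(np.percentile(g, 25)),
                    "ghge_q3": float(np.percentile(g, 75)),
                }
            )
        kw = rank_mod.kruskal_wallis(groups)
        jt = rank_mod.jonckheere_terpstra(groups)
        test_rows.append(
            {"sex": sex, "test": "kruskal-wallis", "statistic": kw.statistic, "p": kw.p_value}
        )
        test_rows.append(
            {"sex": sex, "test": "jonckheere-terpstra", "statistic": jt.statistic,
             "p": jt.p_value, "p_one_sided": jt.p_one_sided}
        )
        for r in rank_mod.dunn_posthoc(groups):
            test_rows.append(
                {"sex": sex, "test": r.method, "statistic": r.statistic, "p": r.p_value}
            )
    return pd.DataFrame(med_rows), pd.DataFrame(test_rows)


def sensitivity_tables(
    cohort: pd.DataFrame, ties: str = "breslow"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-component-out sensitivity analyses.

    For the full index and each of the nine reduced indices, per sex: the
    adjusted Cox HR per unit of the continuous score, and the Mann-Whitney U
    comparison of GHGE between quintiles 1 and 5 of that (re-ranked) score.
    """
    specs = index_mod.default_components()
    variants: list[str | None] = [None] + [s.name for s in specs]
    cox_rows, mwu_rows = [], []
    adjusted_cols = [c for c in ("energy", *metrics_mod.GRAM_FIELDS, *metrics_mod.EPCT_FIELDS)
                     if c in cohort.columns]
    profile = cohort[adjusted_cols]
    for excluded in variants:
        scores = index_mod.score_profiles(
            profile, cohort["sex"], specs, exclude=excluded
        )
        work = cohort.copy()
        work["loo_score"] = scores[index_mod.SCORE_COLUMN]
        work["loo_quintile"] = strata_mod.assign_quintiles(work, score_col="loo_score")
        label = excluded or "full_index"
        for sex, sub in work.groupby("sex"):
            r = cox_mod.continuous_score_hr(sub, score_col="loo_score", ties=ties)
            cox_rows.append(
                {"sex": sex, "excluded": label, "hr_per_unit": r["hr"],
                 "ci_low": r["ci_low"], "ci_high": r["ci_high"], "p": r["p"]}
            )
            q1 = sub.loc[sub["loo_quintile"] == 1, "ghge_adjusted"].to_numpy()
            q5 = sub.loc[sub["loo_quintile"] == 5, "ghge_adjusted"].to_numpy()
            m = rank_mod.mann_whitney_u(q1, q5)
            mwu_rows.append(
                {"sex": sex, "excluded": label,
                 "q1_median": float(np.median(q1)), "q5_median": float(np.median(q5)),
                 "median_gap": float(np.median(q1) - np.median(q5)),
                 "u": m.statistic, "p": m.p_value}
            )
    return pd.DataFrame(cox_rows), pd.DataFrame(mwu_rows)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage, write delimited-text tables + a JSON manifest.

    Deterministic under a fixed seed: the same config writes byte-identical
    tables.  Returns the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, exclusion_audit, counts = prepare_cohort(config)
    if "follow_up_months" not in cohort.columns:
        raise ValueError("no survival outcome available (stage: survival)")

    float_fmt = "%.10g"
    cohort.to_csv(out / "cohort_analysis.csv", index=False, float_format=float_fmt)
    exclusion_audit.to_csv(out / "exclusion_audit.csv", index=False)

    baseline = baseline_table(cohort)
    baseline.to_csv(out / "table_baseline.csv", index=False, float_format=float_fmt)

    hr_table = cox_mod.quintile_hazard_table(cohort, ties=config.ties)
    hr_table.to_csv(out / "table_quintile_hr.csv", index=False, float_format=float_fmt)

    med_table, test_table = ghge_quintile_table(cohort, seed=config.seed)
    med_table.to_csv(out / "table_ghge_medians.csv", index=False, float_format=float_fmt)
    test_table.to_csv(out / "table_ghge_tests.csv", index=False, float_format=float_fmt)

    if config.run_sensitivity:
        loo_cox, loo_mwu = sensitivity_tables(cohort, ties=config.ties)
        loo_cox.to_csv(out / "table_loo_cox.csv", index=False, float_format=float_fmt)
        loo_mwu.to_csv(out / "table_loo_mwu.csv", index=False, float_format=float_fmt)

    manifest = {
        "package": "sheia",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "counts": counts,
        "ties": config.ties,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
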