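"""Nutrient profiles, energy standardisation and dietary greenhouse-gas totals.

A cohort table stores food-group intakes in ``intake_<group>`` columns
(g/day).  From those and a composition table this module derives the nutrient
profile the diet index consumes, rescales it to the sex-specific reference
energy (2000 kcal/day for women, 2500 for men), and computes the diet's
greenhouse-gas emissions (kg CO2e/day, farm to industry gate), energy-adjusted
with the same scale factor.

Energy adjustment makes every downstream quantity invariant to a uniform
multiplicative reporting bias: if a subject under-reports all foods by a
constant factor, the adjusted profile, the diet-quality score and the adjusted
GHGE are unchanged.  That is the point of standardising to a fixed energy.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .tables import COMPOSITION_COLUMNS, validate_composition_table, validate_emission_table

#: Sex-specific reference energies, kcal/day.
REFERENCE_ENERGY = {"female": 2000.0, "male": 2500.0}

#: Atwater-style energy conversion factors, kcal per g.
KCAL_PER_G = {"fat": 9.0, "carbohydrate": 4.0, "protein": 4.0, "alcohol": 7.0}

INTAKE_PREFIX = "intake_"

#: Gram-denominated profile fields (rescaled by energy adjustment).
GRAM_FIELDS = ("fibre", "veg_fruit", "wholegrain", "seafood", "red_processed_meat")
#: Percent-of-energy profile fields (invariant under energy adjustment).
EPCT_FIELDS = ("mufa_e", "pufa_e", "sfa_e", "added_sugar_e")


def intake_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith(INTAKE_PREFIX)]


def food_groups_of(df: pd.DataFrame) -> list[str]:
    return [c[len(INTAKE_PREFIX):] for c in intake_columns(df)]


def _intake_matrix(df: pd.DataFrame, composition: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    groups = food_groups_of(df)
    missing = [g for g in groups if g not in composition.index]
    if missing:
        raise KeyError(f"food group(s) missing from composition table: {missing}")
    mat = df[[INTAKE_PREFIX + g for g in groups]].to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("negative food-group intake")
    return mat, groups

# Food groups whose intake counts toward each gram-based index component.
_COMPONENT_GROUPS = {
    "veg_fruit": ("vegetables", "fruit"),
    "seafood": ("seafood",),
    "red_processed_meat": ("red_processed_meat",),
}


def nutrient_profile(df: pd.DataFrame, composition: pd.DataFrame) -> pd.DataFrame:
    """Derive the nutrient profile of each diet from food-group intakes.

    Each nutrient is sum over food groups of intake(g)/100 x per-100-g amount.
    E% fields use 9 kcal/g for fatty acids and 4 kcal/g for added sugar; for a
    zero-energy diet every E% is defined as 0 (with a warning).

    Returns a DataFrame aligned with ``df`` holding energy (kcal/day), gram
    nutrients (g/day) and E% fields.
    """
    validate_composition_table(composition)
    mat, groups = _intake_matrix(df, composition)
    comp = composition.loc[groups, list(COMPOSITION_COLUMNS)].to_numpy(dtype=float)
    per100 = mat / 100.0
    totals = per100 @ comp  # columns follow COMPOSITION_COLUMNS
    out = pd.DataFrame(index=df.index)
    energy = totals[:, 0]
    out["energy"] = energy
    out["fibre"] = totals[:, 1]
    mufa_g, pufa_g, sfa_g, sugar_g = totals[:, 2], totals[:, 3], totals[:, 4], totals[:, 5]
    out["wholegrain"] = totals[:, 6]
    for comp_name, member_groups in _COMPONENT_GROUPS.items():
        cols = [INTAKE_PREFIX + g for g in member_groups if INTAKE_PREFIX + g in df.columns]
        out[comp_name] = df[cols].sum(axis=1) if cols else 0.0
    zero = energy <= 0
    if zero.any():
        warnings.warn("zero-energy diet(s): E% fields set to 0", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.where(zero, np.nan, energy)
        out["mufa_e"] = np.where(zero, 0.0, 100.0 * mufa_g * KCAL_PER_G["fat"] / denom)
        out["pufa_e"] = np.where(zero, 0.0, 100.0 * pufa_g * KCAL_PER_G["fat"] / denom)
        out["sfa_e"] = np.where(zero, 0.0, 100.0 * sfa_g * KCAL_PER_G["fat"] / denom)
        out["added_sugar_e"] = np.where(
            zero, 0.0, 100.0 * sugar_g * KCAL_PER_G["carbohydrate"] / denom
        )
    return out


def reference_energy(sex: pd.Series | np.ndarray) -> np.ndarray:
    """Map 'female'/'male' to the 2000/2500 kcal reference."""
    sex = np.asarray(sex)
    unknown = set(np.unique(sex)) - set(REFERENCE_ENERGY)
    if unknown:
        raise ValueError(f"unknown sex value(s): {sorted(unknown)}")
    return np.where(sex == "female", REFERENCE_ENERGY["female"], REFERENCE_ENERGY["male"])


def energy_adjust(profile: pd.DataFrame, sex: pd.Series | np.ndarray) -> pd.DataFrame:
    """Rescale gram-based fields so total energy equals the sex reference.

    scale_factor = reference_energy / reported energy; E% fields are ratios
    and pass through unchanged.  Zero reported energy is an error (the scaling
    is undefined).
    """
    energy = profile["energy"].to_numpy(dtype=float)
    if (energy <= 0).any():
        n_bad = int((energy <= 0).sum())
        raise ValueError(f"energy adjustment undefined for {n_bad} record(s) with energy <= 0")
    ref = reference_energy(sex)
    scale = ref / energy
    out = profile.copy()
    for f in GRAM_FIELDS:
        if f in out.columns:
            out[f] = out[f].to_numpy(dtype=float) * scale
    out["energy"] = ref
    out["reference_energy"] = ref
    out["scale_factor"] = scale
    return out


def diet_ghge(
    df: pd.DataFrame,
    emission_factors: pd.DataFrame,
    sex: pd.Series | np.ndarray | None = None,
    scale_factor: np.ndarray | None = None,
) -> pd.DataFrame:
    """Raw and energy-adjusted dietary greenhouse-gas emissions.

    raw_ghge = sum of intake (kg/day) x factor (kg CO2e per kg edible food).
    adjusted_ghge multiplies by the same scale factor used for nutrient
    energy adjustment; pass either ``scale_factor`` directly or ``sex``
    together with an ``energy`` column on ``df``.
    """
    groups = food_groups_of(df)
    validate_emission_table(emission_factors, groups)
    mat = df[[INTAKE_PREFIX + g for g in groups]].to_numpy(dtype=float)
    factors = emission_factors.loc[groups, "kgco2e_per_kg"].to_numpy(dtype=float)
    raw = (mat / 1000.0) @ factors  # g/day -> kg/day
    out = pd.DataFrame({"ghge_raw": raw}, index=df.index)
    if scale_factor is None:
        if sex is None:
            raise ValueError("provide sex (with an energy column) or scale_factor")
        if "energy" not in df.columns:
            raise ValueError("df must carry an 'energy' column to derive the scale factor")
        energy = df["energy"].to_numpy(dtype=float)
        if (energy <= 0).any():
            raise ValueError("energy must be > 0 to energy-adjust GHGE")
        scale_factor = reference_energy(sex) / energy
    out["ghge_adjusted"] = raw * np.asarray(scale_factor, dtype=float)
    out.attrs["system_boundary"] = "farm to industry gate"
    return out


def single_profile(intakes: Mapping[str, float], composition: pd.DataFrame) -> pd.Series:
    """Nutrient profile of one diet given a food-group -> g/day mapping."""
    df = pd.DataFrame({INTAKE_PREFIX + g: [v] for g, v in intakes.items()})
    return nutrient_profile(df, composition).iloc[0]
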