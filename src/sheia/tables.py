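"""Reference tables: food-group composition and emission factors.

The pipeline works at food-group resolution.  A composition table maps each
food group to its per-100-g energy and nutrient content; an emission-factor
table maps each group to kg CO2-equivalents per kg edible (prepared) food,
system boundary farm to industry gate.  Real national databases are not
redistributable, so :func:`generate_reference_tables` builds synthetic tables
with the qualitative structure that matters for the analysis: ruminant meat
is by far the most emission-intensive group, plant groups are cheap, and
energy densities span the realistic range.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

#: Food groups the default simulated FFQ aggregates to.
DEFAULT_FOOD_GROUPS: tuple[str, ...] = (
    "vegetables",
    "fruit",
    "wholegrain_products",
    "refined_grains",
    "potatoes",
    "dairy",
    "red_processed_meat",
    "poultry",
    "seafood",
    "eggs",
    "sweets_sugar",
    "added_fats",
)

#: Nutrient columns of a composition table, amounts per 100 g edible food.
COMPOSITION_COLUMNS: tuple[str, ...] = (
    "energy_kcal",      # kcal / 100 g
    "fibre_g",          # g / 100 g
    "mufa_g",           # g / 100 g
    "pufa_g",           # g / 100 g
    "sfa_g",            # g / 100 g
    "added_sugar_g",    # g / 100 g
    "wholegrain_g",     # whole-grain content, g / 100 g
)

# Synthetic per-100-g composition, loosely shaped on Nordic food-table
# magnitudes (not a reproduction of any database).
_DEFAULT_COMPOSITION: dict[str, tuple[float, ...]] = {
    #                      kcal  fibre mufa  pufa  sfa  sugar wholegrain
    "vegetables":         (35.0, 2.5,  0.1,  0.1,  0.0,  0.0,  0.0),
    "fruit":              (55.0, 2.0,  0.0,  0.0,  0.0,  0.0,  0.0),
    "wholegrain_products": (250.0, 8.0, 0.8,  0.8,  0.4,  1.0, 50.0),
    "refined_grains":     (270.0, 3.0,  0.8,  0.8,  0.5,  2.0,  0.0),
    "potatoes":           (80.0, 1.8,  0.0,  0.1,  0.0,  0.0,  0.0),
    "dairy":              (60.0, 0.0,  1.0,  0.1,  2.2,  0.5,  0.0),
    "red_processed_meat": (230.0, 0.0,  6.0,  1.0,  5.0,  0.0,  0.0),
    "poultry":            (150.0, 0.0,  2.5,  1.5,  1.5,  0.0,  0.0),
    "seafood":            (130.0, 0.0,  2.0,  2.0,  0.8,  0.0,  0.0),
    "eggs":               (140.0, 0.0,  4.0,  1.5,  3.0,  0.0,  0.0),
    "sweets_sugar":       (400.0, 0.5,  3.0,  0.5,  5.0, 55.0,  0.0),
    "added_fats":         (720.0, 0.0, 35.0, 12.0, 30.0,  0.0,  0.0),
}

# Synthetic emission factors, kg CO2e per kg edible food, farm to industry
# gate.  Ruminant/processed meat dominates; plant groups are <= 1.
_DEFAULT_EMISSION_FACTORS: dict[str, float] = {
    "vegetables": 0.8,
    "fruit": 0.6,
    "wholegrain_products": 0.8,
    "refined_grains": 0.8,
    "potatoes": 0.3,
    "dairy": 1.4,
    "red_processed_meat": 25.0,
    "poultry": 3.0,
    "seafood": 4.0,
    "eggs": 2.0,
    "sweets_sugar": 2.0,
    "added_fats": 3.5,
}

SYSTEM_BOUNDARY = "farm to industry gate"


def default_composition_table(food_groups: Sequence[str] = DEFAULT_FOOD_GROUPS) -> pd.DataFrame:
    """Composition table (index = food group, columns = COMPOSITION_COLUMNS)."""
    rows = {}
    for g in food_groups:
        if g not in _DEFAULT_COMPOSITION:
            raise KeyError(f"no default composition for food group {g!r}")
        rows[g] = _DEFAULT_COMPOSITION[g]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(COMPOSITION_COLUMNS))
    df.index.name = "food_group"
    return df


def default_emission_table(food_groups: Sequence[str] = DEFAULT_FOOD_GROUPS) -> pd.DataFrame:
    """Emission-factor table (index = food group, column kgco2e_per_kg)."""
    df = pd.DataFrame(
        {"kgco2e_per_kg": [_DEFAULT_EMISSION_FACTORS[g] for g in food_groups]},
        index=pd.Index(food_groups, name="food_group"),
    )
    return df


def generate_reference_tables(
    food_groups: Sequence[str] = DEFAULT_FOOD_GROUPS,
    emission_overrides: Mapping[str, float] | None = None,
    composition_overrides: Mapping[str, Mapping[str, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build (composition, emission) tables for the given food groups.

    ``emission_overrides`` replaces individual factors; ``composition_overrides``
    maps food group -> {column: value}.  Duplicate food-group names are an
    error, as are overrides for unknown groups.
    """
    groups = list(food_groups)
    if len(set(groups)) != len(groups):
        dupes = sorted({g for g in groups if groups.count(g) > 1})
        raise ValueError(f"duplicate food-group names: {dupes}")
    comp = default_composition_table(groups)
    ef = default_emission_table(groups)
    if emission_overrides:
        unknown = set(emission_overrides) - set(groups)
        if unknown:
            raise KeyError(f"emission override for unknown food group(s): {sorted(unknown)}")
        for g, v in emission_overrides.items():
            if v < 0:
                raise ValueError(f"emission factor for {g!r} must be >= 0, got {v}")
            ef.loc[g, "kgco2e_per_kg"] = float(v)
    if composition_overrides:
        unknown = set(composition_overrides) - set(groups)
        if unknown:
            raise KeyError(f"composition override for unknown food group(s): {sorted(unknown)}")
        for g, cols in composition_overrides.items():
            for c, v in cols.items():
                if c not in COMPOSITION_COLUMNS:
                    raise KeyError(f"unknown composition column {c!r}")
                comp.loc[g, c] = float(v)
    validate_composition_table(comp)
    validate_emission_table(ef, groups)
    return comp, ef


def validate_composition_table(comp: pd.DataFrame) -> None:
    missing = set(COMPOSITION_COLUMNS) - set(comp.columns)
    if missing:
        raise ValueError(f"composition table missing columns: {sorted(missing)}")
    if (comp["energy_kcal"] <= 0).any():
        bad = comp.index[comp["energy_kcal"] <= 0].tolist()
        raise ValueError(f"non-positive energy for food group(s): {bad}")
    if (comp[list(COMPOSITION_COLUMNS)] < 0).any().any():
        raise ValueError("negative nutrient amount in composition table")


def validate_emission_table(ef: pd.DataFrame, food_groups: Sequence[str]) -> None:
    if "kgco2e_per_kg" not in ef.columns:
        raise ValueError("emission table must have a 'kgco2e_per_kg' column")
    missing = set(food_groups) - set(ef.index)
    if missing:
        raise ValueError(f"emission factor missing for food group(s): {sorted(missing)}")
    if (ef["kgco2e_per_kg"] < 0).any():
        raise ValueError("negative emission factor")
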