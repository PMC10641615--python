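"""Nutrient derivation, energy standardisation and GHGE arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sheia.metrics import (
    INTAKE_PREFIX,
    diet_ghge,
    energy_adjust,
    nutrient_profile,
)
from sheia.tables import generate_reference_tables

from conftest import random_intake_frame


def _single_food_composition():
    comp = pd.DataFrame(
        {
            "energy_kcal": [100.0],
            "fibre_g": [3.0],
            "mufa_g": [0.0],
            "pufa_g": [0.0],
            "sfa_g": [2.0],
            "added_sugar_g": [5.0],
            "wholegrain_g": [0.0],
        },
        index=pd.Index(["bread"], name="food_group"),
    )
    return comp


def test_unit_weighting_single_food():
    df = pd.DataFrame({INTAKE_PREFIX + "bread": [100.0]})
    prof = nutrient_profile(df, _single_food_composition())
    assert prof.loc[0, "energy"] == pytest.approx(100.0)
    assert prof.loc[0, "fibre"] == pytest.approx(3.0)
    # E%: 2 g SFA * 9 kcal/g over 100 kcal = 18 %; 5 g sugar * 4 = 20 %
    assert prof.loc[0, "sfa_e"] == pytest.approx(18.0)
    assert prof.loc[0, "added_sugar_e"] == pytest.approx(20.0)


def test_zero_intake_profile_is_zero_with_epct_convention():
    df = pd.DataFrame({INTAKE_PREFIX + "bread": [0.0]})
    with pytest.warns(UserWarning, match="zero-energy"):
        prof = nutrient_profile(df, _single_food_composition())
    assert (prof.iloc[0] == 0).all()


def test_doubling_intakes_doubles_grams_not_epct(ref_tables):
    comp, _ = ref_tables
    rng = np.random.default_rng(5)
    df = random_intake_frame(rng, 50)
    p1 = nutrient_profile(df, comp)
    p2 = nutrient_profile(df * 2.0, comp)
    for col in ("energy", "fibre", "veg_fruit", "wholegrain", "seafood", "red_processed_meat"):
        np.testing.assert_allclose(p2[col], 2.0 * p1[col], rtol=1e-12)
    for col in ("mufa_e", "pufa_e", "sfa_e", "added_sugar_e"):
        np.testing.assert_allclose(p2[col], p1[col], rtol=1e-12)


def test_missing_food_group_named_in_error(ref_tables):
    comp, _ = ref_tables
    df = pd.DataFrame({INTAKE_PREFIX + "mead": [10.0]})
    with pytest.raises(KeyError, match="mead"):
        nutrient_profile(df, comp)


def test_energy_adjust_scales_grams_only():
    prof = pd.DataFrame(
        {"energy": [1000.0, 2500.0], "fibre": [10.0, 12.0], "sfa_e": [12.0, 12.0]}
    )
    adj = energy_adjust(prof, np.array(["female", "male"]))
    assert adj.loc[0, "scale_factor"] == pytest.approx(2.0)
    assert adj.loc[0, "fibre"] == pytest.approx(20.0)
    assert adj.loc[1, "scale_factor"] == pytest.approx(1.0)  # male at 2500 kcal
    assert adj.loc[1, "fibre"] == pytest.approx(12.0)
    np.testing.assert_allclose(adj["sfa_e"], prof["sfa_e"])  # E% invariant
    np.testing.assert_allclose(adj["energy"], [2000.0, 2500.0])


def test_energy_adjust_rejects_zero_energy():
    prof = pd.DataFrame({"energy": [0.0], "fibre": [1.0]})
    with pytest.raises(ValueError, match="energy"):
        energy_adjust(prof, np.array(["female"]))


def test_ghge_two_term_dot_product():
    comp = pd.DataFrame(
        {"kgco2e_per_kg": [26.0, 0.5]},
        index=pd.Index(["beef", "oats"], name="food_group"),
    )
    df = pd.DataFrame(
        {INTAKE_PREFIX + "beef": [100.0], INTAKE_PREFIX + "oats": [400.0],
         "energy": [2500.0]}
    )
    g = diet_ghge(df, comp, sex=np.array(["female"]))
    assert g.loc[0, "ghge_raw"] == pytest.approx(2.8)
    # female reporting 2500 kcal: adjusted = 2.8 * 2000/2500
    assert g.loc[0, "ghge_adjusted"] == pytest.approx(2.24)


def test_ghge_missing_factor_and_zero_diet(ref_tables):
    comp, ef = ref_tables
    df = pd.DataFrame({INTAKE_PREFIX + "ambrosia": [5.0], "energy": [100.0]})
    with pytest.raises(ValueError, match="ambrosia"):
        diet_ghge(df, ef, sex=np.array(["male"]))
    zero = pd.DataFrame(
        {INTAKE_PREFIX + g: [0.0] for g in ef.index} | {"energy": [1.0]}
    )
    assert diet_ghge(zero, ef, sex=np.array(["male"]))["ghge_raw"].iloc[0] == 0.0


def test_unit_emission_factors_give_total_mass(ref_tables):
    comp, ef = ref_tables
    _, unit_ef = generate_reference_tables(
        list(ef.index), emission_overrides={g: 1.0 for g in ef.index}
    )
    rng = np.random.default_rng(2)
    df = random_intake_frame(rng, 20)
    df["energy"] = 2000.0
    g = diet_ghge(df, unit_ef, sex=np.array(["female"] * 20))
    mass_kg = df[[c for c in df if c.startswith(INTAKE_PREFIX)]].sum(axis=1) / 1000.0
    np.testing.assert_allclose(g["ghge_raw"], mass_kg, rtol=1e-12)


def test_red_meat_has_strictly_highest_default_factor(ref_tables):
    _, ef = ref_tables
    meat = ef.loc["red_processed_meat", "kgco2e_per_kg"]
    others = ef.drop(index="red_processed_meat")["kgco2e_per_kg"]
    assert (meat > others).all()


def test_ghge_additive_over_disjoint_diet_halves(ref_tables):
    comp, ef = ref_tables
    rng = np.random.default_rng(3)
    a = random_intake_frame(rng, 10)
    b = random_intake_frame(rng, 10)
    for d in (a, b):
        d["energy"] = 2000.0
    combined = a.copy()
    icols = [c for c in a if c.startswith(INTAKE_PREFIX)]
    combined[icols] = a[icols] + b[icols]
    sex = np.array(["male"] * 10)
    np.testing.assert_allclose(
        diet_ghge(combined, ef, sex=sex)["ghge_raw"],
        diet_ghge(a, ef, sex=sex)["ghge_raw"] + diet_ghge(b, ef, sex=sex)["ghge_raw"],
        rtol=1e-12,
    )


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    c=st.floats(min_value=0.05, max_value=50.0, allow_nan=False),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_scale_invariance_of_adjusted_metrics(c, seed):
    """Multiplying every raw intake by c > 0 leaves the energy-adjusted
    profile and the adjusted GHGE unchanged — the under-reporting correction
    the energy standardisation exists to provide."""
    comp, ef = generate_reference_tables()
    rng = np.random.default_rng(seed)
    df = random_intake_frame(rng, 8)
    sex = np.array(["female", "male"] * 4)

    def adjusted(frame):
        prof = nutrient_profile(frame, comp)
        adj = energy_adjust(prof, sex)
        g = diet_ghge(frame.assign(energy=prof["energy"]), ef, sex=sex)
        return adj, g["ghge_adjusted"]

    a1, g1 = adjusted(df)
    a2, g2 = adjusted(df * c)
    # the scale factor itself varies by 1/c; everything it produces must not
    pd.testing.assert_frame_equal(
        a1.drop(columns="scale_factor"), a2.drop(columns="scale_factor"),
        rtol=1e-9, atol=1e-9,
    )
    np.testing.assert_allclose(g1, g2, rtol=1e-9)
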