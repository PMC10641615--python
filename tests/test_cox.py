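"""Cox partial-likelihood estimation, diagnostics and covariate selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from sheia.cox import (
    RankDeficientError,
    cox_fit,
    ph_check,
    purposeful_selection,
    quintile_hazard_table,
)


def brute_force_beta(time, event, x, ties="breslow"):
    """Independent oracle: maximise the explicit Breslow partial likelihood
    (written from its definition) over a 1-d grid/golden section."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)

    def negll(beta):
        ll = 0.0
        for t in np.unique(time[event == 1]):
            dead = (time == t) & (event == 1)
            at_risk = time >= t
            d = dead.sum()
            ll += beta * x[dead].sum() - d * np.log(np.exp(beta * x[at_risk]).sum())
        return -ll

    res = minimize_scalar(negll, bounds=(-20, 20), method="bounded",
                          options={"xatol": 1e-8})
    return res.x


def test_worked_example_closed_form():
    """Events at t=1,2,3 with x=1,0,1: the score equation's root is
    u = e^beta = 1/sqrt(2), i.e. beta = -ln(2)/2, HR = 0.7071."""
    df = pd.DataFrame({"follow_up_months": [1.0, 2.0, 3.0], "event": [1, 1, 1],
                       "x": [1.0, 0.0, 1.0]})
    fit = cox_fit(df, ["x"])
    assert fit.converged
    assert fit.coef["x"] == pytest.approx(-0.5 * np.log(2.0), abs=1e-6)
    assert fit.summary.loc["x", "hr"] == pytest.approx(2.0**-0.5, abs=1e-6)
    assert fit.coef["x"] == pytest.approx(brute_force_beta(df.follow_up_months, df.event, df.x),
                                          abs=1e-4)


@pytest.mark.parametrize("seed", range(12))
def test_newton_matches_brute_force_on_tiny_datasets(seed):
    """On random datasets of <= 8 subjects with one binary covariate
    (censoring and tied times allowed), the Newton estimate agrees with
    golden-section maximisation of the explicit partial likelihood."""
    rng = np.random.default_rng(seed)
    for _ in range(6):
        n = int(rng.integers(3, 9))
        df = pd.DataFrame(
            {
                "follow_up_months": rng.integers(1, 5, n).astype(float),
                "event": rng.integers(0, 2, n),
                "x": rng.integers(0, 2, n).astype(float),
            }
        )
        ev = df["event"].astype(bool)
        if ev.sum() < 2 or df.loc[ev, "x"].nunique() < 2:
            continue
        fit = cox_fit(df, ["x"])
        if not fit.converged:  # monotone likelihood: oracle hits the bound
            continue
        oracle = brute_force_beta(df.follow_up_months, df.event, df.x)
        assert fit.coef["x"] == pytest.approx(oracle, abs=1e-4)


def test_matches_lifelines_on_moderate_data():
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(1)
    n = 300
    df = pd.DataFrame({"x": rng.normal(size=n), "z": rng.binomial(1, 0.4, n).astype(float)})
    t = rng.exponential(1 / np.exp(0.5 * df.x - 0.3 * df.z))
    cens = rng.exponential(2.0, n)
    df["follow_up_months"] = np.minimum(t, cens)
    df["event"] = (t <= cens).astype(int)
    fit = cox_fit(df, ["x", "z"], ties="efron")
    cph = CoxPHFitter().fit(df[["follow_up_months", "event", "x", "z"]],
                            "follow_up_months", "event")
    np.testing.assert_allclose(fit.coef.to_numpy(), cph.params_.to_numpy(), atol=1e-5)
    np.testing.assert_allclose(fit.summary["se"].to_numpy(),
                               cph.standard_errors_.to_numpy(), atol=1e-5)


def test_constant_covariate_raises_rank_deficiency():
    df = pd.DataFrame({"follow_up_months": [1.0, 2.0, 3.0], "event": [1, 1, 1],
                       "x": [2.0, 2.0, 2.0]})
    with pytest.raises(RankDeficientError, match="x"):
        cox_fit(df, ["x"])


def test_separation_is_reported_not_silently_wrong():
    df = pd.DataFrame({"follow_up_months": [1.0, 2.0], "event": [1, 0],
                       "x": [0.0, 1.0]})
    fit = cox_fit(df, ["x"])
    assert not fit.converged
    assert fit.offending_term == "x"


def test_location_and_scale_invariance():
    rng = np.random.default_rng(3)
    n = 120
    df = pd.DataFrame({"x": rng.normal(size=n)})
    t = rng.exponential(1 / np.exp(0.4 * df.x))
    df["follow_up_months"] = np.minimum(t, 2.0)
    df["event"] = (t <= 2.0).astype(int)
    base = cox_fit(df, ["x"]).coef["x"]
    shifted = cox_fit(df.assign(x=df.x + 100.0), ["x"]).coef["x"]
    scaled = cox_fit(df.assign(x=df.x * 4.0), ["x"]).coef["x"]
    assert shifted == pytest.approx(base, abs=1e-6)
    assert scaled == pytest.approx(base / 4.0, abs=1e-6)


def test_ph_check_matches_lifelines():
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    rng = np.random.default_rng(7)
    n = 250
    df = pd.DataFrame({"x": rng.normal(size=n), "z": rng.normal(size=n)})
    t = rng.exponential(1 / np.exp(0.3 * df.x))
    df["follow_up_months"] = np.minimum(t, 3.0)
    df["event"] = (t <= 3.0).astype(int)
    fit = cox_fit(df, ["x", "z"], ties="efron")
    cph = CoxPHFitter().fit(df[["follow_up_months", "event", "x", "z"]],
                            "follow_up_months", "event")
    for transform in ("rank", "identity"):
        mine = ph_check(fit, df, ["x", "z"], transform=transform)
        ref = proportional_hazard_test(cph, df, time_transform=transform)
        np.testing.assert_allclose(
            mine.table["chi2"].to_numpy(), ref.summary["test_statistic"].to_numpy(),
            rtol=1e-4,
        )


def test_ph_check_type_one_error_calibrated():
    """Under an exponential proportional-hazards model the global test should
    reject near its nominal 5 % level."""
    rejections = 0
    n_rep = 200
    for rep in range(n_rep):
        rng = np.random.default_rng(5000 + rep)
        n = 150
        df = pd.DataFrame({"x": rng.normal(size=n)})
        t = rng.exponential(1 / np.exp(0.3 * df.x))
        df["follow_up_months"] = np.minimum(t, 2.5)
        df["event"] = (t <= 2.5).astype(int)
        fit = cox_fit(df, ["x"])
        rejections += ph_check(fit, df, ["x"]).global_p < 0.05
    assert 0.01 <= rejections / n_rep <= 0.10  # 0.05 +/- binomial noise


def test_ph_check_detects_time_varying_effect():
    """Crossing Weibull hazards (shape 0.6 vs 2.0 between groups) violate
    proportionality; the diagnostic should reject most of the time."""
    rejections = 0
    n_rep = 15
    for rep in range(n_rep):
        rng = np.random.default_rng(200 + rep)
        n = 2000
        x = rng.binomial(1, 0.5, n).astype(float)
        shape = np.where(x > 0, 2.0, 0.6)
        t = rng.weibull(shape) * 1.0
        cens = np.full(n, 2.0)
        df = pd.DataFrame({"x": x, "follow_up_months": np.minimum(t, cens),
                           "event": (t <= cens).astype(int)})
        fit = cox_fit(df, ["x"])
        rejections += ph_check(fit, df, ["x"]).global_p < 0.05
    assert rejections / n_rep >= 0.8


def test_ph_check_low_information_flag_and_no_event_error():
    df = pd.DataFrame({"follow_up_months": [1.0, 2.0, 3.0], "event": [1, 0, 0],
                       "x": [1.0, 0.0, 0.5]})
    fit = cox_fit(df, ["x"])
    res = ph_check(fit, df, ["x"])
    assert res.low_information
    df0 = df.assign(event=0)
    with pytest.raises(ValueError, match="no events"):
        ph_check(fit, df0, ["x"])


def _sim_confounding(rng, n, gamma_xc=0.8, beta_c=0.7, beta_x=-0.3):
    """Exposure x, candidate confounder c, optional null candidate u."""
    c = rng.normal(size=n)
    x = gamma_xc * c + rng.normal(size=n)
    u = rng.normal(size=n)
    t = rng.exponential(1 / np.exp(beta_x * x + beta_c * c))
    cens = rng.exponential(1.5, n)
    return pd.DataFrame(
        {"x": x, "c": c, "u": u,
         "follow_up_months": np.minimum(t, cens), "event": (t <= cens).astype(int)}
    )


def test_purposeful_selection_drops_null_candidate():
    dropped = 0
    n_rep = 60
    for rep in range(n_rep):
        rng = np.random.default_rng(900 + rep)
        df = _sim_confounding(rng, 1200, gamma_xc=0.0, beta_c=0.0)
        selected, _ = purposeful_selection(df, ["x"], ["u"])
        dropped += "u" not in selected
    assert dropped / n_rep >= 0.80


def test_purposeful_selection_keeps_strong_confounder():
    kept = 0
    n_rep = 30
    for rep in range(n_rep):
        rng = np.random.default_rng(400 + rep)
        df = _sim_confounding(rng, 1200)
        selected, trail = purposeful_selection(df, ["x"], ["c", "u"])
        kept += "c" in selected
    assert kept / n_rep >= 0.9


def test_purposeful_selection_no_candidates_gives_empty_set():
    rng = np.random.default_rng(0)
    df = _sim_confounding(rng, 200)
    selected, trail = purposeful_selection(df, ["x"], [])
    assert selected == [] and trail.empty


def test_purposeful_selection_audit_trail_records_every_decision():
    rng = np.random.default_rng(12)
    df = _sim_confounding(rng, 800)
    _, trail = purposeful_selection(df, ["x"], ["c", "u"])
    assert set(trail["step"]) <= {"univariable", "backward", "re-offer"}
    assert set(trail.loc[trail["step"] == "univariable", "candidate"]) == {"c", "u"}


def test_quintile_reference_inversion(small_cohort):
    """Relabelling so that quintile 5 becomes the reference must invert the
    hazard ratio: HR(1 vs 5) = 1 / HR(5 vs 1)."""
    cohort, survival, _ = small_cohort
    df = cohort.join(survival[["follow_up_months", "event"]])
    df["quintile"] = pd.qcut(df["true_score"].rank(method="first"), 5,
                             labels=False).astype(int) + 1
    fit = cox_fit(df, ["quintile"])
    flipped = df.assign(quintile=6 - df["quintile"])
    fit2 = cox_fit(flipped, ["quintile"])
    hr_51 = fit.summary.loc["quintile=5", "hr"]
    hr_15 = fit2.summary.loc["quintile=5", "hr"]
    assert hr_15 == pytest.approx(1.0 / hr_51, rel=1e-6)


def test_quintile_hazard_table_structure(small_cohort):
    cohort, survival, _ = small_cohort
    df = cohort.copy()
    df["year"] = pd.to_datetime(df["visit_date"]).dt.year
    rng = np.random.default_rng(0)
    df["quintile"] = rng.integers(1, 6, len(df))
    df = df.join(survival[["follow_up_months", "event"]])
    table = quintile_hazard_table(df)
    assert set(table["model"]) == {"basic", "adjusted"}
    assert set(table["sex"]) == {"female", "male"}
    assert len(table) == 2 * 2 * 5
    ref = table[table["quintile"] == 1]
    assert (ref["hr"] == 1.0).all()
    assert (table.groupby(["sex", "model"])["events"].sum() > 0).all()
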