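"""Cox proportional-hazards regression, covariate selection and diagnostics.

A self-contained Newton-Raphson maximiser of the Cox partial likelihood with
Breslow (default) or Efron handling of tied event times, plus:

* purposeful (Bursac-style) covariate selection: significance screening
  combined with a change-in-estimate confounding criterion;
* a Grambsch-Therneau scaled-Schoenfeld-residual test of the proportional
  hazards assumption;
* the stratified quintile hazard tables the mortality analysis reports.

Convergence is declared when the log partial likelihood changes by less than
1e-9 or the gradient max-norm falls below 1e-6, within 100 Newton steps
(step-halving on any decrease).  Monotone likelihoods (separation) yield an
explicit non-converged result naming the runaway term rather than garbage
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

Z_95 = 1.959964

CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "education": ("basic", "high_school", "university"),
    "physical_activity": (
        "inactive",
        "moderately_inactive",
        "moderately_active",
        "active",
    ),
    "smoking": ("current", "former", "never"),
}

#: Model-term sets used throughout the mortality analysis.
BASIC_TERMS = ("age", "age_sq")
ADJUSTED_TERMS = ("age", "age_sq", "bmi", "education", "physical_activity", "smoking", "year")

MAX_ABS_BETA = 10.0  # |beta| beyond this is treated as a monotone likelihood


class RankDeficientError(ValueError):
    """Design matrix not full rank on the event set."""


@dataclass
class CoxFit:
    summary: pd.DataFrame  # index=term, columns coef se hr ci_low ci_high p
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    ties: str
    converged: bool
    n_iter: int
    offending_term: str | None = None
    cov: np.ndarray | None = None
    term_groups: dict[str, list[int]] = field(default_factory=dict)

    @property
    def coef(self) -> pd.Series:
        return self.summary["coef"]

    def lrt_vs(self, reduced: "CoxFit") -> float:
        """Likelihood-ratio p-value against a nested reduced fit."""
        df = len(self.summary) - len(reduced.summary)
        if df <= 0:
            return 1.0
        return float(stats.chi2.sf(2.0 * (self.loglik - reduced.loglik), df))


def design_matrix(
    df: pd.DataFrame, terms: tuple[str, ...] | list[str]
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Build the (n, p) design matrix for the given terms.

    Numeric terms are centred at the sample mean (changes only the baseline
    hazard); ``age_sq`` is the square of centred age, which keeps it nearly
    orthogonal to age.  Declared categorical terms get reference-level
    indicator coding (reference = first declared level); ``quintile`` is
    categorical with quintile 1 as reference.  Returns the matrix, column
    names, and a map term -> column indices (for block tests).
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    groups: dict[str, list[int]] = {}
    age_c = None
    if "age" in df.columns:
        age = pd.to_numeric(df["age"], errors="coerce").to_numpy(dtype=float)
        age_c = age - np.nanmean(age)
    for term in terms:
        start = len(names)
        if term == "age_sq":
            if age_c is None:
                raise KeyError("age_sq requires an 'age' column")
            x = age_c**2
            cols.append(x - x.mean())
            names.append("age_sq")
        elif term == "age":
            cols.append(age_c)
            names.append("age")
        elif term in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[term]
            vals = df[term].astype(str)
            unknown = set(vals.unique()) - set(levels)
            if unknown:
                raise ValueError(f"{term!r} has undeclared level(s): {sorted(unknown)}")
            for lev in levels[1:]:
                cols.append((vals == lev).to_numpy(dtype=float))
                names.append(f"{term}={lev}")
        elif term == "quintile":
            q = pd.to_numeric(df[term], errors="coerce").astype(int)
            for lev in sorted(q.unique()):
                if lev == 1:
                    continue
                cols.append((q == lev).to_numpy(dtype=float))
                names.append(f"quintile={lev}")
        else:
            x = pd.to_numeric(df[term], errors="coerce").to_numpy(dtype=float)
            if np.isnan(x).any():
                raise ValueError(f"term {term!r} contains missing values")
            cols.append(x - x.mean())
            names.append(term)
        groups[term] = list(range(start, len(names)))
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names, groups


def _check_rank(X: np.ndarray, event: np.ndarray, names: list[str]) -> None:
    # the partial likelihood only sees within-risk-set contrasts, so a
    # constant or collinear column (together with an implicit intercept)
    # makes the information singular
    if X.shape[1] == 0:
        return
    Xe = X
    aug = np.column_stack([np.ones(len(Xe)), Xe])
    if np.linalg.matrix_rank(aug) < aug.shape[1]:
        # identify offending columns via incremental rank
        bad = []
        base = np.ones((len(Xe), 1))
        for j, nm in enumerate(names):
            cand = np.column_stack([base, Xe[:, j]])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                bad.append(nm)
            else:
                base = cand
        raise RankDeficientError(
            f"design matrix rank-deficient on the event set; collinear term(s): {bad or names}"
        )


def _loglik_grad_hess(
    beta: np.ndarray,
    X: np.ndarray,
    event_pos: np.ndarray,
    tie_first: np.ndarray,
    tie_counts: np.ndarray,
    ties: str,
    want_derivs: bool = True,
):
    """Log partial likelihood (and derivatives) on time-ascending-sorted data.

    ``event_pos``: sorted positions of events; ``tie_first``/``tie_counts``:
    first sorted position and death count of each unique event time (the risk
    set at that time is the suffix starting at ``tie_first``).
    """
    n, p = X.shape
    eta = X @ beta if p else np.zeros(n)
    eta = eta - eta.max() if n else eta
    w = np.exp(eta)
    s0 = np.cumsum(w[::-1])[::-1]
    if want_derivs and p:
        wx = w[:, None] * X
        s1 = np.cumsum(wx[::-1], axis=0)[::-1]
        wxx = wx[:, :, None] * X[:, None, :]
        s2 = np.cumsum(wxx[::-1], axis=0)[::-1]
    ll = float(eta[event_pos].sum())
    g = np.zeros(p)
    h = np.zeros((p, p))
    for first, d in zip(tie_first, tie_counts):
        if ties == "efron" and d > 1:
            dead = slice(first, first + d)  # events sorted first within a tie
            s0d = w[dead].sum()
            if want_derivs and p:
                s1d = wx[dead].sum(axis=0)
                s2d = wxx[dead].sum(axis=0)
            for el in range(d):
                phi = el / d
                den = s0[first] - phi * s0d
                ll -= np.log(den)
                if want_derivs and p:
                    m1 = (s1[first] - phi * s1d) / den
                    g -= m1
                    h -= (s2[first] - phi * s2d) / den - np.outer(m1, m1)
        else:
            den = s0[first]
            ll -= d * np.log(den)
            if want_derivs and p:
                m1 = s1[first] / den
                g -= d * m1
                h -= d * (s2[first] / den - np.outer(m1, m1))
    if want_derivs and p:
        g += X[event_pos].sum(axis=0)
    return ll, g, h


def _prepare(time: np.ndarray, event: np.ndarray, X: np.ndarray):
    # sort ascending by time, events before censorings at tied times
    order = np.lexsort((1 - event, time))
    t, d, Xs = time[order], event[order].astype(bool), X[order]
    event_pos = np.flatnonzero(d)
    if len(event_pos):
        ut, first_idx = np.unique(t[event_pos], return_index=True)
        tie_first = np.searchsorted(t, ut, side="left")
        counts = np.diff(np.append(first_idx, len(event_pos)))
    else:
        tie_first = np.empty(0, dtype=int)
        counts = np.empty(0, dtype=int)
    return t, d, Xs, event_pos, tie_first, counts, order


def cox_fit(
    df: pd.DataFrame,
    terms: tuple[str, ...] | list[str],
    duration_col: str = "follow_up_months",
    event_col: str = "event",
    ties: str = "breslow",
    max_iter: int = 100,
    tol_loglik: float = 1e-9,
    tol_grad: float = 1e-6,
) -> CoxFit:
    """Fit a Cox model of ``duration_col``/``event_col`` on ``terms``.

    Breslow tie handling by default; Efron available (``ties='efron'``) and
    preferable when ties are heavy.  Raises :class:`RankDeficientError` for a
    design matrix without full rank on the event set; separation is reported
    via ``converged=False`` with the runaway term named.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"ties must be 'breslow' or 'efron', got {ties!r}")
    time = pd.to_numeric(df[duration_col], errors="coerce").to_numpy(dtype=float)
    event = pd.to_numeric(df[event_col], errors="coerce").to_numpy(dtype=float)
    if np.isnan(time).any() or (time <= 0).any():
        raise ValueError("durations must be positive and non-missing")
    n_events = int(event.sum())
    if n_events < 1:
        raise ValueError("at least one event is required")
    X, names, groups = design_matrix(df, terms)
    _check_rank(X, event, names)
    t, d, Xs, event_pos, tie_first, counts, _ = _prepare(time, event, X)
    p = X.shape[1]

    beta = np.zeros(p)
    ll, g, h = _loglik_grad_hess(beta, Xs, event_pos, tie_first, counts, ties)
    ll_null = ll if p else ll
    if p == 0:
        summary = pd.DataFrame(
            columns=["coef", "se", "hr", "ci_low", "ci_high", "p"], dtype=float
        )
        return CoxFit(summary, ll, ll, len(df), n_events, ties, True, 0, None, None, groups)

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.abs(g).max() < tol_grad:
            converged = True
            break
        try:
            step = np.linalg.solve(-h, g)
        except np.linalg.LinAlgError:
            break
        new_beta = beta + step
        new_ll, new_g, new_h = _loglik_grad_hess(
            new_beta, Xs, event_pos, tie_first, counts, ties
        )
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_g, new_h = _loglik_grad_hess(
                new_beta, Xs, event_pos, tie_first, counts, ties
            )
            halvings += 1
        delta = new_ll - ll
        beta, ll, g, h = new_beta, new_ll, new_g, new_h
        if np.abs(beta).max() > MAX_ABS_BETA:
            break
        if abs(delta) < tol_loglik:
            converged = True
            break

    offending = None
    if np.abs(beta).max() > MAX_ABS_BETA:
        # the likelihood is monotone in some direction: the "estimate" is
        # running to infinity however flat the likelihood has become
        converged = False
        offending = names[int(np.argmax(np.abs(beta)))]
    elif not converged and np.abs(g).max() < tol_grad:
        converged = True

    try:
        cov = np.linalg.inv(-h)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        se = np.full(p, np.nan)
    z = np.divide(beta, se, out=np.zeros(p), where=se > 0)
    summary = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - Z_95 * se),
            "ci_high": np.exp(beta + Z_95 * se),
            "p": 2.0 * stats.norm.sf(np.abs(z)),
        },
        index=pd.Index(names, name="term"),
    )
    return CoxFit(
        summary, ll, ll_null, len(df), n_events, ties, converged, n_iter, offending, cov, groups
    )


def _null_loglik(df: pd.DataFrame, duration_col: str, event_col: str, ties: str) -> float:
    time = pd.to_numeric(df[duration_col], errors="coerce").to_numpy(dtype=float)
    event = pd.to_numeric(df[event_col], errors="coerce").to_numpy(dtype=float)
    X = np.empty((len(df), 0))
    t, d, Xs, event_pos, tie_first, counts, _ = _prepare(time, event, X)
    ll, _, _ = _loglik_grad_hess(np.zeros(0), Xs, event_pos, tie_first, counts, ties)
    return ll


# ---------------------------------------------------------------------------
# Proportional-hazards diagnostic (Grambsch-Therneau)
# ---------------------------------------------------------------------------

@dataclass
class PhCheckResult:
    table: pd.DataFrame  # per-term chi2, df, p
    global_stat: float
    global_df: int
    global_p: float
    passed: bool
    low_information: bool
    transform: str
    alpha: float = 0.05


def ph_check(
    fit: CoxFit,
    df: pd.DataFrame,
    terms: tuple[str, ...] | list[str],
    duration_col: str = "follow_up_months",
    event_col: str = "event",
    transform: str = "rank",
    alpha: float = 0.05,
) -> PhCheckResult:
    """Test proportional hazards via Schoenfeld-residual association with time.

    For each event the Schoenfeld residual is the covariate value minus the
    risk-set weighted mean at that event time; under proportional hazards the
    residuals show no trend in (transformed) time.  The Grambsch-Therneau
    score test is reported per term and globally, with ``transform`` one of
    'identity', 'rank' or 'log'.
    """
    time = pd.to_numeric(df[duration_col], errors="coerce").to_numpy(dtype=float)
    event = pd.to_numeric(df[event_col], errors="coerce").to_numpy(dtype=float)
    n_events = int(event.sum())
    if n_events < 1:
        raise ValueError("no events: proportional-hazards diagnostic undefined")
    X, names, _ = design_matrix(df, terms)
    beta = fit.coef.reindex(names).to_numpy(dtype=float)
    t, d, Xs, event_pos, tie_first, counts, _ = _prepare(time, event, X)
    p = X.shape[1]

    eta = Xs @ beta
    eta -= eta.max()
    w = np.exp(eta)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]

    # risk-set mean covariate at each unique event time
    resid = np.empty((n_events, p))
    times_ev = np.empty(n_events)
    k = 0
    for first, dd in zip(tie_first, counts):
        mean = s1[first] / s0[first]
        for el in range(dd):
            resid[k] = Xs[first + el] - mean
            times_ev[k] = t[first]
            k += 1

    if transform == "identity":
        gt = times_ev
    elif transform == "rank":
        gt = stats.rankdata(times_ev)
    elif transform == "log":
        gt = np.log(times_ev)
    else:
        raise ValueError(f"unknown time transform {transform!r}")
    gt = gt - gt.mean()
    ssw = float((gt**2).sum())

    v = fit.cov  # variance matrix (inverse observed information) at beta-hat
    u = resid.T @ gt  # p-vector
    d_tot = n_events
    vu = v @ u
    with np.errstate(divide="ignore", invalid="ignore"):
        # scaled-Schoenfeld form (Therneau): per-term slope test of d*V*s on g(t)
        per_term = d_tot * vu**2 / (ssw * np.diag(v))
    global_stat = float(d_tot * u @ vu / ssw)
    table = pd.DataFrame(
        {
            "chi2": per_term,
            "df": 1,
            "p": stats.chi2.sf(per_term, 1),
        },
        index=pd.Index(names, name="term"),
    )
    global_p = float(stats.chi2.sf(global_stat, p))
    return PhCheckResult(
        table=table,
        global_stat=global_stat,
        global_df=p,
        global_p=global_p,
        passed=bool(global_p >= alpha),
        low_information=n_events < 10,
        transform=transform,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Purposeful (Bursac) covariate selection
# ---------------------------------------------------------------------------

def purposeful_selection(
    df: pd.DataFrame,
    exposure_terms: tuple[str, ...] | list[str],
    candidates: tuple[str, ...] | list[str],
    duration_col: str = "follow_up_months",
    event_col: str = "event",
    p_entry: float = 0.25,
    p_retain: float = 0.10,
    p_reentry: float = 0.15,
    delta_beta: float = 0.20,
    ties: str = "breslow",
) -> tuple[list[str], pd.DataFrame]:
    """Select confounders for a Cox model by purposeful selection.

    (1) univariable screen at ``p_entry``; (2) backward elimination at
    ``p_retain``, retaining any covariate whose removal changes a remaining
    coefficient by more than ``delta_beta`` (relative) — the confounding
    criterion; (3) one re-offer of every excluded candidate at ``p_reentry``.
    Block p-values are likelihood-ratio tests, so multi-level categorical
    candidates are screened as a unit.  Returns (selected terms, audit trail).
    """
    candidates = list(candidates)
    if set(candidates) & set(exposure_terms):
        raise ValueError("candidates must be disjoint from exposure terms")
    trail: list[dict] = []
    if not candidates:
        return [], pd.DataFrame(trail)

    def fit(terms: list[str]) -> CoxFit:
        return cox_fit(df, terms, duration_col, event_col, ties=ties)

    ll0 = _null_loglik(df, duration_col, event_col, ties)

    kept: list[str] = []
    for c in candidates:
        f = fit([c])
        p_val = float(stats.chi2.sf(2.0 * (f.loglik - ll0), len(f.summary)))
        action = "enter" if p_val < p_entry else "screen_out"
        trail.append({"step": "univariable", "candidate": c, "p": p_val, "action": action})
        if action == "enter":
            kept.append(c)

    locked: set[str] = set()
    current = list(kept)
    while True:
        full = fit(list(exposure_terms) + current)
        removable = []
        for c in current:
            if c in locked:
                continue
            reduced = fit(list(exposure_terms) + [x for x in current if x != c])
            p_val = full.lrt_vs(reduced)
            if p_val > p_retain:
                removable.append((p_val, c, reduced))
        if not removable:
            break
        p_val, c, reduced = max(removable)
        # change-in-estimate check on every coefficient both models share
        shared = reduced.summary.index.intersection(full.summary.index)
        b_full = full.summary.loc[shared, "coef"]
        b_red = reduced.summary.loc[shared, "coef"]
        denom = b_full.abs().where(b_full.abs() > 1e-8)
        rel_change = ((b_red - b_full).abs() / denom).fillna(0.0)
        max_change = float(rel_change.max()) if len(rel_change) else 0.0
        if max_change > delta_beta:
            locked.add(c)
            trail.append(
                {"step": "backward", "candidate": c, "p": p_val,
                 "action": "retain_confounder", "max_delta_beta": max_change}
            )
        else:
            current.remove(c)
            trail.append(
                {"step": "backward", "candidate": c, "p": p_val,
                 "action": "remove", "max_delta_beta": max_change}
            )

    for c in candidates:
        if c in current:
            continue
        base = fit(list(exposure_terms) + current)
        cand_fit = fit(list(exposure_terms) + current + [c])
        p_val = cand_fit.lrt_vs(base)
        action = "re_enter" if p_val < p_reentry else "stay_out"
        trail.append({"step": "re-offer", "candidate": c, "p": p_val, "action": action})
        if action == "re_enter":
            current.append(c)

    return current, pd.DataFrame(trail)


# ---------------------------------------------------------------------------
# Reported hazard tables
# ---------------------------------------------------------------------------

def quintile_hazard_table(
    df: pd.DataFrame,
    duration_col: str = "follow_up_months",
    event_col: str = "event",
    sex_col: str = "sex",
    ties: str = "breslow",
) -> pd.DataFrame:
    """Per-sex HRs (95 % CI, Wald p) for quintiles 2-5 vs quintile 1.

    Two models per sex: basic (age + age squared) and adjusted (+ BMI,
    education, physical activity, smoking, year of participation).
    """
    rows = []
    for sex_val, sub in df.groupby(sex_col):
        for model, covs in (("basic", BASIC_TERMS), ("adjusted", ADJUSTED_TERMS)):
            f = cox_fit(sub, ["quintile", *covs], duration_col, event_col, ties=ties)
            counts = sub.groupby("quintile")[event_col].agg(["size", "sum"])
            rows.append(
                {
                    "sex": sex_val, "model": model, "quintile": 1, "hr": 1.0,
                    "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                    "n": int(counts.loc[1, "size"]), "events": int(counts.loc[1, "sum"]),
                }
            )
            for q in sorted(sub["quintile"].unique()):
                if q == 1:
                    continue
                term = f"quintile={q}"
                r = f.summary.loc[term]
                rows.append(
                    {
                        "sex": sex_val, "model": model, "quintile": int(q),
                        "hr": r["hr"], "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                        "p": r["p"], "n": int(counts.loc[q, "size"]),
                        "events": int(counts.loc[q, "sum"]),
                    }
                )
    return pd.DataFrame(rows)


def continuous_score_hr(
    df: pd.DataFrame,
    score_col: str = "sheia15",
    duration_col: str = "follow_up_months",
    event_col: str = "event",
    ties: str = "breslow",
    covariates: tuple[str, ...] = ADJUSTED_TERMS,
) -> pd.Series:
    """Adjusted HR per unit of the (continuous) diet-quality score."""
    f = cox_fit(df, [score_col, *covariates], duration_col, event_col, ties=ties)
    return f.summary.loc[score_col]
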