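"""Tie-corrected rank tests for group differences in dietary GHGE.

Kruskal-Wallis omnibus, Dunn pairwise z-tests with Bonferroni adjustment,
the Jonckheere-Terpstra test for an a-priori ordered trend, and the
Mann-Whitney U test.  All four use mid-ranks for ties with the standard
tie-corrected null variances, and each offers a permutation null (group
labels permuted; add-one p-value (b + 1)/(m + 1)) as an internal oracle for
the asymptotic approximations.  Two-sided p-values double the smaller tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    null: str  # "asymptotic", "permutation" or "exact"
    tie_correction: float | None = None
    n_per_group: tuple[int, ...] = ()
    z: float | None = None
    p_one_sided: float | None = None
    n_perm: int | None = None
    seed: int | None = None
    df: int | None = None


def _groups_arrays(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    for g in gs:
        if g.size == 0:
            raise ValueError("every group must be non-empty")
    return gs


def _tie_vector(pooled: np.ndarray) -> np.ndarray:
    _, counts = np.unique(pooled, return_counts=True)
    return counts.astype(float)


def _kw_h(gs: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and the correction factor C."""
    pooled = np.concatenate(gs)
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    idx = 0
    h = 0.0
    for g in gs:
        r = ranks[idx: idx + g.size]
        idx += g.size
        h += r.sum() ** 2 / g.size
    h = 12.0 / (n_tot * (n_tot + 1)) * h - 3.0 * (n_tot + 1)
    t = _tie_vector(pooled)
    c = 1.0 - ((t**3 - t).sum()) / (n_tot**3 - n_tot)
    return (h / c if c > 0 else 0.0), c


def kruskal_wallis(groups, permutation: int | None = None, seed: int = 0) -> TestResult:
    """Kruskal-Wallis one-way ANOVA on ranks across k groups.

    Asymptotic p from chi-square with k-1 df; ``permutation`` switches to a
    label-permutation null with that many permutations.  All values identical
    gives H = 0, p = 1.
    """
    gs = _groups_arrays(groups)
    k = len(gs)
    h, c = _kw_h(gs)
    if c <= 0:  # every pooled value identical
        return TestResult(0.0, 1.0, "kruskal-wallis", "asymptotic", c,
                          tuple(g.size for g in gs), df=k - 1)
    p_asym = float(stats.chi2.sf(h, k - 1))
    if permutation is None:
        return TestResult(float(h), p_asym, "kruskal-wallis", "asymptotic", c,
                          tuple(g.size for g in gs), df=k - 1)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate(gs)
    sizes = [g.size for g in gs]
    cuts = np.cumsum(sizes)[:-1]
    b = 0
    for _ in range(permutation):
        perm = rng.permutation(pooled)
        hp, _ = _kw_h(np.split(perm, cuts))
        if hp >= h - 1e-12:
            b += 1
    return TestResult(float(h), (b + 1) / (permutation + 1), "kruskal-wallis",
                      "permutation", c, tuple(sizes), n_perm=permutation, seed=seed,
                      df=k - 1)


def dunn_posthoc(groups, correction: str = "bonferroni", pairs=None) -> list[TestResult]:
    """Dunn's pairwise rank comparisons after Kruskal-Wallis.

    z_ij = (mean rank_i - mean rank_j) / sqrt((N(N+1)/12 - T/(12(N-1)))
    (1/n_i + 1/n_j)) with tie term T = sum(t^3 - t); two-sided p multiplied
    by the number of tested pairs (all pairs by default) and clamped at 1.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    gs = _groups_arrays(groups)
    k = len(gs)
    pooled = np.concatenate(gs)
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    idx = 0
    for g in gs:
        mean_ranks.append(ranks[idx: idx + g.size].mean())
        idx += g.size
    t = _tie_vector(pooled)
    tie_term = (t**3 - t).sum()
    base_var = n_tot * (n_tot + 1) / 12.0 - tie_term / (12.0 * (n_tot - 1))
    pairs = list(pairs) if pairs is not None else list(combinations(range(k), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        se = np.sqrt(base_var * (1.0 / gs[i].size + 1.0 / gs[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, m * p_raw) if correction == "bonferroni" else p_raw
        out.append(
            TestResult(float(z), float(p_adj), f"dunn[{i + 1}v{j + 1}]", "asymptotic",
                       tie_term, (gs[i].size, gs[j].size), z=float(z))
        )
    return out


def _jt_stat(gs: list[np.ndarray]) -> float:
    j = 0.0
    for a, b in combinations(gs, 2):
        # count pairs (x in a, y in b) with y > x, ties counted half
        bs = np.sort(b)
        gt = bs.size - np.searchsorted(bs, a, side="right")
        ge = bs.size - np.searchsorted(bs, a, side="left")
        j += gt.sum() + 0.5 * (ge - gt).sum()
    return float(j)


def jonckheere_terpstra(
    ordered_groups, alternative: str = "two-sided", method: str = "auto",
    n_perm: int = 10_000, seed: int = 0,
) -> TestResult:
    """Jonckheere-Terpstra test for a monotone trend across ordered groups.

    J counts concordant cross-group pairs (ties half); the asymptotic z uses
    the tie-adjusted null moments.  ``method``: 'asymptotic', 'permutation',
    or 'auto' (permutation whenever any group has fewer than 5 values, where
    the normal approximation is poor).  Reports the two-sided p (default)
    with the one-sided increasing-trend p alongside.
    """
    if method not in ("auto", "asymptotic", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    gs = _groups_arrays(ordered_groups)
    sizes = np.array([g.size for g in gs], dtype=float)
    n_tot = int(sizes.sum())
    j_obs = _jt_stat(gs)
    mean = (n_tot**2 - (sizes**2).sum()) / 4.0

    pooled = np.concatenate(gs)
    t = _tie_vector(pooled)
    n1 = float(n_tot)
    var = (
        (n1 * (n1 - 1) * (2 * n1 + 5)
         - (sizes * (sizes - 1) * (2 * sizes + 5)).sum()
         - (t * (t - 1) * (2 * t + 5)).sum()) / 72.0
        + ((sizes * (sizes - 1) * (sizes - 2)).sum() * (t * (t - 1) * (t - 2)).sum())
        / (36.0 * n1 * (n1 - 1) * (n1 - 2))
        + ((sizes * (sizes - 1)).sum() * (t * (t - 1)).sum()) / (8.0 * n1 * (n1 - 1))
    )
    use_perm = method == "permutation" or (method == "auto" and (sizes < 5).any())
    if use_perm:
        permutation = n_perm
        rng = np.random.default_rng(seed)
        cuts = np.cumsum(sizes.astype(int))[:-1]
        b_two = b_one = 0
        dev_obs = abs(j_obs - mean)
        for _ in range(permutation):
            perm = rng.permutation(pooled)
            jp = _jt_stat(np.split(perm, cuts))
            if abs(jp - mean) >= dev_obs - 1e-12:
                b_two += 1
            if jp >= j_obs - 1e-12:
                b_one += 1
        p_two = (b_two + 1) / (permutation + 1)
        p_one = (b_one + 1) / (permutation + 1)
        p = p_two if alternative == "two-sided" else p_one
        return TestResult(j_obs, p, "jonckheere-terpstra", "permutation",
                          float((t**3 - t).sum()), tuple(int(s) for s in sizes),
                          p_one_sided=p_one, n_perm=permutation, seed=seed)
    z = (j_obs - mean) / np.sqrt(var) if var > 0 else 0.0
    p_one = float(stats.norm.sf(z))  # increasing trend
    p_two = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    p = p_two if alternative == "two-sided" else p_one
    return TestResult(j_obs, p, "jonckheere-terpstra", "asymptotic",
                      float((t**3 - t).sum()), tuple(int(s) for s in sizes),
                      z=float(z), p_one_sided=p_one)


def _mwu_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r_x = ranks[: x.size].sum()
    u_x = x.size * y.size + x.size * (x.size + 1) / 2.0 - r_x
    u_y = x.size * y.size - u_x
    return u_x, u_y


def mann_whitney_u(
    x, y, continuity: bool = True, exact_max_n: int = 12,
    permutation: int | None = None, seed: int = 0,
) -> TestResult:
    """Mann-Whitney U with mid-rank ties; U = min(U_x, U_y).

    Exact enumeration of all C(N, n_x) group assignments when N <= ``exact_max_n``
    (valid with ties too); otherwise the tie-corrected normal approximation
    with a continuity correction, or an explicit permutation null.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u_x, u_y = _mwu_u(x, y)
    u = min(u_x, u_y)
    nx, ny = x.size, y.size
    n_tot = nx + ny
    pooled = np.concatenate([x, y])
    t = _tie_vector(pooled)
    tie_term = (t**3 - t).sum()

    if permutation is not None:
        rng = np.random.default_rng(seed)
        b_low = b_high = 0
        for _ in range(permutation):
            perm = rng.permutation(pooled)
            up, _ = _mwu_u(perm[:nx], perm[nx:])
            if up <= u_x + 1e-12:
                b_low += 1
            if up >= u_x - 1e-12:
                b_high += 1
        tail = min((b_low + 1) / (permutation + 1), (b_high + 1) / (permutation + 1))
        return TestResult(float(u), min(1.0, 2.0 * tail), "mann-whitney-u",
                          "permutation", tie_term, (nx, ny), n_perm=permutation, seed=seed)

    if n_tot <= exact_max_n:
        from itertools import combinations as _comb

        count_le = count_ge = 0
        total = comb(n_tot, nx)
        for chosen in _comb(range(n_tot), nx):
            mask = np.zeros(n_tot, dtype=bool)
            mask[list(chosen)] = True
            up, _ = _mwu_u(pooled[mask], pooled[~mask])
            if up <= u_x + 1e-12:
                count_le += 1
            if up >= u_x - 1e-12:
                count_ge += 1
        p = min(1.0, 2.0 * min(count_le, count_ge) / total)
        return TestResult(float(u), float(p), "mann-whitney-u", "exact",
                          tie_term, (nx, ny))

    mu = nx * ny / 2.0
    var = nx * ny / 12.0 * ((n_tot + 1) - tie_term / (n_tot * (n_tot - 1)))
    if var <= 0:
        return TestResult(float(u), 1.0, "mann-whitney-u", "asymptotic", tie_term, (nx, ny), z=0.0)
    cc = 0.5 if continuity else 0.0
    z = (u - mu + cc) / np.sqrt(var)  # u <= mu by construction
    z_nocc = (u - mu) / np.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.cdf(z)))
    return TestResult(float(u), p, "mann-whitney-u", "asymptotic",
                      tie_term, (nx, ny), z=float(z_nocc))
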