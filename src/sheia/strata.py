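"""Quintile assignment of diet-quality scores within sex x baseline-age strata.

Subjects are ranked by score within each stratum and cut into five contiguous
rank blocks of near-equal size (rank-block quantiles).  With heavily tied
index values, threshold quantiles would produce unbalanced groups; ranking
keeps the blocks within one subject of each other.  Remainders go to the
lowest-numbered groups (largest-remainder rule), ties are broken by
subject_id, so the labels are a deterministic function of the record set,
not of input row order.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

AGE_GROUP_EDGES = (35, 45, 55, 66)
AGE_GROUP_LABELS = ("35-44", "45-54", "55-65")


def age_group(age: pd.Series | np.ndarray) -> pd.Series:
    """Baseline age group: 35-44, 45-54, 55-65 (left-inclusive, integer years)."""
    age = pd.Series(np.asarray(age, dtype=float))
    labels = pd.cut(
        age, bins=[AGE_GROUP_EDGES[0] - 0.5, 45 - 0.5, 55 - 0.5, AGE_GROUP_EDGES[3]],
        labels=AGE_GROUP_LABELS, right=False,
    )
    return labels.astype(object)


def _block_sizes(m: int, n_groups: int) -> np.ndarray:
    base, rem = divmod(m, n_groups)
    sizes = np.full(n_groups, base)
    sizes[:rem] += 1  # largest remainder to the lowest-numbered groups
    return sizes


def assign_quintiles(
    df: pd.DataFrame,
    score_col: str = "sheia15",
    n_groups: int = 5,
    strata_cols: tuple[str, ...] = ("sex", "age_group"),
    id_col: str = "subject_id",
) -> pd.Series:
    """Group label 1..n_groups per subject (1 = lowest scores).

    ``df`` must carry the score, the stratum columns and the id column used
    for deterministic tie-breaking.  If a stratum has fewer subjects than
    groups a warning is issued and the degenerate labels (some groups empty)
    are still returned.
    """
    for c in (score_col, id_col) + tuple(strata_cols):
        if c not in df.columns:
            raise KeyError(f"missing column {c!r}")
    labels = pd.Series(np.zeros(len(df), dtype=int), index=df.index, name="quintile")
    for _, sub in df.groupby(list(strata_cols), dropna=False, observed=True):
        m = len(sub)
        if m == 0:
            continue
        if m < n_groups:
            warnings.warn(
                f"stratum with {m} subject(s) < {n_groups} groups: degenerate labels",
                stacklevel=2,
            )
        order = sub.sort_values([score_col, id_col], kind="stable").index
        sizes = _block_sizes(m, n_groups)
        lab = np.repeat(np.arange(1, n_groups + 1), sizes)
        labels.loc[order] = lab
    return labels
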