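"""The SHEIA15 diet-quality score.

SHEIA15 measures adherence to the 2015 Swedish food-based dietary guidelines
with nine components: six adequacy components (vegetables + fruit, seafood,
whole grains, fibre, MUFA, PUFA — more is better) and three moderation
components (SFA, red and processed meat, added sugar — less is better).

Each component is a ratio of intake to the sex-specific recommendation,

* adequacy:   raw = intake / recommended
* moderation: raw = 2 - intake / recommended

truncated to [0, 1] and summed, giving a total in [0, 9].  The moderation
transform gives full credit at or below the cut-off, zero credit at twice the
cut-off, and is linear in between; it is what produces raw ratios below 0
that the truncation rule recodes.  Scores are computed on the energy-adjusted
profile, so they reflect diet quality rather than quantity.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

SCORE_COLUMN = "sheia15"
COMPONENT_PREFIX = "sheia15_"


@dataclass(frozen=True)
class ComponentSpec:
    """One index component.

    ``basis`` names the nutrient-profile field the component reads;
    ``recommended`` maps sex -> recommended intake in ``unit`` (g/day or E%).
    """

    name: str
    direction: str  # "positive" (adequacy) or "negative" (moderation)
    basis: str
    unit: str
    recommended: dict[str, float]

    def __post_init__(self) -> None:
        if self.direction not in ("positive", "negative"):
            raise ValueError(f"direction must be positive/negative, got {self.direction!r}")
        for sex, v in self.recommended.items():
            if v <= 0:
                raise ValueError(f"recommended intake for {self.name}/{sex} must be > 0")


def default_components() -> list[ComponentSpec]:
    """The shipped nine-component sheia15-2015 configuration."""
    text = resources.files("sheia").joinpath("data/sheia15_2015.toml").read_text()
    return parse_components(tomllib.loads(text))


def parse_components(doc: dict) -> list[ComponentSpec]:
    specs = [
        ComponentSpec(
            name=c["name"],
            direction=c["direction"],
            basis=c["basis"],
            unit=c.get("unit", ""),
            recommended={k: float(v) for k, v in c["recommended"].items()},
        )
        for c in doc["component"]
    ]
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate component names: {dupes}")
    return specs


def component_score(
    intake: np.ndarray | float,
    recommended: np.ndarray | float,
    direction: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw ratio and truncated score of one component.

    Adequacy: raw = intake/recommended; moderation: raw = 2 - intake/recommended.
    Truncated = clamp(raw, 0, 1).
    """
    ratio = np.asarray(intake, dtype=float) / np.asarray(recommended, dtype=float)
    raw = ratio if direction == "positive" else 2.0 - ratio
    return raw, np.clip(raw, 0.0, 1.0)


def score_profiles(
    profile: pd.DataFrame,
    sex: pd.Series | np.ndarray,
    specs: Sequence[ComponentSpec] | None = None,
    exclude: str | None = None,
) -> pd.DataFrame:
    """Score energy-adjusted nutrient profiles.

    Returns a DataFrame with one truncated-score column per component
    (``sheia15_<name>``), raw-ratio columns (``sheia15_raw_<name>``) and the
    total in ``sheia15``.  ``exclude`` drops one named component (leave-one-out
    variant; total then lies in [0, 8] and the remaining component scores are
    identical to the full index's).
    """
    specs = list(specs) if specs is not None else default_components()
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate component names")
    if exclude is not None:
        if exclude not in names:
            raise KeyError(f"unknown component {exclude!r}; valid names: {sorted(names)}")
        specs = [s for s in specs if s.name != exclude]
    sex_arr = np.asarray(sex)
    out = pd.DataFrame(index=profile.index)
    total = np.zeros(len(profile))
    for spec in specs:
        if spec.basis not in profile.columns:
            raise KeyError(f"profile lacks field {spec.basis!r} needed by component {spec.name!r}")
        rec = np.where(
            sex_arr == "female", spec.recommended["female"], spec.recommended["male"]
        )
        raw, trunc = component_score(profile[spec.basis].to_numpy(dtype=float), rec, spec.direction)
        out[COMPONENT_PREFIX + "raw_" + spec.name] = raw
        out[COMPONENT_PREFIX + spec.name] = trunc
        total += trunc
    out[SCORE_COLUMN] = total
    return out


def total_score(
    profile: pd.DataFrame,
    sex: pd.Series | np.ndarray,
    specs: Sequence[ComponentSpec] | None = None,
) -> pd.Series:
    """Total SHEIA15 score per subject (full floating precision, in [0, 9])."""
    return score_profiles(profile, sex, specs)[SCORE_COLUMN]


def leave_one_out(
    profile: pd.DataFrame,
    sex: pd.Series | np.ndarray,
    excluded: str,
    specs: Sequence[ComponentSpec] | None = None,
) -> pd.DataFrame:
    """Eight-component score with ``excluded`` removed."""
    return score_profiles(profile, sex, specs, exclude=excluded)


def component_names(specs: Iterable[ComponentSpec] | None = None) -> list[str]:
    return [s.name for s in (specs if specs is not None else default_components())]
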