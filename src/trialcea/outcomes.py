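"""Health outcomes: SF-6D utility scoring, QALY area-under-curve, and the
effect-difference conventions used by the economic comparisons.

The SF-6D is a six-dimension preference-based classification derived from
SF-12 responses; a health state's utility is one minus the sum of population
utility decrements for each dimension level, with an extra decrement when
any dimension sits at its worst level.  The published coefficient set is
licensed and therefore not shipped: scoring is table-driven and the package
includes only a clearly-labelled synthetic toy table for tests and demos.

QALYs over the 12-month horizon are the trapezoidal area under the utility
trajectory observed at months 0, 3, 6, 9, 12 (interval length 0.25 years).
Discounting is not applied at a 12-month horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_WAVES, WAVE_YEARS

__all__ = [
    "SF6DModel",
    "score_sf6d",
    "toy_sf6d_model",
    "qaly_auc",
    "qaly_from_wave_utilities",
    "effect_difference",
    "QALY_TOTAL_WEIGHTS",
]

SF6D_DIMENSIONS = (
    "physical_functioning",
    "role_limitation",
    "social_functioning",
    "pain",
    "mental_health",
    "vitality",
)


@dataclass(frozen=True)
class SF6DModel:
    """Table-driven SF-6D scoring model.

    decrements : (dimension, level) -> utility decrement; level 1 of every
        dimension must have decrement 0.
    most_severe_term : extra decrement applied once if any dimension is at
        its worst (highest) level.  Whether the original scoring applied
        this term is configurable; it defaults to present.
    floor : lowest attainable utility (the worst health state's value).
    """

    decrements: Mapping[tuple[str, int], float]
    most_severe_term: float = 0.0
    floor: float = 0.0
    apply_most_severe: bool = True

    def __post_init__(self) -> None:
        for (dim, level), dec in self.decrements.items():
            if dec < 0:
                raise ValueError(f"negative decrement for {(dim, level)}")
            if level == 1 and dec != 0:
                raise ValueError(f"level 1 of {dim!r} must have decrement 0")
        if self.most_severe_term < 0:
            raise ValueError("most_severe_term must be >= 0")

    @property
    def dimensions(self) -> list[str]:
        return sorted({d for d, _ in self.decrements})

    def worst_level(self, dim: str) -> int:
        return max(l for d, l in self.decrements if d == dim)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SF6DModel":
        """Load a ``dimension, level, decrement`` table (user-supplied weights)."""
        df = pd.read_csv(path)
        dec = {
            (str(r["dimension"]), int(r["level"])): float(r["decrement"])
            for _, r in df.iterrows()
        }
        return cls(decrements=dec, **kwargs)


def score_sf6d(responses: Mapping[str, int], model: SF6DModel) -> float:
    """Score one SF-6D level profile to a utility.

    utility = 1 - sum of dimension decrements - most-severe term (if any
    dimension is at its worst level), clamped below at the model floor.
    """
    total = 0.0
    most_severe = False
    for dim in model.dimensions:
        if dim not in responses:
            raise KeyError(f"no level supplied for dimension {dim!r}")
        level = int(responses[dim])
        if (dim, level) not in model.decrements:
            raise KeyError(f"unknown level {level} for dimension {dim!r}")
        total += model.decrements[(dim, level)]
        if level == model.worst_level(dim):
            most_severe = True
    u = 1.0 - total
    if model.apply_most_severe and most_severe:
        u -= model.most_severe_term
    return max(u, model.floor)


def toy_sf6d_model() -> SF6DModel:
    """Synthetic SF-6D decrement table for tests and demos.

    These are NOT the licensed British general-population weights; they are
    invented values with the same structure (six dimensions, 3-6 levels,
    monotone decrements, a most-severe term, floor 0.29) so the scoring
    algorithm can be exercised and shipped without redistributing the
    licensed coefficient set.
    """
    levels = {
        "physical_functioning": [0.0, 0.035, 0.044, 0.056, 0.083, 0.115],
        "role_limitation": [0.0, 0.026, 0.045, 0.052],
        "social_functioning": [0.0, 0.037, 0.042, 0.051, 0.081],
        "pain": [0.0, 0.025, 0.042, 0.056, 0.079, 0.112],
        "mental_health": [0.0, 0.042, 0.055, 0.079, 0.108],
        "vitality": [0.0, 0.033, 0.048, 0.062, 0.092],
    }
    dec = {
        (dim, i + 1): v
        for dim, vals in levels.items()
        for i, v in enumerate(vals)
    }
    return SF6DModel(decrements=dec, most_severe_term=0.061, floor=0.29)


# ---------------------------------------------------------------------------
# QALYs

#: weights applied to follow-up-wave utility *differences* when the baseline
#: difference is adjusted to zero: d/du_t of the trapezoid AUC at months
#: 3, 6, 9 (interior: two half-intervals) and 12 (endpoint: one).
QALY_TOTAL_WEIGHTS = {3: 0.25, 6: 0.25, 9: 0.25, 12: 0.125}


def qaly_auc(utilities: Sequence[float], waves: Sequence[int] = DEFAULT_WAVES) -> float:
    """Trapezoidal QALY over the trajectory observed at the scheduled waves.

    Requires a utility at every wave (base case); missingness is the
    caller's problem (model-based estimation or imputation).  Result is in
    years and lies in [0, horizon] for utilities in [0, 1].
    """
    u = np.asarray(utilities, dtype=float)
    if u.shape != (len(waves),):
        raise ValueError(f"expected {len(waves)} utilities, got shape {u.shape}")
    if np.isnan(u).any():
        raise ValueError("QALY undefined with missing waves; impute or model instead")
    t = np.asarray(waves, dtype=float) / 12.0
    return float(np.trapezoid(u, t))


def qaly_from_wave_utilities(wide: pd.DataFrame, waves: Sequence[int] = DEFAULT_WAVES) -> pd.Series:
    """Per-participant QALYs from a wide frame with columns ``util_<wave>``.

    Rows with any missing wave get NaN.
    """
    cols = [f"util_{w}" for w in waves]
    u = wide[cols].to_numpy(dtype=float)
    t = np.asarray(waves, dtype=float) / 12.0
    out = np.trapezoid(u, t, axis=1)
    out[np.isnan(u).any(axis=1)] = np.nan
    return pd.Series(out, index=wide.index, name="qaly")


# ---------------------------------------------------------------------------
# Effect conventions


def effect_difference(effect_kind: str, arm_values, control_values) -> float:
    """Between-arm effect difference with the reporting sign convention.

    QALY (higher is better):   dE = mean(arm) - mean(control).
    MADRS (lower is better):   dE = mean(control) - mean(arm), i.e. the
    improvement of the intervention arm over control; positive favours the
    intervention, matching how depression-score differences are tabled.
    """
    a = np.asarray(arm_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    a, c = a[~np.isnan(a)], c[~np.isnan(c)]
    if a.size == 0 or c.size == 0:
        raise ValueError("effect_difference: empty group")
    if effect_kind.lower() == "qaly":
        return float(a.mean() - c.mean())
    if effect_kind.lower() == "madrs":
        return float(c.mean() - a.mean())
    raise ValueError(f"unknown effect kind {effect_kind!r}")
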