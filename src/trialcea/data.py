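"""Trial data containers and validated CSV I/O.

The canonical representation is *long* format: one row per participant-wave,
with explicit missing markers (``NaN``) for any field not collected at that
wave.  Service-use counts live in columns named ``svc_<category>``; a wave
whose questionnaire was not returned has *all* service columns missing,
which is what makes its cost missing downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_WAVES, config_hash

__all__ = [
    "TrialDataset",
    "UnitCostTable",
    "read_trial_long",
    "read_unit_costs",
    "write_results",
    "SERVICE_PREFIX",
    "ARM_LABELS",
]

SERVICE_PREFIX = "svc_"

ARM_LABELS: dict[int, str] = {
    1: "control forum",
    2: "psychoeducation",
    3: "psychoeducation+CBT",
}

#: columns every long-format trial table must carry
CORE_COLUMNS = ("participant_id", "arm", "sex", "country", "wave", "utility", "madrs")

SEX_LEVELS = ("female", "male")
COUNTRY_LEVELS = ("US", "Australia", "other")


class TrialDataValidationError(ValueError):
    """Raised when a trial table fails validation; message carries row context."""


@dataclass
class TrialDataset:
    """Validated participant-wave records for a three-arm trial.

    Attributes
    ----------
    df : long-format frame, one row per (participant, wave), columns
        ``participant_id, arm, sex, country, wave, svc_*, utility, madrs``
        and optionally ``cost_aud`` (attached by the costing step).
    wave_schedule : assessment months, default ``(0, 3, 6, 9, 12)``.
    arms : arm-id -> human label.
    """

    df: pd.DataFrame
    wave_schedule: tuple[int, ...] = DEFAULT_WAVES
    arms: Mapping[int, str] = field(default_factory=lambda: dict(ARM_LABELS))

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def service_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith(SERVICE_PREFIX)]

    @property
    def service_categories(self) -> list[str]:
        return [c[len(SERVICE_PREFIX):] for c in self.service_columns]

    @property
    def participants(self) -> pd.Index:
        return pd.Index(self.df["participant_id"].unique())

    @property
    def n_participants(self) -> int:
        return self.df["participant_id"].nunique()

    def arm_sizes(self) -> dict[int, int]:
        base = self.df[self.df["wave"] == self.wave_schedule[0]]
        return base.groupby("arm")["participant_id"].nunique().to_dict()

    def wave_frame(self, wave: int) -> pd.DataFrame:
        return self.df[self.df["wave"] == wave]

    def validate(self) -> None:
        df = self.df
        missing_cols = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing_cols:
            raise TrialDataValidationError(f"missing required columns: {missing_cols}")

        bad_arm = df.loc[~df["arm"].isin(list(self.arms)), ["participant_id", "arm"]]
        if len(bad_arm):
            r = bad_arm.iloc[0]
            raise TrialDataValidationError(
                f"unknown arm code {r['arm']!r} for participant {r['participant_id']!r}"
            )
        bad_wave = df.loc[~df["wave"].isin(self.wave_schedule), ["participant_id", "wave"]]
        if len(bad_wave):
            r = bad_wave.iloc[0]
            raise TrialDataValidationError(
                f"wave {r['wave']!r} outside schedule {self.wave_schedule} "
                f"for participant {r['participant_id']!r}"
            )
        dup = df.duplicated(subset=["participant_id", "wave"], keep=False)
        if dup.any():
            r = df.loc[dup].iloc[0]
            raise TrialDataValidationError(
                f"duplicate record for participant {r['participant_id']!r} at wave {r['wave']}"
            )
        baseline_wave = self.wave_schedule[0]
        have_baseline = set(df.loc[df["wave"] == baseline_wave, "participant_id"])
        everyone = set(df["participant_id"])
        if everyone - have_baseline:
            missing = sorted(everyone - have_baseline)[:5]
            raise TrialDataValidationError(f"participants without a baseline record: {missing}")

        util = df["utility"].dropna()
        if ((util < 0) | (util > 1)).any():
            raise TrialDataValidationError("utility values outside [0, 1]")
        madrs = df["madrs"].dropna()
        if ((madrs < 0) | (madrs > 60)).any():
            raise TrialDataValidationError("MADRS scores outside [0, 60]")
        for col in self.service_columns:
            vals = df[col].dropna()
            if (vals < 0).any():
                raise TrialDataValidationError(f"negative service count in {col}")
            if not np.allclose(vals, np.round(vals)):
                raise TrialDataValidationError(f"non-integer service count in {col}")
        if "cost_aud" in df.columns:
            costs = df["cost_aud"].dropna()
            if (costs < 0).any():
                raise TrialDataValidationError("negative cost_aud")
        # arm consistent within participant
        n_arms = df.groupby("participant_id")["arm"].nunique()
        if (n_arms > 1).any():
            pid = n_arms[n_arms > 1].index[0]
            raise TrialDataValidationError(f"participant {pid!r} appears in more than one arm")

    # -- missingness book-keeping -----------------------------------------
    def service_use_missing(self) -> pd.Series:
        """Boolean per row: questionnaire not returned (all service counts NaN)."""
        svc = self.df[self.service_columns]
        if svc.shape[1] == 0:
            return pd.Series(False, index=self.df.index)
        return svc.isna().all(axis=1)

    def completion_by_wave(self) -> pd.Series:
        """Fraction of randomized participants with observed service use, per wave."""
        n = self.n_participants
        obs = (~self.service_use_missing()).groupby(self.df["wave"]).sum()
        return (obs / n).reindex(self.wave_schedule)

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def copy(self) -> "TrialDataset":
        return TrialDataset(self.df.copy(), self.wave_schedule, dict(self.arms))


def read_trial_long(path, schema: Sequence[int] = DEFAULT_WAVES) -> TrialDataset:
    """Read a long-format trial CSV and validate it.

    Empty cells become explicit missing markers (never zeros).  Rows failing
    type checks are rejected with the offending participant/wave named.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    for col in df.columns:
        if col in ("arm", "wave"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
        elif col.startswith(SERVICE_PREFIX) or col in ("utility", "madrs", "cost_aud"):
            df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    return TrialDataset(df, wave_schedule=tuple(schema))


@dataclass(frozen=True)
class UnitCostTable:
    """Service category -> AUD unit cost per occasion of service.

    Prices are 2018-19 Australian dollars.  The USD exchange rate is carried
    as metadata only and never enters a computation.
    """

    entries: Mapping[str, float]
    currency_year: str = "2018-19 AUD"
    fx_note: str = "Aus $1 = US $0.7058"

    def __post_init__(self) -> None:
        for cat, cost in self.entries.items():
            if not np.isfinite(cost) or cost <= 0:
                raise ValueError(f"unit cost for {cat!r} must be positive, got {cost}")

    def __getitem__(self, category: str) -> float:
        try:
            return float(self.entries[category])
        except KeyError:
            raise KeyError(
                f"service category {category!r} has no unit cost; add it to the unit-cost table"
            ) from None

    def require(self, categories: Sequence[str]) -> None:
        missing = [c for c in categories if c not in self.entries]
        if missing:
            raise KeyError(f"unit-cost table is missing categories: {missing}")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"category": list(self.entries), "unit_cost_aud": list(self.entries.values())}
        ).to_csv(path, index=False)


def read_unit_costs(path) -> UnitCostTable:
    """Read a two-column ``category, unit_cost_aud`` table."""
    df = pd.read_csv(path)
    cat_col, cost_col = df.columns[:2]
    if df[cat_col].duplicated().any():
        dup = df.loc[df[cat_col].duplicated(), cat_col].iloc[0]
        raise ValueError(f"duplicate unit-cost category {dup!r}")
    entries = {str(c): float(v) for c, v in zip(df[cat_col], df[cost_col])}
    return UnitCostTable(entries)


def write_results(results: pd.DataFrame, path, *, config=None, seed=None) -> None:
    """Write a result table as CSV, stamped with config hash and seed.

    The stamp lives in ``#``-prefixed header lines so that reading the file
    back with :func:`read_results` reproduces the values exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    if config is not None:
        lines.append(f"# config_hash={config_hash(config)}")
    if seed is not None:
        lines.append(f"# seed={seed}")
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
        results.to_csv(fh, index=False)


def read_results(path) -> pd.DataFrame:
    # round_trip parsing honours the full-stored-precision contract
    return pd.read_csv(path, comment="#", float_precision="round_trip")
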