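"""Microcosting of intervention delivery, pricing of self-reported service
use, per-participant 12-month health-sector totals, and the threshold and
population-rollout cost analyses.

All amounts are 2018-19 Australian dollars.  Website development/maintenance
is a fixed cost apportioned across the three internet arms by complexity
shares; equipment (computer leases) and personnel (forum monitoring and
debriefing wages, with a 25% employer-overhead loading) are apportioned by
the number of randomized participants per arm.  Per-arm delivery cost is
attached at the 3-month wave and summed with the priced 3-12-month service
use to form each participant's health-sector total; the baseline wave is a
covariate only.

Rounding discipline: internal arithmetic is exact decimal; displayed line
items are rounded half-up to cents, per-participant averages half-up to
whole dollars, and arm totals are the rounded sum of *unrounded* line items
(so a total can differ from the sum of displayed items by a cent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP, getcontext
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import FOLLOWUP_WAVES
from .data import TrialDataset, UnitCostTable, SERVICE_PREFIX

__all__ = [
    "InterventionLedger",
    "ArmCostBreakdown",
    "microcost_interventions",
    "personnel_cost_from_hours",
    "cost_service_use",
    "total_health_sector_cost",
    "threshold_intervention_cost",
    "population_rollout_cost",
    "demo_ledger",
    "default_unit_cost_table",
]

getcontext().prec = 28

_CENT = Decimal("0.01")
_DOLLAR = Decimal("1")


def _dec(x) -> Decimal:
    return x if isinstance(x, Decimal) else Decimal(str(x))


def _round_cents(x: Decimal) -> Decimal:
    return x.quantize(_CENT, rounding=ROUND_HALF_UP)


def _round_dollars(x: Decimal) -> Decimal:
    return x.quantize(_DOLLAR, rounding=ROUND_HALF_UP)


@dataclass(frozen=True)
class InterventionLedger:
    """Resource line items for delivering the three internet-based arms.

    website_total : development + maintenance cost, AUD, split across arms
        by ``complexity_shares`` (must sum to 1).
    equipment_total : computer lease total, apportioned by arm size.
    personnel_items : (label, total AUD) pairs, overhead already included;
        use :func:`personnel_cost_from_hours` to build a total from hours
        and a wage rate with the overhead loading.
    overhead_rate : employer overhead fraction applied to wages (0.25).
    arm_sizes : numbers randomized to arms 1..3.
    """

    website_total: float
    complexity_shares: tuple[float, float, float]
    equipment_total: float
    personnel_items: tuple[tuple[str, float], ...]
    arm_sizes: tuple[int, int, int]
    overhead_rate: float = 0.25

    def __post_init__(self) -> None:
        if abs(sum(self.complexity_shares) - 1.0) > 1e-9:
            raise ValueError("complexity shares must sum to 1")
        if self.website_total < 0 or self.equipment_total < 0:
            raise ValueError("ledger totals must be nonnegative")
        if any(t < 0 for _, t in self.personnel_items):
            raise ValueError("personnel totals must be nonnegative")
        if any(n <= 0 for n in self.arm_sizes):
            raise ValueError("arm sizes must be positive")

    @property
    def n_total(self) -> int:
        return int(sum(self.arm_sizes))


def personnel_cost_from_hours(hours: float, wage_rate: float, overhead_rate: float = 0.25) -> float:
    """Wage cost for ``hours`` at ``wage_rate`` AUD/h plus employer overhead."""
    return float(hours) * float(wage_rate) * (1.0 + float(overhead_rate))


@dataclass
class ArmCostBreakdown:
    """Per-arm intervention delivery costs.

    ``table`` has one row per line item plus a total row, columns arm_1..3
    and overall, in AUD rounded to cents; ``average_per_participant`` is
    whole AUD per randomized participant.
    """

    table: pd.DataFrame
    arm_totals: dict[int, float]           # rounded to cents
    overall_total: float
    average_per_participant: dict[int, float]  # whole AUD
    overall_average: float
    arm_sizes: tuple[int, int, int]
    _unrounded: pd.DataFrame | None = None

    def delivery_cost(self, arm: int) -> float:
        """Per-capita delivery cost attached to a participant of ``arm``."""
        return self.average_per_participant[arm]

    def variable_cost_per_participant(self, arm: int) -> float:
        """Equipment + personnel (non-website) cost per randomized participant."""
        u = self._unrounded
        col = f"arm_{arm}"
        nonweb = u.loc[u.index != "Website development and maintenance", col].sum()
        return float(nonweb) / self.arm_sizes[arm - 1]

    def website_cost(self, arm: int) -> float:
        return float(self._unrounded.loc["Website development and maintenance", f"arm_{arm}"])


def microcost_interventions(ledger: InterventionLedger) -> ArmCostBreakdown:
    """Apportion the resource ledger into the per-arm delivery cost table.

    Website lines follow the fixed complexity shares; equipment and each
    personnel line are split participant-proportionally (n_arm / n_total).
    """
    if ledger.n_total <= 0:
        raise ValueError("total participants must be positive")
    n = [_dec(k) for k in ledger.arm_sizes]
    N = _dec(ledger.n_total)

    rows: dict[str, list[Decimal]] = {}
    rows["Website development and maintenance"] = [
        _dec(ledger.website_total) * _dec(s) for s in ledger.complexity_shares
    ]
    rows["Desktop computers"] = [_dec(ledger.equipment_total) * k / N for k in n]
    for label, total in ledger.personnel_items:
        rows[label] = [_dec(total) * k / N for k in n]

    unrounded = pd.DataFrame(
        {f"arm_{a}": [float(rows[item][a - 1]) for item in rows] for a in (1, 2, 3)},
        index=list(rows),
    )

    arm_tot_unrounded = [sum(vals[a] for vals in rows.values()) for a in range(3)]
    arm_totals = {a + 1: float(_round_cents(t)) for a, t in enumerate(arm_tot_unrounded)}
    # grand total re-sums the displayed (rounded) arm totals
    overall_total = float(_round_cents(sum(_round_cents(t) for t in arm_tot_unrounded)))
    averages = {
        a + 1: float(_round_dollars(t / n[a])) for a, t in enumerate(arm_tot_unrounded)
    }
    overall_average = float(_round_dollars(_dec(overall_total) / N))

    table = pd.DataFrame(
        {
            f"arm_{a}": [float(_round_cents(rows[item][a - 1])) for item in rows]
            for a in (1, 2, 3)
        },
        index=pd.Index(list(rows), name="item"),
    )
    table["overall"] = [
        float(_round_cents(sum(rows[item]))) for item in rows
    ]
    total_row = {f"arm_{a}": arm_totals[a] for a in (1, 2, 3)}
    total_row["overall"] = overall_total
    avg_row = {f"arm_{a}": averages[a] for a in (1, 2, 3)}
    avg_row["overall"] = overall_average
    table = pd.concat(
        [
            table,
            pd.DataFrame([total_row, avg_row],
                         index=["Total intervention cost", "Average cost per trial participant"]),
        ]
    )
    table.index.name = "item"

    return ArmCostBreakdown(
        table=table,
        arm_totals=arm_totals,
        overall_total=overall_total,
        average_per_participant=averages,
        overall_average=overall_average,
        arm_sizes=ledger.arm_sizes,
        _unrounded=unrounded,
    )


# ---------------------------------------------------------------------------
# Service-use pricing and participant totals


def cost_service_use(dataset: TrialDataset, prices: UnitCostTable) -> TrialDataset:
    """Price each participant-wave's service counts: cost = sum count x unit cost.

    A wave with no questionnaire (all counts missing) gets a missing cost;
    an all-zero count row costs 0.  Every observed category must be priced.
    """
    prices.require(dataset.service_categories)
    out = dataset.copy()
    svc = out.df[out.service_columns]
    unit = np.array([prices[c] for c in dataset.service_categories])
    missing = svc.isna().all(axis=1)
    counts = svc.to_numpy(dtype=float)
    counts = np.nan_to_num(counts, nan=0.0)
    cost = counts @ unit
    cost[missing.to_numpy()] = np.nan
    out.df["cost_aud"] = cost
    return out


def total_health_sector_cost(
    dataset: TrialDataset, breakdown: ArmCostBreakdown
) -> pd.DataFrame:
    """Per-participant wave costs and the 3-12-month health-sector total.

    The arm's per-capita delivery cost is added at the 3-month wave; the
    total is delivery + sum of priced service use over months 3-12, and is
    missing when any follow-up wave is missing (base-case complete-sum
    rule).  Baseline cost is carried as a covariate, excluded from totals.

    Returns a frame indexed by participant with columns ``arm, sex,
    country, cost_0, cost_3, ..., cost_12, intervention_cost, total_3_12``.
    """
    if "cost_aud" not in dataset.df.columns:
        raise ValueError("dataset has no cost_aud column; run cost_service_use first")
    df = dataset.df
    wide = df.pivot(index="participant_id", columns="wave", values="cost_aud")
    wide = wide.reindex(columns=dataset.wave_schedule)
    wide.columns = [f"cost_{w}" for w in dataset.wave_schedule]
    meta = df[df["wave"] == dataset.wave_schedule[0]].set_index("participant_id")[
        ["arm", "sex", "country"]
    ]
    out = meta.join(wide)
    out["intervention_cost"] = out["arm"].map(breakdown.delivery_cost).astype(float)
    # delivery cost is attributed to the 3-month wave; the total is the same
    # either way (intervention + sum of service use over months 3-12)
    out["service_cost_3"] = out["cost_3"]
    out["cost_3"] = out["cost_3"] + out["intervention_cost"]
    follow = [f"cost_{w}" for w in FOLLOWUP_WAVES]
    out["total_3_12"] = out[follow].sum(axis=1, skipna=False)
    return out


def threshold_intervention_cost(
    arm_a_totals, arm_b_totals, current_delivery_cost_b: float
) -> float:
    """Delivery cost c* at which arm b's mean total equals arm a's.

    Since the delivery cost enters every participant's total additively,
    c* = current delivery cost + (mean_total_a - mean_total_b) in closed
    form; any mean-difference estimator may supply the two means.
    """
    a = np.asarray(arm_a_totals, dtype=float)
    b = np.asarray(arm_b_totals, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("threshold undefined: an arm has no complete totals")
    return float(current_delivery_cost_b + (a.mean() - b.mean()))


def population_rollout_cost(
    ledger: InterventionLedger,
    population_table: pd.DataFrame,
    prevalence: float | None = None,
    service_use_fraction: float = 0.677,
) -> dict:
    """Per-user delivery cost under population-level rollout.

    Potential users = sum over age-sex strata of population x prevalence x
    the fraction of prevalent cases using health services for their mental
    health.  The website (fixed) cost is spread over all users; equipment
    and personnel remain per-participant variable costs from the trial.

    ``population_table`` needs a ``population`` column and optionally a
    ``prevalence`` column (stratum-specific); a scalar ``prevalence``
    overrides/fills it.
    """
    pop = population_table["population"].to_numpy(dtype=float)
    if (pop <= 0).any():
        raise ValueError("population counts must be positive")
    if "prevalence" in population_table.columns and prevalence is None:
        prev = population_table["prevalence"].to_numpy(dtype=float)
    else:
        if prevalence is None:
            raise ValueError("supply a prevalence column or scalar")
        prev = np.full_like(pop, float(prevalence))
    users = float(np.sum(pop * prev) * service_use_fraction)
    if users <= 0:
        raise ValueError("zero potential users; rollout cost undefined")
    breakdown = microcost_interventions(ledger)
    out = {"users": users}
    for arm in (1, 2, 3):
        fixed = breakdown.website_cost(arm) / users
        variable = breakdown.variable_cost_per_participant(arm)
        out[arm] = fixed + variable
    return out


# ---------------------------------------------------------------------------
# Demo inputs


def demo_ledger() -> InterventionLedger:
    """The worked-example resource ledger used throughout the docs and demo.

    Website Aus $120,000 split 19/38/43% by arm complexity; two leased
    desktop computers; research-assistant and supervisor time for forum
    monitoring and debriefing (wage totals include the 25% overhead
    loading); 102/102/100 participants randomized.
    """
    return InterventionLedger(
        website_total=120_000.00,
        complexity_shares=(0.19, 0.38, 0.43),
        equipment_total=3590.14,
        personnel_items=(
            ("Research assistant (monitoring)", 44_046.65),
            ("Research assistant (debriefing)", 4404.66),
            ("Supervisor (debriefing)", 8015.85),
        ),
        arm_sizes=(102, 102, 100),
    )


def default_unit_cost_table() -> UnitCostTable:
    """Illustrative AUD unit costs for the four broad service categories
    captured by a service-use questionnaire (medical, psychological, acute
    care, support).  Synthetic round figures for simulation and demos, not
    a published schedule.
    """
    return UnitCostTable(
        {
            "medical": 150.0,
            "psychological": 180.0,
            "acute_care": 1200.0,
            "support": 60.0,
        }
    )
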