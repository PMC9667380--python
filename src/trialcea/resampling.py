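"""Economic inference: bootstrap of incremental (cost, effect) pairs,
ICER/dominance classification, reordered-percentile confidence intervals,
cost-effectiveness planes and acceptability curves, and the
imputation-nested bootstrap for missing data.

Conventions.  A pair (dC, dE) lives on the cost-effectiveness plane with
the effect on the abscissa and the cost on the ordinate.  The intervention
is *dominant* when it is cheaper and more effective (south-east quadrant),
*dominated* when costlier and less effective (north-west); otherwise the
ICER dC/dE is a meaningful trade-off.  The cost-effectiveness
acceptability curve (CEAC) reports, at each willingness-to-pay lambda, the
fraction of bootstrap replicates with positive net monetary benefit
lambda*dE - dC (strict inequality; ties count as not cost-effective).

The reordered percentile CI orders replicates by angle around the plane —
starting at the positive-cost axis and proceeding counterclockwise
(NW -> SW -> SE -> NE -> back) so that economic preference is monotone
along the ordering — and takes the alpha/2 and 1-alpha/2 order statistics;
a bound in the SE quadrant is reported as "dominant", in the NW as
"dominated", else as its ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig, FOLLOWUP_WAVES
from .estimation import fit_outcome_glm, EstimationError
from .impute import chained_pmm_impute

__all__ = [
    "IncrementalPair",
    "ICERResult",
    "BootstrapDistribution",
    "CEACCurve",
    "icer_point",
    "bootstrap_incrementals",
    "reordered_percentile_ci",
    "ceac",
    "ce_plane_export",
    "plot_ce_plane",
    "plot_ceac",
    "adjusted_mean_difference_estimator",
    "glm_incremental_estimator",
    "mi_nested_bootstrap",
]

EFFECT_TOL = 1e-9  # |dE| below this: report via net monetary benefit instead


@dataclass(frozen=True)
class IncrementalPair:
    delta_cost: float
    delta_effect: float
    effect_kind: str = "qaly"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.delta_cost) and np.isfinite(self.delta_effect)):
            raise ValueError("incremental pair must be finite")


@dataclass(frozen=True)
class ICERResult:
    """Ratio or dominance label with its cost-effectiveness-plane quadrant."""

    kind: str       # "ratio" | "dominant" | "dominated" | "undefined"
    quadrant: str   # NE | SE | SW | NW
    value: float | None = None      # AUD per effect unit when kind == "ratio"
    nmb_at: float | None = None     # NMB fallback threshold used, if any
    nmb: float | None = None

    def __str__(self) -> str:
        if self.kind == "ratio":
            return f"{self.value:,.0f}"
        return self.kind


def icer_point(pair: IncrementalPair, *, wtp: float | None = None) -> ICERResult:
    """Classify one incremental pair.

    dominant iff dC < 0 and dE > 0; dominated iff dC > 0 and dE < 0;
    otherwise the ratio dC/dE (rounded to whole AUD only at display).  An
    effect difference below tolerance makes the ratio undefined; the net
    monetary benefit at ``wtp`` is reported instead.
    """
    dc, de = pair.delta_cost, pair.delta_effect
    if de > 0:
        quadrant = "NE" if dc > 0 else "SE"
    elif de < 0:
        quadrant = "NW" if dc > 0 else "SW"
    else:
        quadrant = "NE" if dc > 0 else "SE"
    if abs(de) < EFFECT_TOL:
        lam = 0.0 if wtp is None else wtp
        return ICERResult(kind="undefined", quadrant=quadrant,
                          nmb_at=lam, nmb=lam * de - dc)
    if dc < 0 and de > 0:
        return ICERResult(kind="dominant", quadrant="SE")
    if dc > 0 and de < 0:
        return ICERResult(kind="dominated", quadrant="NW")
    return ICERResult(kind="ratio", quadrant=quadrant, value=dc / de)


@dataclass
class BootstrapDistribution:
    """B resampled incremental pairs around a point estimate."""

    replicates: np.ndarray          # (B, 2): columns dC, dE
    point_estimate: IncrementalPair
    effect_kind: str
    seed: int
    estimator: str = ""
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        self.replicates = np.asarray(self.replicates, dtype=float)
        if self.replicates.ndim != 2 or self.replicates.shape[1] != 2:
            raise ValueError("replicates must be (B, 2)")

    @property
    def B(self) -> int:
        return self.replicates.shape[0]

    @property
    def delta_cost(self) -> np.ndarray:
        return self.replicates[:, 0]

    @property
    def delta_effect(self) -> np.ndarray:
        return self.replicates[:, 1]


def _stratified_indices(arms: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Resample with replacement within each arm, preserving arm sizes."""
    out = np.empty(len(arms), dtype=int)
    pos = 0
    for a in np.unique(arms):
        idx = np.flatnonzero(arms == a)
        out[pos:pos + len(idx)] = rng.choice(idx, size=len(idx), replace=True)
        pos += len(idx)
    return out


def bootstrap_incrementals(
    table: pd.DataFrame,
    estimator: Callable[[pd.DataFrame], tuple[float, float]],
    config: AnalysisConfig,
    *,
    effect_kind: str = "qaly",
    tag: str = "",
    max_redraws_factor: int = 10,
) -> BootstrapDistribution:
    """Nonparametric bootstrap of an incremental-pair estimator.

    Resampling is with replacement *within arm* (the design's arm sizes are
    preserved); the estimator maps a per-participant table to (dC, dE).  A
    replicate on which the estimator fails is redrawn — every distribution
    has exactly B replicates — and the redraw count is recorded.
    """
    arms = table["arm"].to_numpy()
    rng = config.rng(stream=11)
    point = estimator(table)
    reps = np.empty((config.bootstrap_B, 2))
    redrawn = 0
    budget = max_redraws_factor * config.bootstrap_B
    b = 0
    while b < config.bootstrap_B:
        idx = _stratified_indices(arms, rng)
        try:
            dc, de = estimator(table.iloc[idx])
        except Exception:
            redrawn += 1
            if redrawn > budget:
                raise RuntimeError("bootstrap: too many failed replicates")
            continue
        reps[b] = (dc, de)
        b += 1
    return BootstrapDistribution(
        replicates=reps,
        point_estimate=IncrementalPair(point[0], point[1], effect_kind),
        effect_kind=effect_kind,
        seed=config.seed,
        estimator=tag,
        n_redrawn=redrawn,
    )


# ---------------------------------------------------------------------------
# Reordered percentile CI


def _angular_key(dc: np.ndarray, de: np.ndarray) -> np.ndarray:
    """Position along the counterclockwise ordering that starts at the
    positive-cost axis: 0 at due north, through NW, SW, SE, NE."""
    phi = np.arctan2(dc, de)              # angle in the (effect, cost) plane
    return np.mod(phi - np.pi / 2.0, 2.0 * np.pi)


def _bound_label(dc: float, de: float) -> ICERResult:
    return icer_point(IncrementalPair(dc, de))


@dataclass
class ReorderedCI:
    lower: ICERResult
    upper: ICERResult
    alpha: float
    spans_all_quadrants: bool
    lower_pair: tuple[float, float]
    upper_pair: tuple[float, float]

    def __str__(self) -> str:
        tail = " (spans all quadrants)" if self.spans_all_quadrants else ""
        return f"({self.lower} to {self.upper}){tail}"


def reordered_percentile_ci(dist: BootstrapDistribution, alpha: float = 0.05) -> ReorderedCI:
    """Reordered bootstrap percentile CI for an ICER.

    Replicates are sorted by the counterclockwise angular ordering; the
    bounds are the ceil(B*alpha/2)-th and floor(B*(1-alpha/2))-th order
    statistics.  Each bound carries a dominance label when it falls in the
    SE or NW quadrant; a distribution spreading over all four quadrants is
    flagged as hard to interpret.
    """
    if dist.B < 100:
        raise ValueError("reordered percentile CI needs at least 100 replicates")
    return _reordered_ci_impl(dist.replicates, alpha)


def _reordered_ci_impl(reps: np.ndarray, alpha: float) -> ReorderedCI:
    dc, de = reps[:, 0], reps[:, 1]
    B = len(reps)
    order = np.argsort(_angular_key(dc, de), kind="stable")
    lo_i = order[max(int(np.ceil(B * alpha / 2.0)), 1) - 1]
    hi_i = order[int(np.floor(B * (1.0 - alpha / 2.0))) - 1]
    quads = set()
    quads.update(np.unique(np.where(de > 0, np.where(dc > 0, "NE", "SE"),
                                    np.where(dc > 0, "NW", "SW"))))
    return ReorderedCI(
        lower=_bound_label(dc[lo_i], de[lo_i]),
        upper=_bound_label(dc[hi_i], de[hi_i]),
        alpha=alpha,
        spans_all_quadrants=len(quads & {"NE", "SE", "SW", "NW"}) == 4,
        lower_pair=(float(dc[lo_i]), float(de[lo_i])),
        upper_pair=(float(dc[hi_i]), float(de[hi_i])),
    )


# ---------------------------------------------------------------------------
# CEAC and CE plane


@dataclass
class CEACCurve:
    lambdas: np.ndarray
    probability: np.ndarray
    effect_kind: str = "qaly"

    def at(self, lam: float) -> float:
        i = int(np.argmin(np.abs(self.lambdas - lam)))
        if abs(self.lambdas[i] - lam) > 1e-9:
            raise KeyError(f"lambda {lam} not on the grid")
        return float(self.probability[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.lambdas, "prob_cost_effective": self.probability})


def ceac(dist: BootstrapDistribution, grid: Sequence[float]) -> CEACCurve:
    """Probability cost-effective at each willingness-to-pay lambda:
    fraction of replicates with lambda*dE - dC > 0."""
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    nmb = grid[:, None] * dist.delta_effect[None, :] - dist.delta_cost[None, :]
    prob = (nmb > 0).mean(axis=1)
    return CEACCurve(lambdas=grid, probability=prob, effect_kind=dist.effect_kind)


def ce_plane_export(dist: BootstrapDistribution) -> pd.DataFrame:
    """Lossless table of the B replicates plus the point estimate; effect on
    the abscissa, cost on the ordinate."""
    df = pd.DataFrame(
        {
            "delta_effect": dist.delta_effect,
            "delta_cost": dist.delta_cost,
            "kind": "replicate",
        }
    )
    point = pd.DataFrame(
        {
            "delta_effect": [dist.point_estimate.delta_effect],
            "delta_cost": [dist.point_estimate.delta_cost],
            "kind": ["point_estimate"],
        }
    )
    return pd.concat([df, point], ignore_index=True)


def plot_ce_plane(dist: BootstrapDistribution, path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(dist.delta_effect, dist.delta_cost, s=6, alpha=0.4, label="bootstrap replicates")
    ax.scatter([dist.point_estimate.delta_effect], [dist.point_estimate.delta_cost],
               color="red", marker="D", zorder=3, label="point estimate")
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    unit = "QALYs" if dist.effect_kind == "qaly" else "MADRS points (improvement)"
    ax.set_xlabel(f"Incremental effect ({unit})")
    ax.set_ylabel("Incremental cost (AUD)")
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ceac(curve: CEACCurve, path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.lambdas, curve.probability)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("Willingness to pay (AUD per effect unit)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Estimators for the bootstrap


def _ols_arm_difference(
    d: pd.DataFrame, outcome: str, baseline: str, comparison: tuple[int, int]
) -> float:
    """Adjusted arm difference by least squares on complete rows."""
    d = d.dropna(subset=[outcome, baseline])
    if d["arm"].nunique() < len(set(comparison)):
        raise EstimationError("an arm has no complete observations in this resample")
    X = np.column_stack(
        [
            np.ones(len(d)),
            (d["arm"] == 2).to_numpy(float),
            (d["arm"] == 3).to_numpy(float),
            d[baseline].to_numpy(float),
            (d["sex"] == "female").to_numpy(float),
            (d["country"] == "Australia").to_numpy(float),
            (d["country"] == "other").to_numpy(float),
        ]
    )
    beta, *_ = np.linalg.lstsq(X, d[outcome].to_numpy(float), rcond=None)
    arm_coef = {1: 0.0, 2: beta[1], 3: beta[2]}
    a, b = comparison
    return float(arm_coef[a] - arm_coef[b])


def adjusted_mean_difference_estimator(
    comparison: tuple[int, int],
    effect_kind: str = "qaly",
    *,
    cost_col: str = "total_3_12",
    adjusted: bool = True,
) -> Callable[[pd.DataFrame], tuple[float, float]]:
    """Complete-case estimator of (dC, dE) on a per-participant table.

    dC is the covariate-adjusted difference in 12-month totals; dE is the
    adjusted QALY difference, or the adjusted 12-month depression-score
    difference with the improvement sign convention.
    """

    def run(t: pd.DataFrame) -> tuple[float, float]:
        a, b = comparison
        if adjusted:
            dc = _ols_arm_difference(t, cost_col, "cost_0", comparison)
            if effect_kind == "qaly":
                de = _ols_arm_difference(t, "qaly", "util_0", comparison)
            else:
                de = -_ols_arm_difference(t, "madrs_12", "madrs_0", comparison)
        else:
            ta, tb = t[t["arm"] == a], t[t["arm"] == b]
            dc = ta[cost_col].mean() - tb[cost_col].mean()
            if effect_kind == "qaly":
                de = ta["qaly"].mean() - tb["qaly"].mean()
            else:
                de = tb["madrs_12"].mean() - ta["madrs_12"].mean()
        return float(dc), float(de)

    return run


def glm_incremental_estimator(
    comparison: tuple[int, int],
    effect_kind: str = "qaly",
    config: AnalysisConfig | None = None,
) -> Callable[[pd.DataFrame], tuple[float, float]]:
    """(dC, dE) from identity-link GLMs: gamma for the cost total,
    inverse-Gaussian for QALYs (gaussian for the depression score)."""
    config = config or AnalysisConfig()

    def run(t: pd.DataFrame) -> tuple[float, float]:
        cost_ests, _ = fit_outcome_glm(t, "total_3_12", "cost_0", "gamma", config)
        if effect_kind == "qaly":
            eff_ests, _ = fit_outcome_glm(t, "qaly", "util_0", "inverse_gaussian", config)
            sign = 1.0
        else:
            eff_ests, _ = fit_outcome_glm(t, "madrs_12", "madrs_0", "gaussian", config)
            sign = -1.0
        a, b = comparison

        def get(ests):
            if (a, b) in ests:
                return ests[(a, b)].diff
            return -ests[(b, a)].diff

        return float(get(cost_ests)), float(sign * get(eff_ests))

    return run


# ---------------------------------------------------------------------------
# Imputation nested in the bootstrap


def _impute_and_estimate(
    t: pd.DataFrame,
    comparison: tuple[int, int],
    effect_kind: str,
    config: AnalysisConfig,
    rng: np.random.Generator,
    waves=FOLLOWUP_WAVES,
) -> tuple[float, float]:
    cost_cols = [f"cost_{w}" for w in waves]
    util_cols = [f"util_{w}" for w in waves]
    madrs_cols = [f"madrs_{w}" for w in waves]
    targets = [c for trio in zip(cost_cols, util_cols, madrs_cols) for c in trio]
    predictors = ["cost_0", "util_0", "madrs_0", "_female", "_cau", "_cot"]
    t = t.copy()
    t["_female"] = (t["sex"] == "female").astype(float)
    t["_cau"] = (t["country"] == "Australia").astype(float)
    t["_cot"] = (t["country"] == "other").astype(float)
    targets = [c for c in targets if c in t.columns]
    # impute separately within each randomized group: donors and imputation
    # models never cross arms, so treatment contrasts are not shrunk toward
    # the pooled mean at high missingness
    parts = []
    for _, g in t.groupby("arm", sort=True):
        parts.append(
            chained_pmm_impute(
                g, targets, predictors, rng,
                cycles=config.mice_cycles, donors=config.pmm_donors,
            )
        )
    filled = pd.concat(parts)
    filled["total_3_12"] = filled[cost_cols].sum(axis=1)
    from .outcomes import qaly_from_wave_utilities  # wide frame -> QALYs

    filled["qaly"] = qaly_from_wave_utilities(filled, waves=(0, *waves))
    return glm_incremental_estimator(comparison, effect_kind, config)(filled)


def mi_nested_bootstrap(
    table: pd.DataFrame,
    comparison: tuple[int, int],
    config: AnalysisConfig,
    *,
    effect_kind: str = "qaly",
) -> BootstrapDistribution:
    """Single imputation nested in the bootstrap.

    For each of B stratified resamples: complete the wave-level costs,
    utilities and depression scores once by chained equations with
    predictive mean matching, then compute the GLM-based incremental pair.
    With no missing data this reduces to the plain GLM bootstrap.  The
    point estimate is the same impute-then-GLM pipeline on the original
    sample.  Resamples where imputation or the GLM fails (for instance an
    all-missing wave-arm cell) are redrawn and counted.
    """
    # the resampling stream matches bootstrap_incrementals, so with no
    # missing data the distribution equals the plain GLM bootstrap
    arms = table["arm"].to_numpy()
    rng = config.rng(stream=11)
    irng = config.rng(stream=22)
    point = _impute_and_estimate(table, comparison, effect_kind, config, irng)
    reps = np.empty((config.bootstrap_B, 2))
    redrawn = 0
    b = 0
    while b < config.bootstrap_B:
        idx = _stratified_indices(arms, rng)
        try:
            reps[b] = _impute_and_estimate(
                table.iloc[idx].reset_index(drop=True), comparison, effect_kind, config, irng
            )
        except Exception:
            redrawn += 1
            if redrawn > 10 * config.bootstrap_B:
                raise RuntimeError("imputation-nested bootstrap: too many failed replicates")
            continue
        b += 1
    return BootstrapDistribution(
        replicates=reps,
        point_estimate=IncrementalPair(point[0], point[1], effect_kind),
        effect_kind=effect_kind,
        seed=config.seed,
        estimator=f"mi_nested_glm_{comparison[0]}v{comparison[1]}",
        n_redrawn=redrawn,
    )
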