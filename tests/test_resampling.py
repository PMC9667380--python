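"""Bootstrap engine, ICER classification, reordered percentile CIs, CEAC,
CE-plane export, and the imputation-nested bootstrap."""

import functools
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trialcea.config import AnalysisConfig
from trialcea.impute import chained_pmm_impute
from trialcea.resampling import (
    BootstrapDistribution,
    IncrementalPair,
    adjusted_mean_difference_estimator,
    bootstrap_incrementals,
    ce_plane_export,
    ceac,
    glm_incremental_estimator,
    icer_point,
    mi_nested_bootstrap,
    reordered_percentile_ci,
    _reordered_ci_impl,
)


# ---------------------------------------------------------------------------
# brute-force angular ordering oracle (no trigonometry): bucket the eight
# compass sectors in the counterclockwise order that starts at due north
# (positive cost axis), then sort within sector by the cross-product
# comparator


def _sector(de, dc):
    if de == 0 and dc > 0:
        return 0          # N
    if de < 0 and dc > 0:
        return 1          # NW
    if de < 0 and dc == 0:
        return 2          # W
    if de < 0 and dc < 0:
        return 3          # SW
    if de == 0 and dc < 0:
        return 4          # S
    if de > 0 and dc < 0:
        return 5          # SE
    if de > 0 and dc == 0:
        return 6          # E
    return 7              # NE


def oracle_angular_order(reps):
    def cmp(i, j):
        (ci, ei), (cj, ej) = reps[i], reps[j]
        si, sj = _sector(ei, ci), _sector(ej, cj)
        if si != sj:
            return -1 if si < sj else 1
        cross = ei * cj - ci * ej  # positive when j is counterclockwise of i
        if cross > 0:
            return -1
        if cross < 0:
            return 1
        return -1 if i < j else 1  # stable on ties
    return sorted(range(len(reps)), key=functools.cmp_to_key(cmp))


def oracle_ci(reps, alpha=0.05):
    order = oracle_angular_order(reps)
    B = len(reps)
    lo = order[max(int(np.ceil(B * alpha / 2.0)), 1) - 1]
    hi = order[int(np.floor(B * (1 - alpha / 2.0))) - 1]
    return reps[lo], reps[hi]


def _dist(reps, point=None, kind="qaly"):
    reps = np.asarray(reps, dtype=float)
    if point is None:
        point = IncrementalPair(reps[:, 0].mean(), reps[:, 1].mean(), kind)
    return BootstrapDistribution(replicates=reps, point_estimate=point,
                                 effect_kind=kind, seed=0)


class TestICERPoint:
    @pytest.mark.parametrize(
        "dc, de, expected",
        [
            (743.0, 3.6, 206), (113.0, 1.1, 103),
            (7798.0, 0.7, 11140), (466.0, 0.3, 1553),
        ],
    )
    def test_published_style_ratios(self, dc, de, expected):
        res = icer_point(IncrementalPair(dc, de, "madrs"))
        assert res.kind == "ratio"
        assert round(res.value) == expected

    def test_dominance_labels(self):
        assert icer_point(IncrementalPair(-2858.0, 3.8, "madrs")).kind == "dominant"
        assert icer_point(IncrementalPair(7798.0, -0.004, "qaly")).kind == "dominated"

    @pytest.mark.parametrize("dc", [-1.0, 0.0, 1.0])
    @pytest.mark.parametrize("de", [-1.0, 0.0, 1.0])
    def test_exhaustive_sign_grid(self, dc, de):
        res = icer_point(IncrementalPair(dc, de), wtp=50_000.0)
        if abs(de) < 1e-9:
            assert res.kind == "undefined"
            assert res.nmb == pytest.approx(50_000.0 * de - dc)
        elif dc < 0 and de > 0:
            assert res.kind == "dominant" and res.quadrant == "SE"
        elif dc > 0 and de < 0:
            assert res.kind == "dominated" and res.quadrant == "NW"
        else:
            assert res.kind == "ratio"
            assert res.value == pytest.approx(dc / de)


class TestBootstrap:
    def _toy_table(self, n=30, rng=None, degenerate=False):
        rng = rng or np.random.default_rng(0)
        arm = np.repeat([1, 2, 3], n)
        if degenerate:
            cost = np.where(arm == 1, 5000.0, np.where(arm == 2, 4000.0, 6000.0))
            qaly = np.where(arm == 1, 0.6, np.where(arm == 2, 0.62, 0.59))
            cost0 = np.full(arm.shape, 100.0)
            util0 = np.full(arm.shape, 0.6)
        else:
            cost = 5000 + rng.normal(0, 800, arm.shape)
            qaly = 0.6 + rng.normal(0, 0.05, arm.shape)
            cost0 = rng.gamma(1, 500, arm.shape)
            util0 = 0.6 + rng.normal(0, 0.05, arm.shape)
        return pd.DataFrame(
            {
                "arm": arm,
                "sex": rng.choice(["female", "male"], arm.shape),
                "country": rng.choice(["US", "Australia", "other"], arm.shape),
                "total_3_12": cost, "qaly": qaly, "cost_0": cost0, "util_0": util0,
            }
        )

    def test_degenerate_data_gives_point_mass(self):
        t = self._toy_table(degenerate=True)
        cfg = AnalysisConfig(seed=1, bootstrap_B=50)
        # sex/country vary but carry no signal; use the unadjusted estimator
        # so every resample reproduces the identical arm means
        d = bootstrap_incrementals(
            t, adjusted_mean_difference_estimator((2, 1), "qaly", adjusted=False), cfg
        )
        assert np.allclose(d.delta_cost, -1000.0)
        assert np.allclose(d.delta_effect, 0.02)

    def test_deterministic_given_seed(self):
        t = self._toy_table()
        cfg = AnalysisConfig(seed=9, bootstrap_B=80)
        est = adjusted_mean_difference_estimator((2, 1), "qaly")
        d1 = bootstrap_incrementals(t, est, cfg)
        d2 = bootstrap_incrementals(t, est, cfg)
        assert np.array_equal(d1.replicates, d2.replicates)
        d3 = bootstrap_incrementals(t, est, cfg.with_(seed=10))
        assert not np.array_equal(d1.replicates, d3.replicates)

    def test_stratification_preserves_arm_sizes(self):
        t = self._toy_table()
        counts = []

        def spy(tab):
            counts.append(tab["arm"].value_counts().to_dict())
            return 0.0, 0.0

        cfg = AnalysisConfig(seed=2, bootstrap_B=10)
        bootstrap_incrementals(t, spy, cfg)
        for c in counts:
            assert c == {1: 30, 2: 30, 3: 30}

    def test_replicate_mean_near_point_estimate(self, participant_table):
        cfg = AnalysisConfig(seed=3, bootstrap_B=400)
        d = bootstrap_incrementals(
            participant_table,
            adjusted_mean_difference_estimator((2, 1), "qaly"),
            cfg,
        )
        mc_se = d.delta_cost.std(ddof=1) / np.sqrt(d.B)
        assert abs(d.delta_cost.mean() - d.point_estimate.delta_cost) < 3 * mc_se

    def test_failing_replicates_redrawn(self):
        t = self._toy_table()
        calls = {"n": 0}

        def flaky(tab):
            calls["n"] += 1
            if calls["n"] % 3 == 2:
                raise RuntimeError("boom")
            return 1.0, 1.0

        cfg = AnalysisConfig(seed=4, bootstrap_B=20)
        d = bootstrap_incrementals(t, flaky, cfg)
        assert d.B == 20 and d.n_redrawn > 0


class TestReorderedCI:
    def test_forty_replicates_match_first_and_last_order_statistics(self):
        rng = np.random.default_rng(42)
        reps = np.column_stack([rng.normal(0, 1000, 40), rng.normal(0, 0.02, 40)])
        order = oracle_angular_order(reps)
        ci = _reordered_ci_impl(reps, alpha=0.05)
        assert ci.lower_pair == tuple(reps[order[0]])
        assert ci.upper_pair == tuple(reps[order[38]])

    def test_matches_bruteforce_oracle_on_random_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            B = int(rng.integers(100, 400))
            reps = np.column_stack(
                [rng.normal(rng.normal(0, 2000), 3000, B),
                 rng.normal(rng.normal(0, 0.01), 0.02, B)]
            )
            lo, hi = oracle_ci(reps)
            ci = _reordered_ci_impl(reps, 0.05)
            assert ci.lower_pair == tuple(lo)
            assert ci.upper_pair == tuple(hi)

    def test_all_dominant_replicates(self):
        rng = np.random.default_rng(1)
        reps = np.column_stack([-rng.gamma(2, 500, 200), rng.gamma(2, 0.01, 200)])
        ci = reordered_percentile_ci(_dist(reps))
        assert ci.lower.kind == "dominant" and ci.upper.kind == "dominant"
        assert not ci.spans_all_quadrants

    def test_spans_all_quadrants_flagged(self):
        rng = np.random.default_rng(2)
        reps = np.column_stack([rng.normal(0, 1000, 400), rng.normal(0, 0.02, 400)])
        ci = reordered_percentile_ci(_dist(reps))
        assert ci.spans_all_quadrants

    def test_needs_at_least_100_replicates(self):
        reps = np.ones((50, 2))
        with pytest.raises(ValueError, match="100"):
            reordered_percentile_ci(_dist(reps))


class TestCEAC:
    def test_all_dominant_curve_is_one(self):
        reps = np.column_stack([-np.ones(100) * 10, np.ones(100) * 0.01])
        curve = ceac(_dist(reps), [0.0, 1000.0, 50_000.0])
        assert np.all(curve.probability == 1.0)

    def test_hand_count_two_replicates(self):
        reps = np.array([[-1.0, -1.0], [1.0, 1.0]])
        curve = ceac(_dist(reps), [0.0, 1e9])
        assert curve.at(0.0) == 0.5          # only the cost-saving replicate
        assert curve.probability[-1] == 0.5  # only the effect-gaining one

    def test_lambda_zero_equals_cost_saving_fraction(self):
        rng = np.random.default_rng(3)
        reps = np.column_stack([rng.normal(0, 100, 500), rng.normal(0, 1, 500)])
        curve = ceac(_dist(reps), [0.0])
        assert curve.probability[0] == (reps[:, 0] < 0).mean()

    def test_exact_counting_measure(self):
        rng = np.random.default_rng(4)
        reps = np.column_stack([rng.normal(0, 2000, 300), rng.normal(0.005, 0.02, 300)])
        grid = [0.0, 10_000.0, 50_000.0, 100_000.0]
        curve = ceac(_dist(reps), grid)
        for lam, p in zip(grid, curve.probability):
            brute = sum(1 for dc, de in reps if lam * de - dc > 0) / len(reps)
            assert p == brute

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ceac(_dist(np.ones((100, 2))), [])


class TestCEPlaneExport:
    def test_lossless_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        reps = np.column_stack([rng.normal(0, 1000, 1000), rng.normal(0, 0.02, 1000)])
        d = _dist(reps)
        out = ce_plane_export(d)
        assert (out["kind"] == "replicate").sum() == 1000
        assert list(out.columns[:2]) == ["delta_effect", "delta_cost"]  # x then y
        p = tmp_path / "plane.csv"
        out.to_csv(p, index=False)
        back = pd.read_csv(p, float_precision="round_trip")
        reread = back[back["kind"] == "replicate"][["delta_cost", "delta_effect"]].to_numpy()
        assert np.array_equal(reread, reps)


class TestImputation:
    def _frame_with_missing(self, n=200, miss=0.4, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n)
        frame = pd.DataFrame(
            {
                "x": x,
                "a": 2 * x + rng.normal(0, 1, n),
                "b": -x + rng.normal(0, 1, n),
            }
        )
        for c in ("a", "b"):
            frame.loc[rng.random(n) < miss, c] = np.nan
        return frame

    def test_imputed_values_live_in_observed_support(self):
        frame = self._frame_with_missing()
        rng = np.random.default_rng(1)
        filled = chained_pmm_impute(frame, ["a", "b"], ["x"], rng)
        for c in ("a", "b"):
            observed = set(frame[c].dropna())
            imputed = filled.loc[frame[c].isna(), c]
            assert imputed.notna().all()
            assert all(v in observed for v in imputed)

    def test_observed_values_untouched(self):
        frame = self._frame_with_missing()
        filled = chained_pmm_impute(frame, ["a", "b"], ["x"], np.random.default_rng(2))
        for c in ("a", "b"):
            m = frame[c].notna()
            assert np.array_equal(filled.loc[m, c], frame.loc[m, c])

    def test_all_missing_column_rejected(self):
        frame = self._frame_with_missing()
        frame["a"] = np.nan
        with pytest.raises(ValueError, match="no observed"):
            chained_pmm_impute(frame, ["a", "b"], ["x"], np.random.default_rng(3))


class TestMINestedBootstrap:
    def test_reduces_to_plain_glm_bootstrap_without_missingness(self, complete_table):
        cfg = AnalysisConfig(seed=6, bootstrap_B=25)
        plain = bootstrap_incrementals(
            complete_table, glm_incremental_estimator((2, 1), "qaly", cfg), cfg,
            effect_kind="qaly",
        )
        nested = mi_nested_bootstrap(complete_table, (2, 1), cfg)
        assert np.allclose(plain.replicates, nested.replicates)
        assert plain.point_estimate.delta_cost == pytest.approx(
            nested.point_estimate.delta_cost)

    def test_mcar_deletion_widens_interval_but_keeps_center(self, complete_table):
        cfg = AnalysisConfig(seed=7, bootstrap_B=250)
        full = mi_nested_bootstrap(complete_table, (2, 1), cfg)
        dropped = complete_table.copy()
        rng = np.random.default_rng(8)
        for w in (3, 6, 9, 12):
            m = rng.random(len(dropped)) < 0.4
            dropped.loc[m, [f"cost_{w}", f"util_{w}", f"madrs_{w}"]] = np.nan
        dropped["total_3_12"] = dropped[[f"cost_{w}" for w in (3, 6, 9, 12)]].sum(
            axis=1, skipna=False)
        part = mi_nested_bootstrap(dropped, (2, 1), cfg)
        # discarding 40% of every wave must inflate the replicate spread
        assert part.delta_cost.std(ddof=1) > full.delta_cost.std(ddof=1)
        spread = full.delta_cost.std(ddof=1)
        assert abs(part.point_estimate.delta_cost - full.point_estimate.delta_cost) < 3 * spread
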