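"""Correlation statistics, Wald test, and the positive/negative/neutral rule."""

import numpy as np
import pytest
from scipy import stats

from pvchr import (
    CircadianProfile,
    Label,
    LinearRampProfile,
    MechanismConfig,
    MechanismKind,
    Methodology,
    Scale,
    SimulationSpec,
    classify_cohort,
    classify_points,
    classify_record,
    cohort_proportions,
    ols_slope,
    pearson_r,
    results_to_frame,
    simulate_record,
    wald_p,
)
from pvchr.classify import (
    DegenerateInputError,
    InsufficientDataError,
    assign_label,
)


def brute_force_r_and_slope(x, y):
    """Two-pass covariance loop, independent of the vectorised path."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / (n - 1)
    vx = sum((a - mx) ** 2 for a in x) / (n - 1)
    vy = sum((b - my) ** 2 for b in y) / (n - 1)
    return cov / (vx**0.5 * vy**0.5), cov / vx


class TestPearsonAndSlope:
    def test_perfectly_linear(self):
        assert pearson_r([60, 70, 80], [30, 35, 40]) == pytest.approx(1.0)
        assert pearson_r([60, 70, 80], [40, 35, 30]) == pytest.approx(-1.0)

    def test_hand_worked_example(self):
        x, y = [1, 2, 3, 4], [2, 1, 4, 3]
        assert pearson_r(x, y) == pytest.approx(0.6)
        slope, _ = ols_slope(x, y)
        assert slope == pytest.approx(0.6)

    def test_bigeminy_slope(self):
        slope, _ = ols_slope([60, 70, 80], [30, 35, 40])
        assert slope == pytest.approx(0.5)

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            pearson_r([1, 2], [3, 4])
        with pytest.raises(DegenerateInputError, match="heart rate"):
            pearson_r([5, 5, 5], [1, 2, 3])
        with pytest.raises(DegenerateInputError, match="PVC"):
            ols_slope([1, 2, 3], [7, 7, 7])

    def test_matches_brute_force_and_library_oracles(self):
        """r and B vs a covariance loop (1e-12) and scipy/polyfit."""
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            x = rng.uniform(50, 110, n)
            y = rng.uniform(0, 300, n) + rng.uniform(-2, 2) * x
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r, b = pearson_r(x, y), ols_slope(x, y)[0]
            br, bb = brute_force_r_and_slope(list(x), list(y))
            assert r == pytest.approx(br, abs=1e-12)
            assert b == pytest.approx(bb, abs=1e-12)
            assert r == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-9)
            assert b == pytest.approx(np.polyfit(x, y, 1)[0], abs=1e-8)

    def test_sign_of_r_equals_sign_of_slope(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            x = rng.uniform(0, 1, 10)
            y = rng.uniform(0, 1, 10)
            assert np.sign(pearson_r(x, y)) == np.sign(ols_slope(x, y)[0])


class TestWaldP:
    def test_zero_correlation_gives_p_one(self):
        assert wald_p(0.0, 10) == pytest.approx(1.0)

    def test_derived_small_sample_value(self):
        # t = 0.6*sqrt(2)/0.8 = 1.0607 on 2 df -> p ~ 0.40
        assert wald_p(0.6, 4) == pytest.approx(0.40, abs=0.005)

    def test_matches_pearsonr_p(self):
        """Same p as scipy's exact Pearson test on the generating data."""
        x, y = [1.0, 2, 3, 4], [2.0, 1, 4, 3]
        assert wald_p(pearson_r(x, y), 4) == pytest.approx(
            stats.pearsonr(x, y).pvalue, abs=1e-10
        )

    def test_perfect_correlation_limit(self):
        assert wald_p(1.0, 5) == 0.0
        assert wald_p(0.999999, 5) < 1e-8

    def test_monotone_decreasing_in_n(self):
        """More intervals at the same r always shrink the p-value."""
        ps = [wald_p(0.3, n) for n in (5, 10, 50, 200, 1000)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_insufficient_n(self):
        with pytest.raises(InsufficientDataError):
            wald_p(0.5, 2)


class TestLabelRule:
    @pytest.mark.parametrize(
        "r, p, expected",
        [
            (0.4, 0.01, Label.POSITIVE),
            (-0.3, 0.02, Label.NEGATIVE),
            (0.2, 0.20, Label.NEUTRAL),
            (0.9, 0.05, Label.NEUTRAL),  # boundary atom p = .05
            (-0.9, 0.049999, Label.NEGATIVE),
        ],
    )
    def test_rule(self, r, p, expected):
        assert assign_label(r, p) is expected

    def test_rule_is_total(self):
        rng = np.random.default_rng(1)
        for r, p in zip(rng.uniform(-1, 1, 200), rng.uniform(0, 1, 200)):
            assert assign_label(r, p) in (
                Label.POSITIVE,
                Label.NEGATIVE,
                Label.NEUTRAL,
            )


class TestClassifyRecord:
    def test_ramp_bigeminy_positive(self, ramp_bigeminy_record):
        results = classify_record(
            ramp_bigeminy_record, (Methodology(60.0),), min_valid_intervals=10
        )
        whole = [r for r in results if r.day_index == -1]
        assert all(r.label is Label.POSITIVE for r in whole)
        assert all(r.slope_B > 0 for r in whole)

    def test_circadian_bigeminy_positive_all_methodologies(
        self, circadian_bigeminy_record
    ):
        """A stable NIB=1 rhythm classifies positive on every methodology."""
        from pvchr import STANDARD_METHODOLOGIES

        results = classify_record(circadian_bigeminy_record, STANDARD_METHODOLOGIES)
        usable = [r for r in results if r.label is not Label.UNUSABLE]
        assert len(usable) >= 6  # 4 whole-record + per-day rows
        assert all(r.label is Label.POSITIVE for r in usable)

    def test_zero_pvc_record_is_unusable_not_neutral(self):
        rec = simulate_record(
            SimulationSpec(
                record_id="Z",
                hr_profile=LinearRampProfile(60, 90, 3600.0, jitter_sd=0.0),
                duration_s=3600.0,
                seed=0,
            )
        )
        results = classify_record(rec, (Methodology(60.0),))
        whole = [r for r in results if r.day_index == -1][0]
        assert whole.label is Label.UNUSABLE
        assert "variance" in whole.reason

    def test_logistic_slope_sign_recovered(self):
        """Generative slope sign matches the classification at 1-min intervals."""
        for sign, want in ((+1, Label.POSITIVE), (-1, Label.NEGATIVE)):
            for seed in range(3):
                mech = MechanismConfig(
                    kind=MechanismKind.LOGISTIC_HR,
                    logistic_slope=sign * 0.08,
                    logistic_intercept=-sign * 0.08 * 75 - 1.5,
                )
                rec = simulate_record(
                    SimulationSpec(
                        record_id="L",
                        mechanism=mech,
                        hr_profile=CircadianProfile(75, 15, jitter_sd=3),
                        duration_s=4 * 3600.0,
                        seed=seed,
                    )
                )
                results = classify_record(rec, (Methodology(60.0),))
                whole = [r for r in results if r.day_index == -1][0]
                assert whole.label is want

    def test_log_scale_reports_dropped_zeros(self):
        rec = simulate_record(
            SimulationSpec(
                record_id="LG",
                mechanism=MechanismConfig(
                    kind=MechanismKind.LOGISTIC_HR,
                    logistic_slope=0.1,
                    logistic_intercept=-10.5,  # sparse PVCs: many zero minutes
                ),
                hr_profile=CircadianProfile(75, 15, jitter_sd=3),
                duration_s=4 * 3600.0,
                seed=2,
            )
        )
        lin = Methodology(60.0)
        log = Methodology(60.0, scale=Scale.LOG_LINEAR)
        res_lin = [r for r in classify_record(rec, (lin,)) if r.day_index == -1][0]
        res_log = [r for r in classify_record(rec, (log,)) if r.day_index == -1][0]
        assert res_log.n_zero_dropped > 0
        assert res_log.n_points == res_lin.n_points - res_log.n_zero_dropped


class TestCohortProportions:
    def test_small_example(self):
        rows = []
        for rid, label in zip("ABCD", ["positive", "positive", "neutral", "negative"]):
            rows.append(
                {
                    "record_id": rid,
                    "day_index": 0,
                    "methodology": "1 hr",
                    "scale": "linear",
                    "n_points": 24,
                    "n_zero_dropped": 0,
                    "r": 0.1,
                    "slope": 0.1,
                    "p": 0.01,
                    "label": label,
                }
            )
        import pandas as pd

        table = cohort_proportions(pd.DataFrame(rows))
        col = table[0]
        assert col[("1 hr", "positive")] == pytest.approx(0.5)
        assert col[("1 hr", "neutral")] == pytest.approx(0.25)
        assert col[("1 hr", "negative")] == pytest.approx(0.25)
        assert col.sum() == pytest.approx(1.0, abs=1e-9)

    def test_table_shape_on_synthetic_cohort(self):
        """Per-day proportions: methodologies x 3 classes by day columns."""
        from pvchr import cohort_preset, simulate_cohort

        recs = simulate_cohort(cohort_preset(n_records=6, days=2, seed=4))
        df = classify_cohort(
            recs, (Methodology(3600.0), Methodology(600.0), Methodology(60.0))
        )
        table = cohort_proportions(df)
        assert set(table.index.get_level_values("label")) == {
            "positive",
            "neutral",
            "negative",
        }
        assert len(table) == 9  # 3 methodologies x 3 classes
        sums = table.groupby("methodology").sum()
        for col in sums.columns:
            np.testing.assert_allclose(sums[col], 1.0, atol=1e-9)
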