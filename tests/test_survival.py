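"""Median split, Kaplan–Meier, log-rank calibration, and t-based accuracy CIs."""

import numpy as np
import pytest

from histoimmune.survival import (
    SurvivalRecord,
    accuracy_ci,
    km_estimate,
    logrank_test,
    median_split,
)
from histoimmune.survival import km_survival_at
from histoimmune.synthetic_data import simulate_survival_cohort


class TestMedianSplit:
    def test_even_distinct_values(self):
        labels = median_split({"a": 1, "b": 2, "c": 3, "d": 4})
        assert labels.threshold == 2.5
        assert labels.label_of == {"a": "low", "b": "low", "c": "high", "d": "high"}

    def test_ties_at_median_go_low(self):
        labels = median_split({"a": 1, "b": 2, "c": 2, "d": 3})
        assert labels.threshold == 2.0
        assert labels.label_of["b"] == labels.label_of["c"] == "low"
        assert labels.label_of["d"] == "high"

    def test_all_identical_errors(self):
        with pytest.raises(ValueError, match="identical"):
            median_split({f"p{i}": 5.0 for i in range(10)})

    def test_balanced_split_with_distinct_values(self):
        rng = np.random.default_rng(0)
        vals = {f"p{i}": float(v) for i, v in enumerate(rng.permutation(100))}
        labels = median_split(vals)
        assert abs(labels.n_high - labels.n_low) <= 1


class TestKaplanMeier:
    def test_all_censored_survival_stays_one(self):
        recs = [SurvivalRecord(f"p{i}", t, 0, "low") for i, t in enumerate([1.0, 2.0, 3.0])]
        km = km_estimate(recs)["low"]
        assert km.empty  # no event times; S(t) == 1 everywhere

    def test_hand_product_limit(self):
        recs = [SurvivalRecord(f"p{i}", t, 1, "g") for i, t in enumerate([1.0, 2.0, 3.0])]
        km = km_estimate(recs)["g"]
        np.testing.assert_allclose(km["survival"], [2 / 3, 1 / 3, 0.0])

    def test_tied_events_aggregated(self):
        recs = [SurvivalRecord(f"p{i}", t, 1, "g") for i, t in enumerate([1.0, 1.0, 2.0])]
        km = km_estimate(recs)["g"]
        assert list(km["time"]) == [1.0, 2.0]
        np.testing.assert_allclose(km["survival"], [1 / 3, 0.0])

    def test_equals_empirical_survivor_function_without_censoring(self):
        cohort = simulate_survival_cohort(300, 1.0, censor_rate=0.0, seed=3)
        km = km_estimate(cohort)
        times = np.array([r.time for r in cohort if r.group == "high"])
        for t in np.quantile(times, [0.2, 0.5, 0.8]):
            empirical = np.mean(times > t)
            assert km_survival_at(km["high"], t) == pytest.approx(empirical, abs=1e-12)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        cohort = simulate_survival_cohort(100, 2.0, censor_rate=0.3, seed=4)
        km = km_estimate(cohort)["low"]
        lows = [r for r in cohort if r.group == "low"]
        kmf = KaplanMeierFitter().fit([r.time for r in lows], [r.event for r in lows])
        for _, row in km.iterrows():
            want = float(kmf.survival_function_at_times(row["time"]).iloc[0])
            assert row["survival"] == pytest.approx(want, abs=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalRecord("p", -1.0, 1, "g")


class TestLogRank:
    def test_identical_curves_null(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        recs = [SurvivalRecord(f"a{i}", t, 1, "high") for i, t in enumerate(times)]
        recs += [SurvivalRecord(f"b{i}", t, 1, "low") for i, t in enumerate(times)]
        stat, p = logrank_test(recs)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_group_label_swap_invariance(self):
        cohort = simulate_survival_cohort(80, 2.0, censor_rate=0.1, seed=5)
        stat1, p1 = logrank_test(cohort)
        swapped = [
            SurvivalRecord(r.patient_id, r.time, r.event, "low" if r.group == "high" else "high")
            for r in cohort
        ]
        stat2, p2 = logrank_test(swapped)
        assert stat1 == pytest.approx(stat2, abs=1e-9)
        assert p1 == pytest.approx(p2, abs=1e-9)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        for seed in range(5):
            cohort = simulate_survival_cohort(120, 1.8, censor_rate=0.2, seed=seed)
            stat, p = logrank_test(cohort)
            hi = [r for r in cohort if r.group == "high"]
            lo = [r for r in cohort if r.group == "low"]
            res = ll_logrank(
                [r.time for r in hi], [r.time for r in lo],
                event_observed_A=[r.event for r in hi], event_observed_B=[r.event for r in lo],
            )
            assert stat == pytest.approx(res.test_statistic, rel=1e-9)
            assert p == pytest.approx(res.p_value, rel=1e-9)

    def test_requires_two_groups(self):
        recs = [SurvivalRecord("a", 1.0, 1, "high")]
        with pytest.raises(ValueError):
            logrank_test(recs)

    def test_type_i_error_near_nominal(self):
        rejections = 0
        n_reps = 400
        for s in range(n_reps):
            cohort = simulate_survival_cohort(100, 1.0, censor_rate=0.1, seed=10_000 + s)
            _, p = logrank_test(cohort)
            rejections += p < 0.05
        rate = rejections / n_reps
        assert 0.02 < rate < 0.08

    def test_power_at_hazard_ratio_two(self):
        rejections = 0
        n_reps = 150
        for s in range(n_reps):
            cohort = simulate_survival_cohort(200, 2.0, censor_rate=0.2, seed=20_000 + s)
            _, p = logrank_test(cohort)
            rejections += p < 0.05
        assert rejections / n_reps > 0.8


class TestAccuracyCI:
    def test_zero_variance_runs(self):
        mean, lo, hi = accuracy_ci(per_run_accuracies=[0.8, 0.8, 0.8])
        assert mean == pytest.approx(0.8)
        assert lo == pytest.approx(mean) and hi == pytest.approx(mean)

    def test_two_runs_t_quantile(self):
        mean, lo, hi = accuracy_ci(per_run_accuracies=[0.6, 0.8])
        assert mean == pytest.approx(0.7)
        half = 12.7062047364 * np.std([0.6, 0.8], ddof=1) / np.sqrt(2)
        assert hi - mean == pytest.approx(half, rel=1e-6)
        assert lo <= mean <= hi

    def test_single_run_mean_only(self):
        mean, lo, hi = accuracy_ci(per_run_accuracies=[0.9])
        assert mean == 0.9 and lo is None and hi is None

    def test_pooled_point_estimate(self):
        mean, lo, hi = accuracy_ci(correct=45, total=50)
        assert mean == 0.9 and lo is None

    def test_needs_some_input(self):
        with pytest.raises(ValueError):
            accuracy_ci()


class TestEndToEndPlantedEffect:
    def test_median_split_logrank_flags_planted_type_only(self):
        """A cell type whose high group carries hazard ratio 2 is flagged at
        p < 0.05; a no-effect cell type is not flagged (at seed level)."""
        rng = np.random.default_rng(42)
        n = 200
        cohort = simulate_survival_cohort(n, 2.0, censor_rate=0.1, seed=7)
        # effect type: fraction correlates with the planted group
        frac_effect = {
            r.patient_id: (0.6 if r.group == "high" else 0.4) + rng.normal(0, 0.05)
            for r in cohort
        }
        # null type: fraction independent of group
        frac_null = {r.patient_id: float(rng.random()) for r in cohort}
        out = {}
        for name, fr in [("effect", frac_effect), ("null", frac_null)]:
            labels = median_split(fr, cell_type=name)
            recs = [
                SurvivalRecord(r.patient_id, r.time, r.event, labels.label_of[r.patient_id])
                for r in cohort
            ]
            out[name] = logrank_test(recs)[1]
        assert out["effect"] < 0.05
        assert out["null"] > 0.05
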