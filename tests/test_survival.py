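"""Kaplan–Meier estimation and Gompertz aging-rate fitting."""

import numpy as np
import pandas as pd
import pytest

from bactaging import (compare_groups, event_table_from_lifespans,
                       fit_gompertz, fit_gompertz_curve, gompertz_hazard,
                       gompertz_isf, gompertz_survival, kaplan_meier,
                       sample_gompertz_lifespans)


def brute_force_km(durations, observed):
    """Hand product-limit estimate S(t) = prod_{t_i<=t} (1 - d_i/n_i)."""
    durations = np.asarray(durations, float)
    observed = np.asarray(observed, bool)
    times = np.unique(durations)
    surv = {}
    s = 1.0
    for t in times:
        at_risk = np.sum(durations >= t)
        deaths = np.sum((durations == t) & observed)
        if deaths:
            s *= 1.0 - deaths / at_risk
        surv[t] = s
    return surv


class TestKaplanMeier:
    def test_hand_worked_example(self):
        """Deaths at 2,2,5 and a censoring at 10 among n=4 cells."""
        c = kaplan_meier([2, 2, 5, 10], [1, 1, 1, 0])
        assert c.evaluate(2)[0] == pytest.approx(0.5)
        assert c.evaluate(5)[0] == pytest.approx(0.25)
        assert c.evaluate(1.9)[0] == 1.0

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(2, 21)
            durations = rng.integers(1, 8, n).astype(float)
            observed = rng.random(n) < 0.7
            if not observed.any():
                observed[0] = True
            curve = kaplan_meier(durations, observed)
            oracle = brute_force_km(durations, observed)
            for t, s in oracle.items():
                assert curve.evaluate(t)[0] == pytest.approx(s, abs=1e-12)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(5.0, 30)
        curve = kaplan_meier(x)
        for t in x:
            emp = np.mean(x > t)
            assert curve.evaluate(t)[0] == pytest.approx(emp, abs=1e-12)

    def test_everyone_dies_at_once(self):
        c = kaplan_meier([1.0, 1.0, 1.0])
        assert c.evaluate(1.0)[0] == 0.0

    def test_all_censored_warns_and_stays_flat(self):
        with pytest.warns(UserWarning):
            c = kaplan_meier([1, 2, 3], [0, 0, 0])
        assert c.all_censored
        assert np.all(c.survival == 1.0)


class TestGompertzClosedForms:
    def test_survival_starts_at_one(self):
        assert gompertz_survival(0.0, 0.3, 0.7) == 1.0

    def test_exponential_limit_value(self):
        # b -> 0: S(10) = exp(-0.1*10) = e^-1
        assert gompertz_survival(10.0, 0.1, 0.0) == pytest.approx(
            np.exp(-1), abs=1e-12)

    def test_median_lifespan(self):
        # S(t)=0.5 at t = ln(1 + (b/a) ln 2)/b = 20.71 h for a=0.01, b=0.1
        t_med = gompertz_isf(0.5, 0.01, 0.1)
        assert t_med == pytest.approx(20.71, abs=0.005)
        assert gompertz_survival(20.71, 0.01, 0.1) == pytest.approx(0.5,
                                                                    abs=0.005)

    def test_tiny_b_matches_exponential_uniformly(self):
        t = np.linspace(0, 50, 2001)
        diff = np.abs(gompertz_survival(t, 0.1, 1e-8) - np.exp(-0.1 * t))
        assert diff.max() < 1e-6

    def test_hazard_at_zero_and_doubling_time(self):
        a, b = 0.05, 0.4
        assert gompertz_hazard(0.0, a, b) == pytest.approx(a)
        assert gompertz_hazard(np.log(2) / b, a, b) == pytest.approx(2 * a)

    def test_hazard_matches_log_survival_slope(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = rng.uniform(0.005, 0.5)
            b = rng.uniform(0.0, 1.0)
            t_hi = gompertz_isf(1e-6, a, b)
            t = np.linspace(0.01, t_hi, 200)
            h = 1e-5
            lam_num = (np.log(gompertz_survival(t - h, a, b))
                       - np.log(gompertz_survival(t + h, a, b))) / (2 * h)
            lam = gompertz_hazard(t, a, b)
            assert np.max(np.abs(lam_num - lam) / lam) < 1e-6

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            gompertz_survival(-1.0, 0.1, 0.1)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gompertz_survival(1.0, -0.1, 0.1)
        with pytest.raises(ValueError):
            gompertz_hazard(1.0, 0.1, -0.1)


class TestGompertzFitting:
    def test_exact_curve_recovered_to_machine_precision(self):
        a, b = 0.01, 0.2
        t = np.linspace(0.5, 30, 60)
        s = gompertz_survival(t, a, b)
        a_hat, b_hat, rmse = fit_gompertz_curve(t, s)
        assert a_hat == pytest.approx(a, rel=1e-6)
        assert b_hat == pytest.approx(b, rel=1e-6)
        assert rmse < 1e-9

    @pytest.mark.parametrize("method", ["nls_on_km", "mle"])
    def test_parameter_recovery_from_samples(self, method):
        x = sample_gompertz_lifespans(0.01, 0.2, 1000, seed=42)
        fit = fit_gompertz(x, method=method, n_boot=0)
        assert abs(fit.b - 0.2) / 0.2 <= 0.10

    def test_exponential_data_pins_b_at_boundary(self):
        x = sample_gompertz_lifespans(0.1, 0.0, 1000, seed=3)
        fit = fit_gompertz(x, n_boot=0)
        assert fit.b <= 0.02

    def test_bootstrap_is_seed_reproducible(self):
        x = sample_gompertz_lifespans(0.02, 0.3, 200, seed=5)
        f1 = fit_gompertz(x, n_boot=50, seed=11)
        f2 = fit_gompertz(x, n_boot=50, seed=11)
        assert f1.ci95_b == f2.ci95_b

    def test_censoring_aware_mle_with_censored_tail(self):
        x = sample_gompertz_lifespans(0.01, 0.2, 2000, seed=6)
        cens = x > 15.0
        durations = np.where(cens, 15.0, x)
        fit = fit_gompertz(durations, ~cens, method="mle", n_boot=0)
        assert abs(fit.b - 0.2) / 0.2 <= 0.15

    def test_degenerate_data_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_gompertz(np.full(20, 3.0), n_boot=0)
        with pytest.raises(ValueError):
            fit_gompertz([1.0, 2.0, 3.0], [0, 0, 0], n_boot=0)

    def test_clock_label_carried(self):
        x = sample_gompertz_lifespans(0.05, 0.3, 200, seed=7)
        fit = fit_gompertz(x, n_boot=0, clock="generations")
        assert fit.clock == "generations"


class TestCompareGroups:
    def test_ordering_and_disjoint_flag(self):
        slow = fit_gompertz(sample_gompertz_lifespans(0.01, 0.05, 1000, seed=1),
                            n_boot=100, seed=1)
        fast = fit_gompertz(sample_gompertz_lifespans(0.01, 0.3, 1000, seed=2),
                            n_boot=100, seed=2)
        table, flagged = compare_groups({"slow": slow, "fast": fast})
        assert list(table["group"]) == ["slow", "fast"]
        assert ("slow", "fast") in flagged

    def test_identical_cohorts_not_flagged(self):
        x = sample_gompertz_lifespans(0.01, 0.2, 500, seed=4)
        f1 = fit_gompertz(x, n_boot=100, seed=1)
        f2 = fit_gompertz(x, n_boot=100, seed=2)
        _, flagged = compare_groups({"g1": f1, "g2": f2})
        assert flagged == []

    def test_missing_group_passes_through(self):
        f = fit_gompertz(sample_gompertz_lifespans(0.01, 0.2, 300, seed=8),
                         n_boot=0)
        table, _ = compare_groups({"ok": f, "failed": None})
        assert table.shape[0] == 2
        assert np.isnan(table.set_index("group").loc["failed", "b"])


class TestEventTable:
    def test_lysis_and_arrest_clocks(self):
        records = pd.DataFrame({
            "cell_id": ["a", "b"], "arl_h": [10.0, 12.0],
            "arl_generations": [20, 24], "prl_h": [5.0, 3.0],
            "censored": [False, True]})
        ev = event_table_from_lifespans(records, clock="hours", event="lysis")
        assert list(ev["duration"]) == [15.0, 15.0]
        assert list(ev["observed"]) == [True, False]
        ev2 = event_table_from_lifespans(records, clock="hours",
                                         event="arrest")
        assert list(ev2["duration"]) == [10.0, 12.0]
        ev3 = event_table_from_lifespans(records, clock="generations")
        assert list(ev3["duration"]) == [20.0, 24.0]

    def test_invalid_options(self):
        records = pd.DataFrame({"arl_h": [1.0], "prl_h": [1.0],
                                "arl_generations": [2], "censored": [False]})
        with pytest.raises(ValueError):
            event_table_from_lifespans(records, clock="days")
        with pytest.raises(ValueError):
            event_table_from_lifespans(records, event="sporulation")
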