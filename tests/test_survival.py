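import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metasig.simulate import SimConfig, SurvivalSim, simulate_survival
from metasig.survival import (
    SurvivalCohort,
    cox_fit,
    hazard_ratio,
    km_estimate,
    logrank_test,
    risk_groups,
)


def _grid_partial_likelihood(times, events, x, betas):
    """Independent brute-force Cox partial log-likelihood (no ties)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    out = np.zeros(len(betas))
    for b_i, beta in enumerate(betas):
        ll = 0.0
        for i in np.where(events == 1)[0]:
            risk = times >= times[i]
            ll += beta * x[i] - math.log(np.sum(np.exp(beta * x[risk])))
        out[b_i] = ll
    return out


class TestCoxFit:
    def test_matches_grid_search_oracle(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 1, 1]
        x = [1.0, 0.0, 1.0, 0.0]
        grid = np.arange(-5.0, 5.0, 1e-4)
        ll = _grid_partial_likelihood(times, events, x, grid)
        oracle = grid[np.argmax(ll)]
        fit = cox_fit(times, events, np.array(x)[:, None])
        assert fit.betas[0] == pytest.approx(oracle, abs=1e-4)

    def test_local_optimum_on_grid(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 1, 0, 1, 1, 1]
        x = [0.5, -1.0, 0.3, 1.2, -0.7, 0.1]
        fit = cox_fit(times, events, np.array(x)[:, None])
        b = fit.betas[0]
        around = np.linspace(b - 0.5, b + 0.5, 101)
        ll = _grid_partial_likelihood(times, events, x, around)
        assert np.max(ll) <= _grid_partial_likelihood(times, events, x, [b])[0] + 1e-8

    def test_constant_covariate_beta_zero(self):
        fit = cox_fit([1, 2, 3], [1, 1, 1], np.ones((3, 1)))
        assert fit.betas[0] == 0.0
        assert fit.converged

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            cox_fit([1, 2], [0, 0], np.ones((2, 1)))

    def test_separation_flagged(self):
        # covariate perfectly orders the death times -> monotone likelihood
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 1, 1]
        x = [3.0, 2.0, 1.0, 0.0]
        fit = cox_fit(times, events, np.array(x)[:, None])
        assert fit.separation
        assert abs(fit.betas[0]) <= 15.0

    def test_recovery_simulated_cohort(self):
        config = SimConfig(
            seed=5,
            survival=SurvivalSim(
                n_patients=2000, true_betas=(math.log(2.0),),
                panel_names=("hsa-miR-200a-3p",), censoring_fraction=0.2,
            ),
        )
        cohort = simulate_survival(config)
        fit = cox_fit(cohort.time, cohort.event, cohort.panel.to_numpy())
        assert fit.betas[0] == pytest.approx(math.log(2.0), abs=0.1)

    def test_matches_lifelines_without_ties(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 80
        x = rng.normal(size=(n, 2))
        times = rng.exponential(1.0, n) * np.exp(-0.5 * x[:, 0])
        events = (rng.uniform(size=n) < 0.8).astype(int)
        events[0] = 1
        df = pd.DataFrame({"t": times, "e": events, "x0": x[:, 0], "x1": x[:, 1]})
        cph = lifelines.CoxPHFitter().fit(df, duration_col="t", event_col="e")
        fit = cox_fit(times, events, x)  # no tied times: Breslow == Efron
        np.testing.assert_allclose(fit.betas, cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.to_numpy(), atol=1e-4)

    def test_efron_ties_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 60
        x = rng.normal(size=(n, 1))
        times = np.ceil(rng.exponential(3.0, n))  # heavy ties
        events = (rng.uniform(size=n) < 0.8).astype(int)
        events[0] = 1
        df = pd.DataFrame({"t": times, "e": events, "x0": x[:, 0]})
        cph = lifelines.CoxPHFitter().fit(df, duration_col="t", event_col="e")
        fit = cox_fit(times, events, x, ties="efron")
        assert fit.betas[0] == pytest.approx(cph.params_.iloc[0], abs=1e-5)
        b_bres = cox_fit(times, events, x, ties="breslow").betas[0]
        assert b_bres != pytest.approx(fit.betas[0], abs=1e-8)


class TestRiskGroups:
    def _cohort(self, scores):
        n = len(scores)
        return SurvivalCohort(
            patient_id=np.array([f"p{i}" for i in range(n)]),
            time=np.arange(1.0, n + 1),
            event=np.ones(n, dtype=int),
            panel=pd.DataFrame({"m": scores}),
        )

    def test_median_split(self):
        model = risk_groups(self._cohort([1.0, 2.0, 3.0, 4.0]), [1.0])
        assert list(model.group) == ["low", "low", "high", "high"]

    def test_odd_n_sizes(self):
        model = risk_groups(self._cohort([1.0, 2.0, 3.0, 4.0, 5.0]), [1.0])
        assert (model.group == "high").sum() == 2
        assert (model.group == "low").sum() == 3

    def test_ties_at_median_go_low(self):
        model = risk_groups(self._cohort([1.0, 2.0, 2.0, 3.0]), [1.0])
        assert (model.group == "low").sum() == 3

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            risk_groups(self._cohort([2.0, 2.0, 2.0]), [1.0])

    def test_two_component_recovery(self, rng):
        lo = rng.normal(-3.0, 0.5, 100)
        hi = rng.normal(3.0, 0.5, 100)
        scores = np.concatenate([lo, hi])
        model = risk_groups(self._cohort(scores), [1.0])
        truth = np.array(["low"] * 100 + ["high"] * 100)
        assert np.mean(model.group == truth) >= 0.95


class TestKaplanMeier:
    def test_no_censoring(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(km["survival"], [1.0, 2 / 3, 1 / 3, 0.0])

    def test_all_censored(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        np.testing.assert_allclose(km["survival"], [1.0])

    def test_hand_computed_mixed_censoring(self):
        # patients: death@1, censored@2, death@3, death@4, censored@5, death@6
        km = km_estimate([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1])
        expected = [1.0, 5 / 6, 5 / 6 * 3 / 4, 5 / 6 * 3 / 4 * 2 / 3, 0.0]
        np.testing.assert_allclose(km["survival"], expected)
        np.testing.assert_allclose(km["n_at_risk"], [6, 6, 4, 3, 1])

    def test_monotone_and_bounded(self, rng):
        times = rng.exponential(1.0, 50)
        events = (rng.uniform(size=50) < 0.6).astype(int)
        km = km_estimate(times, events)
        s = km["survival"].to_numpy()
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((0 <= s) & (s <= 1))

    def test_equals_empirical_survival_without_censoring(self, rng):
        times = rng.exponential(1.0, 40)
        km = km_estimate(times, np.ones(40, dtype=int))
        for t, s in zip(km["time"][1:], km["survival"][1:]):
            assert s == pytest.approx(np.mean(times > t))


class TestLogrank:
    def test_identical_groups(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [1, 1, 1, 1, 1, 1]
        group = ["a", "a", "a", "b", "b", "b"]
        chi2, p = logrank_test(times, events, group)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_strong_effect(self, rng):
        n = 200
        t1 = rng.exponential(1.0, n)
        t2 = rng.exponential(0.25, n)
        times = np.concatenate([t1, t2])
        events = np.ones(2 * n, dtype=int)
        group = np.array(["low"] * n + ["high"] * n)
        _, p = logrank_test(times, events, group)
        assert p < 0.001

    def test_one_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], ["a", "a"])

    def test_matches_lifelines(self, rng):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        n = 60
        times = rng.exponential(1.0, n)
        events = (rng.uniform(size=n) < 0.7).astype(int)
        events[:2] = 1
        group = rng.choice(["a", "b"], size=n)
        chi2, p = logrank_test(times, events, group)
        res = lifelines_stats.logrank_test(
            times[group == "a"], times[group == "b"],
            events[group == "a"], events[group == "b"],
        )
        assert chi2 == pytest.approx(res.test_statistic, rel=1e-9)
        assert p == pytest.approx(res.p_value, rel=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(min_value=0.1, max_value=10.0),
           power=st.floats(min_value=0.5, max_value=2.0))
    def test_monotone_time_transform_invariance(self, scale, power):
        rng = np.random.default_rng(99)
        times = rng.exponential(1.0, 30) + 0.01
        events = (rng.uniform(size=30) < 0.7).astype(int)
        events[0] = 1
        group = rng.choice(["a", "b"], size=30)
        if len(set(group)) < 2:
            group[0] = "a"
            group[1] = "b"
        chi2a, _ = logrank_test(times, events, group)
        chi2b, _ = logrank_test(scale * times**power, events, group)
        assert chi2a == pytest.approx(chi2b, rel=1e-12)


class TestHazardRatio:
    def test_identical_groups_hr_one(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [1, 1, 1, 1, 1, 1]
        group = ["high", "high", "high", "low", "low", "low"]
        hr, (lo, hi) = hazard_ratio(times, events, group)
        assert hr == pytest.approx(1.0, abs=1e-6)
        assert lo <= 1.0 <= hi

    def test_label_swap_inverts(self, rng):
        n = 100
        times = rng.exponential(1.0, n)
        events = np.ones(n, dtype=int)
        group = rng.choice(["high", "low"], size=n)
        hr, _ = hazard_ratio(times, events, group)
        flipped = np.where(group == "high", "low", "high")
        hr_flipped, _ = hazard_ratio(times, events, flipped)
        assert hr_flipped == pytest.approx(1.0 / hr, rel=1e-6)

    def test_constant_group_rejected(self):
        with pytest.raises(ValueError):
            hazard_ratio([1, 2], [1, 1], ["high", "high"])


class TestSurvivalCohort:
    def test_round_trip(self, tmp_path):
        cohort = simulate_survival(SimConfig(seed=1, survival=SurvivalSim(n_patients=20)))
        path = tmp_path / "cohort.tsv"
        cohort.to_tsv(path)
        back = SurvivalCohort.from_tsv(path)
        np.testing.assert_allclose(back.time, cohort.time, rtol=1e-10)
        np.testing.assert_array_equal(back.event, cohort.event)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SurvivalCohort(
                patient_id=np.array(["a"]), time=np.array([0.0]),
                event=np.array([1]), panel=pd.DataFrame({"m": [1.0]}),
            )

    def test_bad_event_rejected(self):
        with pytest.raises(ValueError, match="event"):
            SurvivalCohort(
                patient_id=np.array(["a"]), time=np.array([1.0]),
                event=np.array([2]), panel=pd.DataFrame({"m": [1.0]}),
            )

    def test_missing_panel_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            SurvivalCohort(
                patient_id=np.array(["a"]), time=np.array([1.0]),
                event=np.array([1]), panel=pd.DataFrame({"m": [np.nan]}),
            )

    def test_panel_subset_selection(self, tmp_path):
        cohort = simulate_survival(SimConfig(seed=1, survival=SurvivalSim(n_patients=10)))
        path = tmp_path / "cohort.tsv"
        cohort.to_tsv(path)
        back = SurvivalCohort.from_tsv(path, panel=["hsa-miR-200c-3p"])
        assert list(back.panel.columns) == ["hsa-miR-200c-3p"]
        with pytest.raises(ValueError, match="absent"):
            SurvivalCohort.from_tsv(path, panel=["hsa-miR-999-3p"])
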