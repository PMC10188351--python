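import numpy as np
import pandas as pd
import pytest

from geroscreen.datasets import CohortSpec, ValidationError
from geroscreen.survival_screen import (
    KMCurve,
    assign_cohorts,
    direction_of_harm,
    heatmap_table,
    km_estimate,
    logrank_test,
    median_split,
    screen_survival,
    stratifying_genes,
)

import oracles
from conftest import make_survival_dataset


def _meta(ages):
    return pd.DataFrame({
        "age": ages,
        "os_time": [100.0] * len(ages),
        "os_event": [1.0] * len(ages),
    }, index=pd.Index([f"S{i}" for i in range(len(ages))], name="sample_id"))


class TestCohortAssignment:
    def test_boundaries(self):
        labels = assign_cohorts(_meta([44.9, 45.0, 60.0, 60.5, 30.0, 75.0]))
        assert labels.tolist() == ["young", "middle", "middle", "senior",
                                   "young", "senior"]

    def test_samples_without_age_or_survival_excluded(self):
        meta = _meta([50.0, 50.0, 50.0])
        meta.loc["S0", "age"] = np.nan
        meta.loc["S1", ["os_time", "os_event"]] = np.nan
        assert assign_cohorts(meta).index.tolist() == ["S2"]

    def test_custom_bounds(self):
        labels = assign_cohorts(_meta([50.0]), CohortSpec(young_max=55, senior_min=65))
        assert labels.tolist() == ["young"]


class TestMedianSplit:
    def test_odd_count_puts_median_in_high(self):
        vals = pd.Series([1, 2, 3, 4, 5], index=list("abcde"))
        high, low, indet = median_split(vals)
        assert set(high) == {"c", "d", "e"} and set(low) == {"a", "b"}
        assert not indet

    def test_even_split_between_distinct_values(self):
        vals = pd.Series([1, 1, 2, 2], index=list("abcd"))  # median 1.5
        high, low, _ = median_split(vals)
        assert set(high) == {"c", "d"} and set(low) == {"a", "b"}

    def test_constant_vector_is_indeterminate(self):
        high, low, indet = median_split(pd.Series([2.0, 2.0, 2.0]))
        assert indet and len(low) == 0 and len(high) == 3


class TestKaplanMeier:
    def test_all_censored_is_flat_one(self):
        curve = km_estimate([5, 8, 12], [False, False, False])
        assert curve.event_times.size == 0
        assert curve.survival_at(100.0) == 1.0
        assert np.isinf(curve.median)

    def test_three_events_hand_product(self):
        curve = km_estimate([1, 2, 3], [True, True, True])
        np.testing.assert_allclose(curve.survival_probs, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])
        assert curve.median == 2.0

    def test_single_event_among_censored(self):
        curve = km_estimate([5, 9, 9, 9], [True, False, False, False])
        assert curve.survival_at(5) == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", list(range(8)))
    def test_matches_brute_force_product_limit(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        times = np.round(rng.exponential(10, n), 1) + 0.1
        events = rng.random(n) < 0.6
        if not events.any():
            events[0] = True
        curve = km_estimate(times, events)
        expected = oracles.km_product_limit(times, events)
        assert len(curve.event_times) == len(expected)
        for (t, s, n_risk), ct, cs, c_risk in zip(
                expected, curve.event_times, curve.survival_probs, curve.at_risk):
            assert ct == pytest.approx(t)
            assert cs == pytest.approx(s, abs=1e-12)
            assert c_risk == n_risk

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])


class TestLogRank:
    def test_identical_groups_are_null(self):
        t = [3, 6, 9, 12]
        e = [True, True, False, True]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_tabulation(self):
        ta, ea = [2.0, 5.0, 7.0], [True, True, False]
        tb, eb = [1.0, 4.0, 9.0], [True, False, True]
        chi2, _ = logrank_test(ta, ea, tb, eb)
        assert chi2 == pytest.approx(oracles.logrank_chi2(ta, ea, tb, eb), abs=1e-10)

    @pytest.mark.parametrize("seed", list(range(6)))
    def test_matches_hand_oev_and_invariances(self, seed):
        rng = np.random.default_rng(100 + seed)
        na, nb = int(rng.integers(3, 7)), int(rng.integers(3, 7))
        ta = np.round(rng.exponential(10, na), 1) + 0.1
        tb = np.round(rng.exponential(15, nb), 1) + 0.1
        ea = rng.random(na) < 0.7
        eb = rng.random(nb) < 0.7
        if ea.sum() + eb.sum() == 0:
            ea[0] = True
        chi2, p = logrank_test(ta, ea, tb, eb)
        assert chi2 == pytest.approx(oracles.logrank_chi2(ta, ea, tb, eb), abs=1e-10)
        # label-swap invariance
        chi2_sw, p_sw = logrank_test(tb, eb, ta, ea)
        assert chi2_sw == pytest.approx(chi2, abs=1e-12)
        # time-rescaling invariance
        chi2_rs, p_rs = logrank_test(ta * 3.7, ea, tb * 3.7, eb)
        assert chi2_rs == pytest.approx(chi2, abs=1e-10)
        assert p_rs == pytest.approx(p, abs=1e-10)

    def test_zero_events_warns_and_returns_null(self, caplog):
        chi2, p = logrank_test([5, 6], [False, False], [7, 8], [False, False])
        assert (chi2, p) == (0.0, 1.0)

    def test_strong_hazard_ratio_detected(self):
        rng = np.random.default_rng(42)
        n = 100
        ta = rng.exponential(100, n)   # hazard ratio 3
        tb = rng.exponential(300, n)
        _, p = logrank_test(ta, np.ones(n, bool), tb, np.ones(n, bool))
        assert p < 0.001


class TestDirectionOfHarm:
    def _curve(self, median, max_time=1000.0, s_at_end=0.8):
        return KMCurve(event_times=np.array([1.0]), survival_probs=np.array([s_at_end]),
                       at_risk=np.array([10]), median=median, max_time=max_time, n=10)

    def test_smaller_median_is_worse(self):
        assert direction_of_harm(self._curve(200.0), self._curve(500.0)) == "high_worse"
        assert direction_of_harm(self._curve(500.0), self._curve(200.0)) == "low_worse"

    def test_identical_curves_indeterminate(self):
        assert direction_of_harm(self._curve(300.0), self._curve(300.0)) == "indeterminate"

    def test_fallback_when_neither_median_defined(self):
        high = self._curve(np.inf, s_at_end=0.8)
        low = self._curve(np.inf, s_at_end=0.9)
        assert direction_of_harm(high, low) == "high_worse"
        assert direction_of_harm(low, high) == "low_worse"
        assert direction_of_harm(high, self._curve(np.inf, s_at_end=0.8)) == "indeterminate"


class TestScreen:
    def test_planted_senior_hazard_recovered(self):
        ds = make_survival_dataset(n=900, effect_gene="G2", loghr=1.2,
                                   cohort="senior", seed=5)
        results = screen_survival(ds, [f"G{i}" for i in range(4)])
        row = results.set_index(["gene", "cohort"]).loc[("G2", "senior")]
        assert row["significant"] and row["direction"] == "high_worse"
        assert "G2" in stratifying_genes(results)
        heat = heatmap_table(results)
        assert heat.loc["G2", "senior"] == "red"

    def test_empty_gene_list_gives_empty_table(self):
        ds = make_survival_dataset(n=100, seed=1)
        results = screen_survival(ds, [])
        assert results.empty
        assert heatmap_table(results).empty

    def test_small_or_eventless_cohorts_not_evaluable(self):
        ds = make_survival_dataset(n=60, seed=2)
        # force all ages young -> middle/senior cohorts empty
        meta = ds.metadata.copy()
        meta["age"] = 30.0
        ds2 = type(ds).from_frames("Y", ds.values, meta)
        results = screen_survival(ds2, ["G0", "G1"])
        by = results.set_index(["gene", "cohort"])
        assert bool(by.loc[("G0", "young"), "evaluable"])
        assert not bool(by.loc[("G0", "senior"), "evaluable"])
        heat = heatmap_table(results)
        assert heat.loc["G0", "senior"] == "NA"

    def test_counts_partition_cohort(self):
        ds = make_survival_dataset(n=400, seed=3)
        results = screen_survival(ds, ["G0"])
        cohorts = assign_cohorts(ds.metadata)
        for _, row in results[results["evaluable"]].iterrows():
            assert row["n_high"] + row["n_low"] == int((cohorts == row["cohort"]).sum())
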