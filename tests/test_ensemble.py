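import numpy as np
import pytest

from dioxhop.ensemble import (
    collect_ensemble,
    detect_equilibrium,
    dissociation_half_time,
    dissociation_statistics,
    ensemble_report,
    histogram2d,
    population_time_series,
    quantum_yields,
    rlse_report,
)
from dioxhop.fixtures import load_fixture


class TestQuantumYields:
    def test_published_ensemble_counts(self):
        """180 S0, 52 S1 and 70 T1 products over 302 completed
        trajectories give 59.6%, 17.2% and 23.2% yields."""
        counts = load_fixture("table4_counts")
        labels = [lab for lab, c in counts.items() for _ in range(c)]
        y = quantum_yields(labels, 302)
        assert y["S0"] == pytest.approx(59.6, abs=0.05)
        assert y["S1"] == pytest.approx(17.2, abs=0.05)
        assert y["T1"] == pytest.approx(23.2, abs=0.05)

    def test_single_label_is_hundred_percent(self):
        assert quantum_yields(["T1"] * 7, 7) == {"T1": 100.0}

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        labels = list(rng.choice(["S0", "S1", "T1"], size=500))
        y = quantum_yields(labels, 500)
        for lab in set(labels):
            assert y[lab] == pytest.approx(100.0 * labels.count(lab) / 500)

    def test_yields_sum_to_hundred(self):
        rng = np.random.default_rng(1)
        labels = list(rng.choice(["S0", "S1", "T1", "T2"], size=311))
        assert sum(quantum_yields(labels, 311).values()) == pytest.approx(100.0)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            quantum_yields([], 0)


class TestHalfTime:
    def test_odd_count_median(self):
        assert dissociation_half_time([10.0, 20.0, 30.0]) == 20.0

    def test_even_count_midpoint_gives_quarter_femtosecond_values(self):
        """The midpoint convention produces quarter-fs half-times from
        half-fs-quantized dissociation times."""
        assert dissociation_half_time([100.5, 406.0]) == pytest.approx(253.25)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        t = rng.uniform(10, 4000, 101)
        shuffled = t.copy()
        rng.shuffle(shuffled)
        assert dissociation_half_time(t) == dissociation_half_time(shuffled)

    def test_order_statistic_property(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(10, 4000, 90)
        h = dissociation_half_time(t)
        assert np.sum(t <= h) >= len(t) / 2
        assert np.sum(t >= h) >= len(t) / 2

    def test_statistics_block(self):
        stats = dissociation_statistics([39.0, 100.0, 4329.0])
        assert stats["minimum"] == 39.0
        assert stats["maximum"] == 4329.0
        assert stats["half_time"] == 100.0


class TestPopulations:
    def test_initial_population_all_on_ground_singlet(self, ensemble):
        t, pops = population_time_series(ensemble, "mch_collapsed")
        assert pops["S0"][0] == pytest.approx(1.0)

    def test_fractions_sum_to_one_everywhere(self, ensemble):
        t, pops = population_time_series(ensemble, "mch_collapsed")
        total = np.sum(list(pops.values()), axis=0)
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_final_populations_equal_quantum_yields(self, ensemble):
        """After every trajectory has terminated the collapsed-MCH
        populations are constant and equal the quantum yields."""
        result = collect_ensemble(ensemble)
        yields = quantum_yields([s.product for s in result.summaries],
                                result.n_completed)
        completed = [r for r in ensemble if r.status == "dissociated"]
        t, pops = population_time_series(completed, "mch_collapsed")
        for lab, pct in yields.items():
            assert 100.0 * pops[lab][-1] == pytest.approx(pct, abs=1e-9)

    def test_diagonal_basis_well_formed(self, ensemble):
        t, pops = population_time_series(ensemble, "diagonal")
        assert all(k.startswith("D") for k in pops)
        total = np.sum(list(pops.values()), axis=0)
        assert np.allclose(total, 1.0, atol=1e-12)


class TestEquilibriumDetection:
    def test_constant_series_settles_at_origin(self):
        t = np.arange(0.0, 100.0, 1.0)
        series = {"S0": np.full_like(t, 0.6), "T1": np.full_like(t, 0.4)}
        assert detect_equilibrium(series, t, window=10.0, tolerance=0.01) == 0.0

    def test_step_function_settling_point(self):
        t = np.arange(0.0, 100.0, 1.0)
        s = np.where(t < 40.0, 0.2, 0.7)
        assert detect_equilibrium({"x": s}, t, window=10.0,
                                  tolerance=0.01) == pytest.approx(40.0)

    def test_persistent_oscillation_never_settles(self):
        """Populations that keep fluctuating beyond tolerance (like the
        triplet sz sublevels) yield no equilibrium time."""
        t = np.arange(0.0, 200.0, 1.0)
        s = 0.1 + 0.05 * np.sin(0.3 * t)
        assert detect_equilibrium({"x": s}, t, window=10.0,
                                  tolerance=0.01) is None

    def test_window_longer_than_series_rejected(self):
        t = np.arange(0.0, 10.0, 1.0)
        with pytest.raises(ValueError):
            detect_equilibrium({"x": np.zeros_like(t)}, t, window=50.0)


class TestHistogram2D:
    def test_single_point_lands_in_its_cell(self):
        counts = histogram2d([0.5], [1.5], [0, 1, 2], [0, 1, 2])
        assert counts[0, 1] == 1
        assert counts.sum() == 1

    def test_shared_edge_goes_to_higher_bin(self):
        counts = histogram2d([1.0], [1.0], [0, 1, 2], [0, 1, 2])
        assert counts[1, 1] == 1

    def test_last_edge_closed(self):
        counts = histogram2d([2.0], [2.0], [0, 1, 2], [0, 1, 2])
        assert counts[1, 1] == 1

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 10, 1000)
        y = rng.uniform(-5, 5, 1000)
        xe = np.linspace(0, 10, 11)
        ye = np.linspace(-5, 5, 6)
        counts = histogram2d(x, y, xe, ye)
        brute = np.zeros_like(counts)
        for xi, yi in zip(x, y):
            for i in range(len(xe) - 1):
                for j in range(len(ye) - 1):
                    in_x = (xe[i] <= xi < xe[i + 1]) or (i == len(xe) - 2 and xi == xe[-1])
                    in_y = (ye[j] <= yi < ye[j + 1]) or (j == len(ye) - 2 and yi == ye[-1])
                    if in_x and in_y:
                        brute[i, j] += 1
        assert np.array_equal(counts, brute)

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError):
            histogram2d([0.5], [0.5], [0, 2, 1], [0, 1, 2])


class TestRLSE:
    def test_negative_endpoint_subrange(self):
        """Global range [-3, 2] with an S0 subrange starting at -2: the
        empty length 1.0 is 20.0% of the range length 5.0."""
        rep = rlse_report({"S0": [-2.0, 2.0], "T1": [-3.0, 1.5], "S1": [-2.5, 1.0]})
        assert rep.per_state["S0"].rlse_low == pytest.approx(20.0)

    def test_positive_endpoint_subrange(self):
        rep = rlse_report({"S0": [-2.0, 2.0], "T1": [-3.0, 1.5], "S1": [-2.5, 1.0]})
        assert rep.per_state["S1"].rlse_high == pytest.approx(20.0)

    def test_state_spanning_full_range_has_zero_rlse(self):
        rep = rlse_report({"A": [0.0, 10.0], "B": [2.0, 8.0]})
        assert rep.per_state["A"].rlse_low == 0.0
        assert rep.per_state["A"].rlse_high == 0.0

    def test_published_percentages_reproduced(self):
        """Interval arithmetic on the shipped feature ranges reproduces all
        published RLSE percentages: 20.0, 25.0, 12.5, 23.1, 33.3."""
        ranges = load_fixture("rlse_ranges_fig5")
        seen = set()
        for feature, per_state in ranges.items():
            rep = rlse_report({lab: list(bounds) for lab, bounds in per_state.items()})
            for stat in rep.per_state.values():
                for val in (stat.rlse_low, stat.rlse_high):
                    if val > 0:
                        seen.add(round(val, 1))
        assert {20.0, 25.0, 12.5, 23.1, 33.3} <= seen

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError):
            rlse_report({"A": [1.0, 1.0], "B": [1.0]})

    def test_parallel_sequence_interface(self):
        rep = rlse_report([-3.0, 2.0, -2.0, 1.0], ["T1", "T1", "S0", "S0"])
        assert rep.per_state["S0"].rlse_low == pytest.approx(20.0)


class TestEnsembleStatistics:
    def test_yield_sum_and_bookkeeping(self, ensemble):
        result = collect_ensemble(ensemble)
        assert result.n_launched == len(ensemble)
        assert result.n_completed + result.n_failed == result.n_launched
        report = ensemble_report(result)
        assert sum(report["quantum_yields_pct"].values()) == pytest.approx(100.0)

    def test_half_ensemble_yields_agree_within_binomial_interval(self, ensemble):
        """Yields from two disjoint half-ensembles agree within the 95%
        binomial interval, i.e. the estimator is stochastically stable."""
        half = len(ensemble) // 2
        r1 = collect_ensemble(ensemble[:half])
        r2 = collect_ensemble(ensemble[half:])
        y1 = quantum_yields([s.product for s in r1.summaries], r1.n_completed)
        y2 = quantum_yields([s.product for s in r2.summaries], r2.n_completed)
        for lab in set(y1) | set(y2):
            p1 = y1.get(lab, 0.0) / 100.0
            p2 = y2.get(lab, 0.0) / 100.0
            pooled = (p1 * r1.n_completed + p2 * r2.n_completed) / (
                r1.n_completed + r2.n_completed)
            se = np.sqrt(pooled * (1 - pooled)
                         * (1 / r1.n_completed + 1 / r2.n_completed))
            assert abs(p1 - p2) <= max(1.96 * se, 1e-12)

    def test_report_contains_per_product_time_statistics(self, ensemble):
        report = ensemble_report(collect_ensemble(ensemble))
        stats = report["dissociation_times"]["all"]
        assert stats["minimum"] <= stats["half_time"] <= stats["maximum"]
        assert "rlse" in report
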