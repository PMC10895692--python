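import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dioxhop.analysis import (
    UndefinedProductError,
    angle_variation,
    count_frustrated_dissociations,
    dissociation_time,
    mean_oscillation_period,
    product_state_label,
    residence_times,
    summarize_trajectory,
    transition_count_matrix,
    unwrap_dihedral,
)
from dioxhop.fixtures import load_fixture
from dioxhop.states import parse_label


class _Series:
    """Minimal record carrying just the fields the analysis layer reads."""

    def __init__(self, r_cc, dt=0.5, mch=None, labels=None):
        self.r_cc = np.asarray(r_cc, dtype=float)
        self.t = np.arange(len(self.r_cc)) * dt
        self.dt = dt
        self.labels = labels or [parse_label("S0")]
        self.active_mch = np.asarray(mch if mch is not None
                                     else [0] * len(self.r_cc))


class TestDissociationTime:
    def test_first_sample_beyond_threshold(self):
        rec = _Series([2.0, 2.3, 2.45, 3.0])
        assert dissociation_time(rec, 2.4) == pytest.approx(1.0)

    def test_never_crossing_returns_none(self):
        assert dissociation_time(_Series([2.0, 2.3, 2.39]), 2.4) is None

    def test_strictly_greater_convention(self):
        rec = _Series([2.0, 2.4, 2.5])   # 2.4 itself does not count
        assert dissociation_time(rec, 2.4) == pytest.approx(1.0)


class TestProductLabel:
    def _record(self, names, r_cc):
        labels = sorted({parse_label(n) for n in names})
        idx = {l: i for i, l in enumerate(labels)}
        mch = [idx[parse_label(n)] for n in names]
        return _Series(r_cc, mch=mch, labels=list(labels))

    def test_triplet_sublevel_collapsed(self):
        rec = self._record(["S0", "T1,-1", "T1,0"], [2.0, 2.45, 3.8])
        assert product_state_label(rec, 2.4) == "T1"

    def test_singlet_label_kept(self):
        rec = self._record(["S0", "S0", "S0"], [2.0, 2.45, 3.8])
        assert product_state_label(rec, 2.4) == "S0"

    def test_sz_hops_after_crossing_do_not_relabel(self):
        rec = self._record(["S0", "T1,1", "T1,-1", "T1,0"],
                           [2.0, 2.45, 3.0, 3.8])
        assert product_state_label(rec, 2.4) == "T1"

    def test_undissociated_record_rejected(self):
        rec = self._record(["S0", "S0"], [2.0, 2.2])
        with pytest.raises(UndefinedProductError):
            product_state_label(rec, 2.4)


class TestFrustratedDissociations:
    def test_oscillation_peak_count_matches_mean_period_arithmetic(self):
        """A C-C oscillation with the observed ~40.6 fs mean period shows
        24 aborted dissociation attempts within 975.5 fs."""
        period = 975.5 / 24.0
        t = np.arange(0.0, 975.5 + 0.25, 0.5)
        r = 1.6 + 0.2 * np.sin(2 * np.pi * t / period)
        assert count_frustrated_dissociations(r, 0.05) == 24

    def test_monotone_series_has_no_peaks(self):
        assert count_frustrated_dissociations(np.linspace(1.5, 3.8, 100)) == 0

    def test_matches_brute_force_peak_scan(self):
        """Prominence-filtered peak counting equals an exhaustive scan on
        random-walk series."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            r = 1.6 + np.cumsum(rng.normal(scale=0.05, size=200))
            prom = rng.choice([0.0001, 0.02, 0.05, 0.2])
            expected = _brute_force_peaks(r, prom)
            assert count_frustrated_dissociations(r, prom) == expected

    def test_window_excludes_post_dissociation_structure(self):
        r = np.concatenate([1.6 + 0.2 * np.sin(np.linspace(0, 4 * np.pi, 80)),
                            np.linspace(2.5, 3.8, 20)])
        full = count_frustrated_dissociations(r, 0.05)
        clipped = count_frustrated_dissociations(r, 0.05, end_index=80)
        assert clipped <= full
        assert clipped == 2


def _brute_force_peaks(r, prominence):
    """Independent O(n^2) peak scan: a strict interior local maximum counts
    when its height over max(left base, right base) reaches the prominence
    threshold, where each base is the minimum between the peak and the
    nearest strictly higher sample (or the series end)."""
    n = len(r)
    count = 0
    for i in range(1, n - 1):
        if not (r[i] > r[i - 1] and r[i] > r[i + 1]):
            continue
        left = i - 1
        while left > 0 and r[left] <= r[i]:
            left -= 1
        left_base = r[left:i].min() if r[left] > r[i] else r[: i].min()
        right = i + 1
        while right < n - 1 and r[right] <= r[i]:
            right += 1
        right_base = (r[i + 1: right + 1].min() if r[right] > r[i]
                      else r[i + 1:].min())
        if r[i] - max(left_base, right_base) >= prominence:
            count += 1
    return count


class TestMeanPeriod:
    @pytest.mark.parametrize("n,window,expected", [
        (24, 975.5, 40.6),    # long triplet-product trajectory
        (108, 4300.0, 39.8),  # long ground-state trajectory
        (1, 40.0, 40.0),
    ])
    def test_window_over_peak_count(self, n, window, expected):
        assert mean_oscillation_period(n, window) == pytest.approx(expected, abs=0.05)

    def test_zero_peaks_undefined(self):
        assert mean_oscillation_period(0, 100.0) is None


class TestTransitionCounts:
    def test_within_state_steps_on_diagonal(self):
        s0 = parse_label("S0")
        m = transition_count_matrix([s0, s0, s0])
        assert m.counts[0, 0] == 2
        assert m.counts.sum() == 2

    def test_hops_off_diagonal(self):
        series = [parse_label(n) for n in ("S0", "T1,-1", "T1,-1")]
        m = transition_count_matrix(series)
        i = {l.name: k for k, l in enumerate(m.labels)}
        assert m.counts[i["S0"], i["T1,-1"]] == 1
        assert m.counts[i["T1,-1"], i["T1,-1"]] == 1

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(["S0", "S1", "T1,-1", "T1,0", "T2,1"]),
                    min_size=2, max_size=80))
    def test_total_transitions_is_samples_minus_one(self, names):
        series = [parse_label(n) for n in names]
        m = transition_count_matrix(series)
        assert m.total_transitions == len(series) - 1


class TestResidence:
    def test_short_trajectory_table(self):
        """Diagonal-plus-column rule on the published short-trajectory
        matrix: 30.5, 5.5, 34.0, 9.5 fs in S0, S1, T1, T2 and 79.5 fs in
        total."""
        _, collapsed = residence_times(load_fixture("table2_matrix"))
        assert collapsed["S0"] == pytest.approx(30.5)
        assert collapsed["S1"] == pytest.approx(5.5)
        assert collapsed["T1"] == pytest.approx(34.0)
        assert collapsed["T2"] == pytest.approx(9.5)
        assert sum(collapsed.values()) == pytest.approx(79.5)

    def test_long_trajectory_table(self):
        _, collapsed = residence_times(load_fixture("table3_matrix"))
        expected = {"S0": 30.5, "S1": 113.5, "S2": 24.5, "S3": 12.5,
                    "T1": 546.0, "T2": 317.0}
        for name, fs in expected.items():
            assert collapsed[name] == pytest.approx(fs)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(["S0", "S1", "T1,-1", "T1,0", "T2,1"]),
                    min_size=2, max_size=80))
    def test_residence_conserves_total_and_matches_destination_count(self, names):
        """Residence rule equals a direct destination-convention count and
        sums to (samples - 1) * dt on arbitrary series."""
        series = [parse_label(n) for n in names]
        m = transition_count_matrix(series, dt=0.5)
        per_label, collapsed = residence_times(m)
        assert sum(per_label.values()) == pytest.approx((len(series) - 1) * 0.5)
        assert sum(collapsed.values()) == pytest.approx((len(series) - 1) * 0.5)
        # destination convention: sample i > 0 belongs to its own state
        direct = {}
        for lab in series[1:]:
            direct[lab.name] = direct.get(lab.name, 0) + 1
        for name, steps in direct.items():
            assert per_label[name] == pytest.approx(steps * 0.5)


class TestUnwrap:
    def test_wraparound_oscillation_is_continuous(self):
        """178 -> 183 (stored as -177) unwraps back to 183."""
        out = unwrap_dihedral([178.0, -177.0])
        assert np.allclose(out, [178.0, 183.0])

    def test_constant_series_unchanged(self):
        out = unwrap_dihedral([45.0] * 10)
        assert np.allclose(out, 45.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-120.0, 120.0), min_size=2, max_size=50))
    def test_roundtrip_recovers_continuous_path(self, steps):
        """Wrapping a continuous path and unwrapping recovers it up to the
        (preserved) starting point."""
        from dioxhop.model import wrap_degrees
        path = np.concatenate([[10.0], 10.0 + np.cumsum(steps)])
        wrapped = wrap_degrees(path)
        out = unwrap_dihedral(wrapped)
        assert np.allclose(out - out[0], path - path[0], atol=1e-9)

    def test_translation_invariance(self):
        base = [135.8, 180.0, -90.0, 0.0, 32.9]
        from dioxhop.model import wrap_degrees
        shifted = wrap_degrees(np.asarray(base) + 360.0)
        assert angle_variation(base) == pytest.approx(angle_variation(shifted))

    def test_successive_differences_in_half_open_interval(self):
        rng = np.random.default_rng(1)
        series = rng.uniform(-180.0, 180.0, 200)
        d = np.diff(unwrap_dihedral(series))
        assert np.all(d > -180.0) and np.all(d <= 180.0)


class TestAngleVariation:
    def test_long_trajectory_waypoints(self):
        """Unwrapping 135.8 -> 180(-180) -> -90 -> 0 -> 32.9 gives a total
        variation of 257.1 degrees."""
        assert angle_variation(load_fixture("dihedral_waypoints_traj23")) \
            == pytest.approx(257.1, abs=1e-9)

    def test_direct_short_trajectory(self):
        assert angle_variation([135.8, 128.9]) == pytest.approx(6.9)

    def test_most_populated_variation(self):
        assert angle_variation([135.8, 150.0]) == pytest.approx(14.2)


class TestSummaries:
    def test_summary_consistent_with_ensemble_records(self, ensemble):
        for rec in ensemble:
            if rec.status != "dissociated":
                continue
            s = summarize_trajectory(rec)
            assert s.dissociation_time == rec.dissociation_time
            assert s.product == rec.product_mch.collapsed
            assert s.n_frustrated >= 0
            assert sum(s.residence.values()) == pytest.approx(
                (rec.n_steps - 1) * rec.dt)
            if s.n_frustrated and s.dissociation_time:
                assert s.mean_period == pytest.approx(
                    s.dissociation_time / s.n_frustrated)
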