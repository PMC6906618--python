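import numpy as np
import pytest

from gaitmon.bouts import (
    DEFAULT_BIN_EDGES,
    bin_bouts,
    bin_label,
    bout_speed_summary,
    segment_bouts,
)
from tests.conftest import make_gait_window

HOP = 1.25


def _windows(fx_seq, starts=None, **kw):
    starts = starts or [HOP * i for i in range(len(fx_seq))]
    return [make_gait_window(s, fx=f, **kw) for s, f in zip(starts, fx_seq)]


def _oracle_segment(windows, merge_factor=1.6, max_gap_s=HOP):
    """Independent oracle: mark every adjacent-pair boundary where the gap
    or frequency criterion is violated, then split at the boundaries."""
    eps = 1e-9
    boundaries = []
    for a, b in zip(windows, windows[1:]):
        ratio = max(a.F_x, b.F_x) / min(a.F_x, b.F_x)
        bad = (b.start_time_s - a.start_time_s > max_gap_s + eps) or (
            ratio > merge_factor + eps
        )
        boundaries.append(bad)
    runs, cur = [], [windows[0]]
    for bad, w in zip(boundaries, windows[1:]):
        if bad:
            runs.append(cur)
            cur = [w]
        else:
            cur.append(w)
    runs.append(cur)
    return runs


class TestSegmentation:
    def test_stable_cadence_merges_into_one_bout(self):
        bouts, _ = segment_bouts(_windows([2.0, 2.1, 2.0]), min_steps=0)
        assert len(bouts) == 1
        assert bouts[0].n_windows == 3

    def test_cadence_jump_splits(self):
        bouts, _ = segment_bouts(_windows([1.0, 2.0]), min_steps=0)
        assert len(bouts) == 2  # ratio 2.0 > 1.6

    def test_single_window_is_a_bout(self):
        bouts, _ = segment_bouts(_windows([2.0]), min_steps=0)
        assert len(bouts) == 1
        assert bouts[0].step_count == pytest.approx(2.0 * HOP)

    def test_time_gap_splits(self):
        bouts, _ = segment_bouts(
            _windows([2.0, 2.0], starts=[0.0, 10.0]), min_steps=0
        )
        assert len(bouts) == 2

    def test_unordered_input_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            segment_bouts(_windows([2.0, 2.0], starts=[5.0, 0.0]))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(1, 201))
        t, starts = 0.0, []
        for _ in range(n):
            starts.append(t)
            t += HOP if rng.random() < 0.8 else float(rng.uniform(2 * HOP, 30.0))
        fx = rng.uniform(0.7, 3.0, size=n)
        windows = _windows(list(fx), starts=starts)
        bouts, _ = segment_bouts(windows, min_steps=0)
        runs = _oracle_segment(windows)
        assert len(bouts) == len(runs)
        for b, run in zip(bouts, runs):
            assert b.n_windows == len(run)
            assert b.start_time_s == run[0].start_time_s
            assert b.step_count == pytest.approx(
                sum(w.step_contribution for w in run)
            )

    def test_step_count_conserved_across_bouts_and_discards(self):
        rng = np.random.default_rng(77)
        starts, t = [], 0.0
        for _ in range(200):
            starts.append(t)
            t += HOP if rng.random() < 0.7 else float(rng.uniform(3.0, 20.0))
        windows = _windows(list(rng.uniform(0.7, 3.0, size=200)), starts=starts)
        total_windows = sum(w.step_contribution for w in windows)
        bouts, discarded = segment_bouts(windows, min_steps=5.0)
        total_bouts = sum(b.step_count for b in bouts)
        assert total_bouts + discarded == pytest.approx(total_windows)

    def test_merge_factor_extremes(self):
        rng = np.random.default_rng(3)
        windows = _windows(list(rng.uniform(0.7, 3.0, size=50)))
        one, _ = segment_bouts(windows, merge_factor=np.inf, min_steps=0)
        assert len(one) == 1  # contiguous run, frequency ignored
        split, _ = segment_bouts(windows, merge_factor=1.0, min_steps=0)
        assert len(split) == 50  # splits at every frequency change

    def test_running_mean_mode_differs_only_via_reference(self):
        # 1.0, 1.5, 2.2: adjacent ratios 1.5, 1.47 both pass, but 2.2 vs the
        # running mean 1.25 fails the 1.6-fold criterion
        windows = _windows([1.0, 1.5, 2.2])
        adj, _ = segment_bouts(windows, min_steps=0)
        run, _ = segment_bouts(windows, min_steps=0, running_mean=True)
        assert len(adj) == 1
        assert len(run) == 2

    def test_short_bouts_discarded_by_min_steps(self):
        bouts, discarded = segment_bouts(_windows([2.0]), min_steps=3.0)
        assert bouts == []
        assert discarded == pytest.approx(2.0 * HOP)


class TestBinning:
    def test_examples(self):
        assert bin_label(DEFAULT_BIN_EDGES, 12) == "[10,20)"
        assert bin_label(DEFAULT_BIN_EDGES, 20) == "[20,40)"  # half-open
        assert bin_label(DEFAULT_BIN_EDGES, 640) == "[640,inf)"

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            bin_label([1, 5, 5], 3)

    def test_counts_match_histogram_oracle(self):
        rng = np.random.default_rng(10)
        steps = np.exp(rng.normal(np.log(12), 1.3, size=1000))
        bouts = [make_gait_window(0.0) for _ in steps]  # placeholders
        from gaitmon.bouts import Bout

        bouts = [
            Bout(start_time_s=0, end_time_s=1, step_count=float(s), mean_speed_mps=1.0)
            for s in steps
        ]
        grouped = bin_bouts(bouts, DEFAULT_BIN_EDGES)
        edges = np.array([0] + list(DEFAULT_BIN_EDGES) + [np.inf])
        oracle, _ = np.histogram(steps, bins=edges)
        labels = (
            [f"[0,{DEFAULT_BIN_EDGES[0]})"]
            + [
                f"[{a},{b})"
                for a, b in zip(DEFAULT_BIN_EDGES, DEFAULT_BIN_EDGES[1:])
            ]
            + [f"[{DEFAULT_BIN_EDGES[-1]},inf)"]
        )
        for label, count in zip(labels, oracle):
            assert len(grouped.get(label, [])) == count

    def test_every_bout_in_exactly_one_bin(self):
        from gaitmon.bouts import Bout

        rng = np.random.default_rng(11)
        bouts = [
            Bout(0, 1, step_count=float(s), mean_speed_mps=1.0)
            for s in np.exp(rng.normal(2.5, 1.2, size=300))
        ]
        grouped = bin_bouts(bouts)
        assert sum(len(v) for v in grouped.values()) == 300


class TestSummary:
    def _bout(self, steps, speed):
        from gaitmon.bouts import Bout

        return Bout(0, 1, step_count=steps, mean_speed_mps=speed)

    def test_single_bin_fraction_one(self):
        df = bout_speed_summary([self._bout(12, 0.8), self._bout(15, 0.9)])
        assert len(df) == 1
        assert df.loc[0, "fraction"] == 1.0
        assert df.loc[0, "median_speed_mps"] == pytest.approx(0.85)

    def test_two_bins_equal_fractions(self):
        bouts = [self._bout(12, 0.8)] * 2 + [self._bout(100, 1.0)] * 2
        df = bout_speed_summary(bouts)
        assert list(df["fraction"]) == [0.5, 0.5]

    def test_empty_input_gives_empty_summary(self):
        assert bout_speed_summary([]).empty

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(12)
        bouts = [
            self._bout(float(s), float(v))
            for s, v in zip(
                np.exp(rng.normal(2.5, 1.3, 500)), rng.uniform(0.3, 1.2, 500)
            )
        ]
        assert bout_speed_summary(bouts)["fraction"].sum() == pytest.approx(1.0)

    def test_generator_speed_rises_with_bout_length(self):
        from gaitmon.simulate import DerivedCohortConfig, simulate_derived_cohort

        cohort = simulate_derived_cohort(DerivedCohortConfig(seed=4, n_subjects=10))
        bouts = [b for bs in cohort.bouts_by_day.values() for b in bs]
        df = bout_speed_summary(bouts)
        # the generator's length-speed profile rises up to ~80 steps and then
        # saturates; medians must be nondecreasing over the rising part
        rising = df[
            df["bin"].map(lambda s: float(s.strip("[").split(",")[0]) <= 80)
            & (df["n"] >= 20)
        ]
        med = rising["median_speed_mps"].to_numpy()
        assert np.all(np.diff(med) > -0.02)
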