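import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gaitmon.bouts import Bout
from gaitmon.clinical import (
    DEFAULT_BIN_MAPPING,
    GapError,
    agreement,
    assessment_speed,
    build_validity_pairs,
    extract_assessment_window,
)
from gaitmon.compliance import VisitEpoch, apply_threshold, build_epochs
from gaitmon.io import AccelRecording, AssessmentRecord, ObservationPeriod
from gaitmon.simulate import (
    DerivedCohortConfig,
    SimulationConfig,
    simulate_derived_cohort,
    simulate_still,
    simulate_walk,
)
from gaitmon.weartime import DailySummary

T0 = pd.Timestamp("2018-03-01 09:00:00", tz="UTC")
RATE = 100.0


def _assessment(a_type="6MWT", start=None, dur_s=360.0, dist=270.0):
    start = start or T0 + pd.Timedelta(seconds=600)
    return AssessmentRecord(
        "S1", "V1", a_type, start, start + pd.Timedelta(seconds=dur_s), dist
    )


class TestExtraction:
    def _period(self, n=120000):
        rng = np.random.default_rng(0)
        samples = rng.normal(0, 0.3, size=(n, 3))
        return ObservationPeriod("S1", [AccelRecording("S1", "D1", T0, RATE, samples)])

    def test_six_minute_slice_with_pad(self):
        sl = extract_assessment_window(self._period(), _assessment(), pad_s=2.0)
        assert sl.n_samples == 36400  # 364 s at 100 Hz

    def test_zero_pad_is_exact(self):
        sl = extract_assessment_window(self._period(), _assessment(), pad_s=0.0)
        assert sl.n_samples == 36000

    def test_assessment_over_gap_raises(self):
        period = self._period(n=6000)  # ends after 60 s
        with pytest.raises(GapError, match="V1"):
            extract_assessment_window(period, _assessment())


class TestAssessmentSpeed:
    @pytest.mark.parametrize("true_speed,dur", [(0.6, 30.0), (0.9, 360.0)])
    def test_simulated_walk_test_recovered(self, speed_model, true_speed, dur):
        cfg = SimulationConfig(seed=31)
        samples, _ = simulate_walk(true_speed, dur, cfg, np.random.default_rng(31))
        sl = AccelRecording("S1", "D1", T0, RATE, samples)
        est = assessment_speed(sl, speed_model)
        assert est == pytest.approx(true_speed, abs=0.1)

    def test_pure_standing_is_absent(self, speed_model):
        samples, _ = simulate_still(30.0, SimulationConfig(), np.random.default_rng(1))
        sl = AccelRecording("S1", "D1", T0, RATE, samples)
        assert assessment_speed(sl, speed_model) is None


class TestAgreement:
    def test_identity_line(self):
        pairs = [(v, v) for v in (0.3, 0.5, 0.8, 1.1)]
        st = agreement(pairs)
        assert st.slope == pytest.approx(1.0)
        assert st.intercept == pytest.approx(0.0, abs=1e-12)
        assert st.pearson_r == pytest.approx(1.0)
        assert st.residual_standard_error == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_linear_fit_recovered(self):
        ref = np.linspace(0.3, 1.2, 20)
        est = 0.78 * ref + 0.15
        st = agreement(list(zip(ref, est)))
        assert st.slope == pytest.approx(0.78)
        assert st.intercept == pytest.approx(0.15)
        assert st.residual_standard_error == pytest.approx(0.0, abs=1e-12)

    def test_noise_level_recovered(self):
        rng = np.random.default_rng(123)
        ref = rng.uniform(0.3, 1.2, size=1000)
        est = ref + rng.normal(0, 0.08, size=1000)
        st = agreement(list(zip(ref, est)))
        assert st.residual_standard_error == pytest.approx(0.08, abs=0.01)

    def test_matches_closed_form_ols_oracle(self):
        rng = np.random.default_rng(9)
        ref = rng.uniform(0.3, 1.2, size=200)
        est = 0.8 * ref + 0.1 + rng.normal(0, 0.05, size=200)
        st = agreement(list(zip(ref, est)))
        X = np.column_stack([np.ones_like(ref), ref])
        beta = np.linalg.solve(X.T @ X, X.T @ est)
        resid = est - X @ beta
        assert st.intercept == pytest.approx(beta[0], rel=1e-10)
        assert st.slope == pytest.approx(beta[1], rel=1e-10)
        assert st.residual_standard_error == pytest.approx(
            float(np.sqrt(resid @ resid / (len(ref) - 2))), rel=1e-10
        )

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3"):
            agreement([(0.5, 0.5), (0.6, 0.6)])

    def test_zero_reference_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            agreement([(0.5, 0.4), (0.5, 0.6), (0.5, 0.5)])


class TestValidityPairs:
    def _epoch(self, dailies, vid="V1", vdate=dt.date(2016, 3, 10)):
        ep = VisitEpoch("S1", vid, vdate, dailies=dailies)
        return ep

    def _daily(self, date, wear=6.0):
        return DailySummary("S1", date, wear, 1000.0)

    def _bout(self, steps, speed=0.8):
        return Bout(0, 60, step_count=steps, mean_speed_mps=speed)

    def test_pair_omitted_when_no_bouts_in_range(self):
        day = dt.date(2016, 3, 5)
        ep = self._epoch([self._daily(day)])
        a = _assessment("4mWT", dur_s=6.0, dist=4.0)
        pairs = build_validity_pairs(
            [ep], {day: [self._bout(30), self._bout(60)]}, [a]
        )
        assert pairs == []

    def test_boundary_bout_excluded_half_open(self):
        day = dt.date(2016, 3, 5)
        ep = self._epoch([self._daily(day)])
        a = _assessment("6MWT")
        pairs = build_validity_pairs([ep], {day: [self._bout(640.0)]}, [a])
        assert pairs == []
        pairs = build_validity_pairs([ep], {day: [self._bout(639.0)]}, [a])
        assert len(pairs) == 1

    def test_assessment_day_excluded_by_construction(self):
        a_day = dt.date(2018, 3, 1)  # start T0 + 600 s is on this date
        other = dt.date(2018, 3, 5)
        ep = self._epoch(
            [self._daily(a_day), self._daily(other)], vdate=dt.date(2018, 3, 2)
        )
        a = _assessment("6MWT")
        bouts = {
            a_day: [self._bout(100, speed=2.0)],
            other: [self._bout(100, speed=0.5)],
        }
        pairs = build_validity_pairs([ep], bouts, [a])
        assert len(pairs) == 1
        assert pairs[0].realworld_speed_mps == pytest.approx(0.5)

    def test_unknown_assessment_type_rejected(self):
        ep = self._epoch([])
        bad = AssessmentRecord(
            "S1", "V1", "4mWT", T0, T0 + pd.Timedelta(seconds=6), 4.0
        )
        with pytest.raises(ValueError, match="mapping"):
            build_validity_pairs([ep], {}, [bad], mapping={"6MWT": (80, 640)})

    def test_step_weighted_mean_over_bouts(self):
        day = dt.date(2016, 3, 5)
        ep = self._epoch([self._daily(day)])
        a = _assessment("6MWT")
        bouts = {day: [self._bout(100, 0.6), self._bout(300, 1.0)]}
        pairs = build_validity_pairs([ep], bouts, [a])
        assert pairs[0].realworld_speed_mps == pytest.approx(
            (100 * 0.6 + 300 * 1.0) / 400
        )
        unweighted = build_validity_pairs([ep], bouts, [a], step_weighted=False)
        assert unweighted[0].realworld_speed_mps == pytest.approx(0.8)

    def test_association_recovered_from_derived_cohort(self):
        cfg = DerivedCohortConfig(seed=17, n_subjects=30)
        cohort = simulate_derived_cohort(cfg)
        pairs = []
        for sid, visits in cohort.visits.items():
            dailies = [d for d in cohort.dailies if d.subject_id == sid]
            epochs = build_epochs(dailies, visits)
            kept, _ = apply_threshold(epochs)
            bouts_by_day = {
                date: bs
                for (s, date), bs in cohort.bouts_by_day.items()
                if s == sid
            }
            assessments = [a for a in cohort.assessments if a.subject_id == sid]
            pairs.extend(build_validity_pairs(kept, bouts_by_day, assessments))
        long_pairs = [p for p in pairs if p.assessment_type == "6MWT"]
        assert len(long_pairs) >= 30
        x = np.array([p.clinic_speed_mps for p in long_pairs])
        y = np.array([p.realworld_speed_mps for p in long_pairs])
        fit = stats.linregress(x, y)
        latent_slope, latent_r = cohort.latent_association
        assert fit.slope == pytest.approx(cfg.alpha, abs=0.05)
        assert fit.rvalue > 0
        assert fit.rvalue == pytest.approx(latent_r, abs=0.1)
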