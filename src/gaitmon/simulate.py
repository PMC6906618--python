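"""Synthetic triaxial accelerometry and study calendars with known truth.

The gait signal model is harmonic-plus-noise synthesis, not biomechanical
simulation: the vertical axis carries gravity plus a fundamental at the
cadence (with a second harmonic at 30% amplitude), the lateral and
longitudinal axes oscillate at half the cadence (the stride frequency)
with smaller amplitudes, and all axes carry white sensor noise.  Cadence
and amplitude scale linearly with walking speed:

    cadence_hz = c0 + c1 * speed        (defaults 1.2 + 0.7 * speed)
    A_axis     = a0 + a1 * speed        (per-axis, multiplicative noise)

These coefficients are fixtures chosen to resemble slow elderly gait; they
are not population estimates.  Everything is reproducible bit-exact from
a seed, and signals are clipped to the +/-6 g device range (an optional
flag adds 12-bit quantization).

Two levels of generation are provided:

* raw-signal (:func:`simulate_walk`, :func:`simulate_day`,
  :func:`simulate_cohort`) — exercises the full signal pipeline at desk
  scale;
* derived-level (:func:`simulate_derived_cohort`) — bout/daily/visit
  tables at trial scale for the compliance and ecological-validity
  analytics, with ground-truth compliance labels and a configurable
  clinic-to-real-world speed ratio (default alpha = 0.75).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bouts import Bout
from .io import (
    AccelRecording,
    AssessmentRecord,
    ObservationPeriod,
    merge_recordings,
    write_accel_hdf5,
    write_assessments,
)
from .weartime import DailySummary

__all__ = [
    "SimulationConfig",
    "Segment",
    "GroundTruth",
    "DerivedCohortConfig",
    "DerivedCohort",
    "simulate_walk",
    "simulate_still",
    "simulate_nonwalk_activity",
    "simulate_day",
    "simulate_cohort",
    "simulate_derived_cohort",
]

_LSB_G = 12.0 / 4096.0  # 12-bit resolution over +/-6 g


@dataclass
class SimulationConfig:
    """Raw-signal generator parameters (see module docstring for the model)."""

    seed: int = 0
    sampling_rate_hz: float = 100.0
    # cadence model: cadence_hz = c0 + c1 * speed
    cadence_c0: float = 1.2
    cadence_c1: float = 0.7
    # per-axis amplitude models: A = a0 + a1 * speed, in g
    amp_x: tuple[float, float] = (0.05, 0.30)
    amp_y: tuple[float, float] = (0.03, 0.12)
    amp_z: tuple[float, float] = (0.04, 0.18)
    amp_noise_sd: float = 0.05  # multiplicative, per window/segment
    harmonic_ratio: float = 0.3  # 2nd harmonic relative to fundamental (vertical)
    sensor_noise_sd_g: float = 0.02  # white noise while worn
    rest_noise_sd_g: float = 0.0015  # off-body device noise, below the 12-bit LSB
    sway_amp_g: float = 0.08  # non-walking postural sway amplitude
    sway_freq_hz: float = 0.3  # below the 0.7 Hz gait band
    quantize_12bit: bool = False
    # cohort layout
    n_subjects: int = 5
    n_days: int = 10
    speed_range_mps: tuple[float, float] = (0.3, 1.2)
    walks_per_day: int = 4
    walk_duration_s: tuple[float, float] = (20.0, 90.0)
    activity_block_s: float = 60.0
    offbody_still_s: float = 0.0  # leading off-body stillness per day


@dataclass
class Segment:
    """A labeled stretch of simulated signal."""

    start_s: float
    end_s: float
    label: str  # walking | activity | still
    speed_mps: float = float("nan")
    cadence_hz: float = float("nan")

    @property
    def true_steps(self) -> float:
        if self.label != "walking":
            return 0.0
        return self.cadence_hz * (self.end_s - self.start_s)


@dataclass
class GroundTruth:
    """Labels tiling each simulated recording, plus per-visit clinic speeds."""

    segments: dict[str, list[Segment]] = field(default_factory=dict)
    subject_speed: dict[str, float] = field(default_factory=dict)
    clinic_speed: dict[tuple[str, str], float] = field(default_factory=dict)


def _finish(samples: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    samples = np.clip(samples, -6.0, 6.0)
    if cfg.quantize_12bit:
        samples = np.round(samples / _LSB_G) * _LSB_G
    return samples


def simulate_walk(
    speed_mps: float,
    duration_s: float,
    cfg: SimulationConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, Segment]:
    """A continuous walking segment at a given true speed.

    Returns ``(samples, segment)``; the segment carries the true cadence
    (``c0 + c1 * speed``) and hence the true step count
    ``cadence * duration``.
    """
    cfg = cfg or SimulationConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if not 0 < speed_mps <= 2.0:
        raise ValueError("speed must be in (0, 2] m/s")
    if not duration_s > 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * cfg.sampling_rate_hz))
    t = np.arange(n) / cfg.sampling_rate_hz
    cadence = cfg.cadence_c0 + cfg.cadence_c1 * speed_mps

    def amp(model):
        a0, a1 = model
        return (a0 + a1 * speed_mps) * (1 + cfg.amp_noise_sd * rng.standard_normal())

    ax, ay, az = amp(cfg.amp_x), amp(cfg.amp_y), amp(cfg.amp_z)
    ph = rng.uniform(0, 2 * np.pi, size=4)
    x = (
        1.0
        + ax * np.sin(2 * np.pi * cadence * t + ph[0])
        + cfg.harmonic_ratio * ax * np.sin(2 * np.pi * 2 * cadence * t + ph[1])
    )
    y = ay * np.sin(2 * np.pi * 0.5 * cadence * t + ph[2])
    z = az * np.sin(2 * np.pi * 0.5 * cadence * t + ph[3])
    samples = np.column_stack([x, y, z])
    samples += cfg.sensor_noise_sd_g * rng.standard_normal(samples.shape)
    seg = Segment(0.0, n / cfg.sampling_rate_hz, "walking", speed_mps, cadence)
    return _finish(samples, cfg), seg


def simulate_still(
    duration_s: float,
    cfg: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
    orientation: str = "flat",
) -> tuple[np.ndarray, Segment]:
    """Off-body / motionless signal: a constant gravity vector plus noise
    below the stillness floor.  ``orientation`` 'flat' puts gravity on the
    longitudinal axis (device lying on a table), 'upright' on the vertical.
    """
    cfg = cfg or SimulationConfig()
    rng = rng or np.random.default_rng()
    n = int(round(duration_s * cfg.sampling_rate_hz))
    g = {"flat": [0.0, 0.0, 1.0], "upright": [1.0, 0.0, 0.0]}[orientation]
    samples = np.tile(g, (n, 1)) + cfg.rest_noise_sd_g * rng.standard_normal((n, 3))
    return _finish(samples, cfg), Segment(0.0, n / cfg.sampling_rate_hz, "still")


def simulate_nonwalk_activity(
    duration_s: float,
    cfg: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, Segment]:
    """Worn but not walking: slow postural sway below the gait band, with a
    random (often non-upright) orientation, plus sensor noise."""
    cfg = cfg or SimulationConfig()
    rng = rng or np.random.default_rng()
    n = int(round(duration_s * cfg.sampling_rate_hz))
    t = np.arange(n) / cfg.sampling_rate_hz
    tilt = rng.uniform(0, np.pi / 2)
    azim = rng.uniform(0, 2 * np.pi)
    g = np.array([np.cos(tilt), np.sin(tilt) * np.cos(azim), np.sin(tilt) * np.sin(azim)])
    sway = cfg.sway_amp_g * np.sin(
        2 * np.pi * cfg.sway_freq_hz * t + rng.uniform(0, 2 * np.pi)
    )
    samples = np.tile(g, (n, 1))
    samples[:, rng.integers(0, 3)] += sway
    samples += cfg.sensor_noise_sd_g * rng.standard_normal((n, 3))
    return _finish(samples, cfg), Segment(0.0, n / cfg.sampling_rate_hz, "activity")


def simulate_day(
    speed_mps: float,
    date_start: pd.Timestamp,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    subject_id: str = "S000",
    device_id: str = "D0",
    assessments: list[tuple[str, str, float]] | None = None,
) -> tuple[AccelRecording, list[Segment], list[AssessmentRecord]]:
    """One day's recording: optional off-body stillness, then alternating
    worn activity blocks and walking bouts (plus in-clinic walk tests on
    visit days).

    ``assessments`` entries are ``(visit_id, assessment_type, clinic_speed)``;
    a 4mWT covers 4 m at the clinic speed and a 6MWT lasts 360 s.
    """
    pieces: list[np.ndarray] = []
    segments: list[Segment] = []
    records: list[AssessmentRecord] = []
    t_cursor = 0.0

    def push(samples, seg: Segment):
        nonlocal t_cursor
        dur = samples.shape[0] / cfg.sampling_rate_hz
        segments.append(replace(seg, start_s=t_cursor, end_s=t_cursor + dur))
        pieces.append(samples)
        t_cursor += dur

    if cfg.offbody_still_s > 0:
        push(*simulate_still(cfg.offbody_still_s, cfg, rng))

    for visit_id, a_type, clinic_speed in assessments or []:
        push(*simulate_nonwalk_activity(cfg.activity_block_s, cfg, rng))
        if a_type == "4mWT":
            dur, dist = 4.0 / clinic_speed, 4.0
        elif a_type == "6MWT":
            dur, dist = 360.0, 360.0 * clinic_speed
        elif a_type == "400mWT":
            dur, dist = 400.0 / clinic_speed, 400.0
        else:
            raise ValueError(f"unknown assessment type {a_type!r}")
        a_start = date_start + pd.Timedelta(seconds=t_cursor)
        push(*simulate_walk(clinic_speed, dur, cfg, rng))
        records.append(
            AssessmentRecord(
                subject_id=subject_id,
                visit_id=visit_id,
                assessment_type=a_type,
                start_time=a_start,
                stop_time=a_start + pd.Timedelta(seconds=dur),
                distance_m=dist,
            )
        )

    for _ in range(cfg.walks_per_day):
        push(*simulate_nonwalk_activity(cfg.activity_block_s, cfg, rng))
        dur = rng.uniform(*cfg.walk_duration_s)
        v = float(np.clip(speed_mps * (1 + 0.1 * rng.standard_normal()), 0.1, 2.0))
        push(*simulate_walk(v, dur, cfg, rng))
    push(*simulate_nonwalk_activity(cfg.activity_block_s, cfg, rng))

    rec = AccelRecording(
        subject_id=subject_id,
        device_id=device_id,
        start_time=date_start,
        sampling_rate_hz=cfg.sampling_rate_hz,
        samples=np.vstack(pieces),
    )
    return rec, segments, records


def simulate_cohort(
    cfg: SimulationConfig,
    out_dir=None,
) -> tuple[dict[str, ObservationPeriod], list[AssessmentRecord], GroundTruth]:
    """A small raw-signal cohort consumable by the full pipeline.

    Each subject gets a characteristic speed from ``speed_range_mps`` and
    ``n_days`` daily recordings of alternating activity and walking; day 1
    is a visit day with a 4mWT and a 6MWT at the subject's clinic speed.
    When ``out_dir`` is given, canonical HDF5 files (one per subject-day)
    and an assessments table are written there.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()
    periods: dict[str, ObservationPeriod] = {}
    all_assessments: list[AssessmentRecord] = []
    base = pd.Timestamp("2018-03-01 09:00:00", tz="UTC")

    for s in range(cfg.n_subjects):
        sid = f"S{s:03d}"
        speed = float(rng.uniform(*cfg.speed_range_mps))
        truth.subject_speed[sid] = speed
        recs = []
        for d in range(cfg.n_days):
            day_start = base + pd.Timedelta(days=d)
            assessments = None
            if d == 0:
                clinic = float(np.clip(speed * (1 + 0.05 * rng.standard_normal()), 0.1, 2.0))
                assessments = [("V1", "4mWT", clinic), ("V1", "6MWT", clinic)]
                truth.clinic_speed[(sid, "V1")] = clinic
            rec, segs, a_recs = simulate_day(
                speed, day_start, cfg, rng, subject_id=sid, device_id="D0",
                assessments=assessments,
            )
            recs.append(rec)
            all_assessments.extend(a_recs)
            truth.segments.setdefault(sid, []).extend(
                replace(
                    sg,
                    start_s=sg.start_s + d * 86400.0,
                    end_s=sg.end_s + d * 86400.0,
                )
                for sg in segs
            )
        periods[sid] = merge_recordings(recs)

    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sid, period in periods.items():
            for i, rec in enumerate(period.recordings):
                write_accel_hdf5(out / f"{sid}_day{i:02d}.h5", rec)
        write_assessments(out / "assessments.csv", all_assessments)
    return periods, all_assessments, truth


# ---------------------------------------------------------------------------
# Derived-level (trial-scale) cohort
# ---------------------------------------------------------------------------


@dataclass
class DerivedCohortConfig:
    """Trial-scale generator for bout/daily/visit tables.

    Encodes the study-shaped relations the analytics must recover: an
    hourly step rate distributed around ``rate_per_hour`` with systematic
    undercounting below 3 h of daily wear, bout speeds rising with bout
    length, and per-visit real-world long-bout speed equal to
    ``alpha * clinic speed`` plus noise.
    """

    seed: int = 0
    n_subjects: int = 30
    visits_per_subject: int = 3
    visit_spacing_days: int = 56
    p_compliant: float = 0.75
    rate_per_hour: float = 410.0
    rate_noise_sd: float = 0.05  # multiplicative, per day
    clinic_speed_range: tuple[float, float] = (0.4, 1.0)
    visit_speed_sd: float = 0.03  # within-subject visit-to-visit variation
    alpha: float = 0.75  # real-world long-bout speed vs clinic speed
    assoc_noise_sd: float = 0.05  # per-visit noise on the association
    bout_lognorm_mu: float = float(np.log(12.0))
    bout_lognorm_sigma: float = 1.3
    bout_speed_noise_sd: float = 0.03
    compliant_wear_h: tuple[float, float] = (3.0, 12.0)
    noncompliant_wear_h: tuple[float, float] = (0.3, 2.9)


@dataclass
class DerivedCohort:
    dailies: list[DailySummary]
    visits: dict[str, list[tuple[str, _dt.date]]]  # per subject
    bouts_by_day: dict[_dt.date, list[Bout]]  # per subject via key (sid, date)
    assessments: list[AssessmentRecord]
    compliant_label: dict[tuple[str, str], bool]
    clinic_speed: dict[tuple[str, str], float]
    realworld_long_speed: dict[tuple[str, str], float]
    alpha: float

    @property
    def latent_association(self) -> tuple[float, float]:
        """Generator-set (slope, correlation) between clinic and latent
        real-world long-bout speed, computed from the drawn values."""
        keys = sorted(self.clinic_speed)
        x = np.array([self.clinic_speed[k] for k in keys])
        y = np.array([self.realworld_long_speed[k] for k in keys])
        slope = float(np.polyfit(x, y, 1)[0])
        r = float(np.corrcoef(x, y)[0, 1])
        return slope, r


def _speed_profile(steps: float) -> float:
    """Relative bout speed vs bout length: rises from ~0.65 for very short
    bouts to 1.0 at 80+ steps (monotone nondecreasing)."""
    lo, hi = 4.0, 80.0
    f = np.clip(np.log(max(steps, lo) / lo) / np.log(hi / lo), 0.0, 1.0)
    return 0.65 + 0.35 * float(f)


def simulate_derived_cohort(cfg: DerivedCohortConfig) -> DerivedCohort:
    """Generate per-day wear/step summaries and bout tables around visits.

    Every generated day lies inside exactly one visit's 20-day epoch
    (visits are spaced far enough apart not to overlap); each visit is
    labeled compliant or not before its days are drawn, and the days are
    drawn consistently with the label (>= 3 days of >= 3 h wear for
    compliant visits, at most 2 otherwise).
    """
    rng = np.random.default_rng(cfg.seed)
    dailies: list[DailySummary] = []
    visits: dict[str, list[tuple[str, _dt.date]]] = {}
    bouts_by_day: dict = {}
    assessments: list[AssessmentRecord] = []
    labels: dict[tuple[str, str], bool] = {}
    clinic: dict[tuple[str, str], float] = {}
    realworld: dict[tuple[str, str], float] = {}
    base_date = _dt.date(2016, 3, 1)
    mean_bout_steps = float(np.exp(cfg.bout_lognorm_mu + cfg.bout_lognorm_sigma**2 / 2))

    for s in range(cfg.n_subjects):
        sid = f"P{s:03d}"
        base_speed = float(rng.uniform(*cfg.clinic_speed_range))
        visits[sid] = []
        for v in range(cfg.visits_per_subject):
            vid = f"V{v + 1}"
            vdate = base_date + _dt.timedelta(days=s % 7 + v * cfg.visit_spacing_days)
            visits[sid].append((vid, vdate))
            key = (sid, vid)

            c_speed = float(
                np.clip(base_speed + cfg.visit_speed_sd * rng.standard_normal(), 0.2, 1.6)
            )
            clinic[key] = c_speed
            rw_speed = float(
                np.clip(
                    cfg.alpha * c_speed + cfg.assoc_noise_sd * rng.standard_normal(),
                    0.1,
                    2.0,
                )
            )
            realworld[key] = rw_speed

            compliant = bool(rng.random() < cfg.p_compliant)
            labels[key] = compliant
            n_comp = int(rng.integers(3, 11)) if compliant else int(rng.integers(0, 3))
            n_noncomp = int(rng.integers(2, 6))

            day_offsets = [d for d in range(-10, 11) if d != 0]
            rng.shuffle(day_offsets)
            chosen = day_offsets[: n_comp + n_noncomp]
            comp_days = chosen[:n_comp]

            for off in chosen:
                date = vdate + _dt.timedelta(days=off)
                if off in comp_days:
                    wear = float(rng.uniform(*cfg.compliant_wear_h))
                else:
                    wear = float(rng.uniform(*cfg.noncompliant_wear_h))
                # hourly rate stabilizes above 3 h of wear, undercounts below
                undercount = min(1.0, wear / 3.0)
                rate = (
                    cfg.rate_per_hour
                    * undercount
                    * (1 + cfg.rate_noise_sd * rng.standard_normal())
                )
                target_steps = max(rate * wear, 0.0)

                day_bouts: list[Bout] = []
                total = 0.0
                t_cursor = 0.0
                while total < target_steps:
                    steps = float(
                        np.exp(
                            cfg.bout_lognorm_mu
                            + cfg.bout_lognorm_sigma * rng.standard_normal()
                        )
                    )
                    steps = min(steps, 1500.0)
                    if total + steps > target_steps + mean_bout_steps:
                        steps = max(target_steps - total, 1.0)
                    speed = rw_speed * _speed_profile(steps) + (
                        cfg.bout_speed_noise_sd * rng.standard_normal()
                    )
                    speed = float(np.clip(speed, 0.05, 2.5))
                    cadence = 1.2 + 0.7 * speed
                    dur = steps / cadence
                    day_bouts.append(
                        Bout(
                            start_time_s=t_cursor,
                            end_time_s=t_cursor + dur,
                            windows=[],
                            step_count=steps,
                            mean_speed_mps=speed,
                            mean_Fx_hz=cadence,
                        )
                    )
                    t_cursor += dur + 60.0
                    total += steps

                dailies.append(
                    DailySummary(
                        subject_id=sid,
                        date=date,
                        wear_hours=wear,
                        total_steps=total,
                    )
                )
                bouts_by_day[(sid, date)] = day_bouts

            a_start = pd.Timestamp(
                _dt.datetime.combine(vdate, _dt.time(10, 0)), tz="UTC"
            )
            for a_type in ("4mWT", "6MWT"):
                if a_type == "4mWT":
                    dur, dist = 4.0 / c_speed, 4.0
                else:
                    dur, dist = 360.0, 360.0 * c_speed
                assessments.append(
                    AssessmentRecord(
                        subject_id=sid,
                        visit_id=vid,
                        assessment_type=a_type,
                        start_time=a_start,
                        stop_time=a_start + pd.Timedelta(seconds=dur),
                        distance_m=dist,
                    )
                )
                a_start += pd.Timedelta(seconds=dur + 600)

    return DerivedCohort(
        dailies=dailies,
        visits=visits,
        bouts_by_day=bouts_by_day,
        assessments=assessments,
        compliant_label=labels,
        clinic_speed=clinic,
        realworld_long_speed=realworld,
        alpha=cfg.alpha,
    )
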