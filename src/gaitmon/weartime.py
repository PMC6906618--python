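"""Wear-time detection and per-day wear/step summaries.

Worn versus not-worn is decided with a stillness run-length rule standard
in actigraphy: fixed-length epochs whose per-axis acceleration standard
deviation stays below a stillness floor on all three axes, for at least a
minimum run length, are not-worn (the device is off-body, e.g. on a table);
unrecorded gaps are not-worn by definition.  Daily summaries normalize the
step count to the detected wear time for that day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bouts import Bout
from .io import ObservationPeriod

__all__ = [
    "WeartimeConfig",
    "WearInterval",
    "DailySummary",
    "detect_weartime",
    "daily_summaries",
    "dailies_to_frame",
]


@dataclass
class WeartimeConfig:
    epoch_s: float = 60.0
    #: stillness floor, g; below the 12-bit LSB noise of a +/-6 g sensor a
    #: resting device sits well under this
    still_sd_g: float = 0.004
    min_nonwear_min: float = 20.0
    tz_offset_hours: float = 0.0


@dataclass
class WearInterval:
    start: pd.Timestamp
    end: pd.Timestamp
    worn: bool

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class DailySummary:
    """Wear hours and step totals for one local calendar day."""

    subject_id: str
    date: object  # datetime.date, local
    wear_hours: float
    total_steps: float

    @property
    def steps_per_wear_hour(self) -> float | None:
        if self.wear_hours <= 0:
            return None
        return self.total_steps / self.wear_hours


def _merge_adjacent(intervals: list[WearInterval]) -> list[WearInterval]:
    out: list[WearInterval] = []
    for iv in intervals:
        if out and out[-1].worn == iv.worn and out[-1].end == iv.start:
            out[-1] = WearInterval(out[-1].start, iv.end, iv.worn)
        else:
            out.append(iv)
    return out


def detect_weartime(
    period: ObservationPeriod, cfg: WeartimeConfig | None = None
) -> list[WearInterval]:
    """Label the observation period as worn / not-worn intervals.

    The returned intervals tile the period span exactly: recorded signal is
    split into ``epoch_s`` epochs, runs of still epochs of at least
    ``min_nonwear_min`` minutes become not-worn, and recording gaps are
    not-worn.
    """
    cfg = cfg or WeartimeConfig()
    min_run = max(1, int(round(cfg.min_nonwear_min * 60.0 / cfg.epoch_s)))
    intervals: list[WearInterval] = []

    prev_end = None
    for rec in period.recordings:
        if prev_end is not None and rec.start_time > prev_end:
            intervals.append(WearInterval(prev_end, rec.start_time, worn=False))
        n_epoch = int(round(cfg.epoch_s * rec.sampling_rate_hz))
        n = rec.n_samples
        bounds = list(range(0, n, n_epoch))
        still = []
        for b in bounds:
            seg = rec.samples[b : min(b + n_epoch, n)]
            still.append(bool((seg.std(axis=0) < cfg.still_sd_g).all()))
        # mark runs of stillness meeting the minimum length as not-worn
        worn = np.ones(len(still), dtype=bool)
        i = 0
        while i < len(still):
            if still[i]:
                j = i
                while j < len(still) and still[j]:
                    j += 1
                if (j - i) >= min_run:
                    worn[i:j] = False
                i = j
            else:
                i += 1
        for k, b in enumerate(bounds):
            e = min(b + n_epoch, n)
            intervals.append(
                WearInterval(
                    rec.time_of_sample(b),
                    rec.time_of_sample(e),
                    worn=bool(worn[k]),
                )
            )
        prev_end = rec.end_time

    return _merge_adjacent(intervals)


def daily_summaries(
    period: ObservationPeriod,
    bouts: list[Bout],
    wear: list[WearInterval],
    tz_offset_hours: float = 0.0,
) -> list[DailySummary]:
    """One summary per local calendar day with any recording.

    Wear seconds are split exactly at local midnight; a bout's steps are
    attributed whole to the day containing the bout's start (bout times are
    seconds from the period start).
    """
    off = pd.Timedelta(hours=tz_offset_hours)
    wear_s: dict = {}
    days: set = set()

    for iv in wear:
        start = iv.start + off
        end = iv.end + off
        day = start.normalize()
        while day < end:
            nxt = day + pd.Timedelta(days=1)
            seg = (min(end, nxt) - max(start, day)).total_seconds()
            days.add(day.date())
            if iv.worn and seg > 0:
                wear_s[day.date()] = wear_s.get(day.date(), 0.0) + seg
            day = nxt

    t0 = period.start_time
    steps: dict = {}
    for b in bouts:
        d = (t0 + pd.Timedelta(seconds=b.start_time_s) + off).date()
        steps[d] = steps.get(d, 0.0) + b.step_count
        days.add(d)

    return [
        DailySummary(
            subject_id=period.subject_id,
            date=d,
            wear_hours=wear_s.get(d, 0.0) / 3600.0,
            total_steps=steps.get(d, 0.0),
        )
        for d in sorted(days)
    ]


def dailies_to_frame(dailies: list[DailySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [d.subject_id for d in dailies],
            "date": [d.date.isoformat() for d in dailies],
            "wear_hours": [d.wear_hours for d in dailies],
            "total_steps": [d.total_steps for d in dailies],
            "steps_per_wear_hour": [
                d.steps_per_wear_hour if d.steps_per_wear_hour is not None else np.nan
                for d in dailies
            ],
        }
    )
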