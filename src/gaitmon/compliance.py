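"""Visit epochs and the two-component wear-time compliance threshold.

Real-world gait behavior around a clinic visit is summarized over a 20-day
epoch straddling the visit (days visit-10 .. visit+10, the visit day itself
excluded).  A visit is retained for analysis only if the patient wore the
device at least ``h_min`` hours per day on at least ``d_min`` days of the
epoch (defaults 3 h / 3 d) — the minimum found to give stable step-count
estimates without excluding most visits.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .weartime import DailySummary

__all__ = [
    "VisitEpoch",
    "ComplianceConfig",
    "build_epochs",
    "apply_threshold",
    "stabilization_curves",
    "epochs_to_frame",
]


@dataclass
class ComplianceConfig:
    h_min: float = 3.0
    d_min: int = 3
    half_window_days: int = 10


@dataclass
class VisitEpoch:
    """The 20-day window straddling one clinic visit (visit day excluded)."""

    subject_id: str
    visit_id: str
    visit_date: _dt.date
    dailies: list[DailySummary] = field(default_factory=list)
    h_min: float = 3.0
    d_min: int = 3

    @property
    def n_days_recorded(self) -> int:
        return len(self.dailies)

    @property
    def n_compliant_days(self) -> int:
        return sum(1 for d in self.dailies if d.wear_hours >= self.h_min)

    @property
    def is_compliant(self) -> bool:
        return self.n_compliant_days >= self.d_min

    @property
    def compliant_dailies(self) -> list[DailySummary]:
        return [d for d in self.dailies if d.wear_hours >= self.h_min]

    @property
    def mean_daily_steps(self) -> float:
        """Mean total steps over compliant days (nan when none)."""
        c = self.compliant_dailies
        if not c:
            return float("nan")
        return float(np.mean([d.total_steps for d in c]))

    def day_range(self, half_window_days: int = 10):
        lo = self.visit_date - _dt.timedelta(days=half_window_days)
        hi = self.visit_date + _dt.timedelta(days=half_window_days)
        return lo, hi


def build_epochs(
    dailies: list[DailySummary],
    visits: list[tuple[str, _dt.date]],
    cfg: ComplianceConfig | None = None,
) -> list[VisitEpoch]:
    """One epoch per visit from a subject's daily summaries.

    Each daily summary inside a visit's +/-10-day window (visit day itself
    excluded) joins that visit's epoch; a day inside two overlapping
    windows is assigned to the nearer visit, ties to the earlier visit, so
    no day is double-counted in cohort tables.  A visit with no recorded
    day in its window yields an empty epoch, not an error.
    """
    cfg = cfg or ComplianceConfig()
    visits = sorted(visits, key=lambda v: (v[1], v[0]))
    subject_id = dailies[0].subject_id if dailies else ""
    epochs = [
        VisitEpoch(
            subject_id=subject_id,
            visit_id=vid,
            visit_date=vdate,
            h_min=cfg.h_min,
            d_min=cfg.d_min,
        )
        for vid, vdate in visits
    ]

    for d in dailies:
        best = None
        best_key = None
        for ep in epochs:
            delta = abs((d.date - ep.visit_date).days)
            if delta > cfg.half_window_days:
                continue
            key = (delta, ep.visit_date)
            if best_key is None or key < best_key:
                best, best_key = ep, key
        # assign to the nearest visit, then drop the visit day itself
        if best is not None and d.date != best.visit_date:
            best.dailies.append(d)

    for ep in epochs:
        ep.dailies.sort(key=lambda d: d.date)
    return epochs


def apply_threshold(
    epochs: list[VisitEpoch], h_min: float = 3.0, d_min: int = 3
) -> tuple[list[VisitEpoch], pd.DataFrame]:
    """Keep epochs with >= ``d_min`` days of >= ``h_min`` wear hours.

    Returns the kept epochs and an exclusion report covering every epoch
    (kept or not) with its per-visit reason.
    """
    kept = []
    rows = []
    for ep in epochs:
        n_comp = sum(1 for d in ep.dailies if d.wear_hours >= h_min)
        ok = n_comp >= d_min
        if ok:
            kept.append(ep)
            reason = "compliant"
        elif ep.n_days_recorded == 0:
            reason = "no_recording_in_window"
        else:
            reason = f"fewer_than_{d_min}_days_with_{h_min}h_wear"
        rows.append(
            {
                "subject_id": ep.subject_id,
                "visit_id": ep.visit_id,
                "n_days_recorded": ep.n_days_recorded,
                "n_compliant_days": n_comp,
                "kept": ok,
                "reason": reason,
            }
        )
    return kept, pd.DataFrame(rows)


def stabilization_curves(
    dailies: list[DailySummary],
    epochs: list[VisitEpoch],
    h_min: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """The two stabilization analyses behind the compliance threshold.

    Returns ``(rate_by_wear_hours, steps_by_n_days, grand_mean_rate)``:

    * per integer-floored wear-hour bin, the distribution of hourly step
      rate (mean/median/sd/n) across days — the rate drops sharply below
      ``h_min`` hours of wear;
    * per number of compliant days in the epoch, the distribution of
      mean daily steps across visits;
    * the grand mean steps-per-wear-hour over all days with wear >= h_min.
    """
    cols_a = ["wear_hour_bin", "n_days", "mean_rate", "median_rate", "sd_rate"]
    rows_a = []
    by_bin: dict[int, list[float]] = {}
    compliant_rates = []
    for d in dailies:
        r = d.steps_per_wear_hour
        if r is None:
            continue
        by_bin.setdefault(int(np.floor(d.wear_hours)), []).append(r)
        if d.wear_hours >= h_min:
            compliant_rates.append(r)
    for b in sorted(by_bin):
        vals = np.asarray(by_bin[b], dtype=float)
        rows_a.append(
            {
                "wear_hour_bin": b,
                "n_days": len(vals),
                "mean_rate": float(vals.mean()),
                "median_rate": float(np.median(vals)),
                "sd_rate": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            }
        )
    rate_by_wear = pd.DataFrame(rows_a, columns=cols_a)

    cols_b = ["n_compliant_days", "n_visits", "mean_steps", "median_steps", "sd_steps"]
    rows_b = []
    by_days: dict[int, list[float]] = {}
    for ep in epochs:
        m = ep.mean_daily_steps
        if np.isfinite(m):
            by_days.setdefault(ep.n_compliant_days, []).append(m)
    for k in sorted(by_days):
        vals = np.asarray(by_days[k], dtype=float)
        rows_b.append(
            {
                "n_compliant_days": k,
                "n_visits": len(vals),
                "mean_steps": float(vals.mean()),
                "median_steps": float(np.median(vals)),
                "sd_steps": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            }
        )
    steps_by_days = pd.DataFrame(rows_b, columns=cols_b)

    grand_mean = float(np.mean(compliant_rates)) if compliant_rates else float("nan")
    return rate_by_wear, steps_by_days, grand_mean


def epochs_to_frame(epochs: list[VisitEpoch]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [e.subject_id for e in epochs],
            "visit_id": [e.visit_id for e in epochs],
            "visit_date": [e.visit_date.isoformat() for e in epochs],
            "n_days_recorded": [e.n_days_recorded for e in epochs],
            "n_compliant_days": [e.n_compliant_days for e in epochs],
            "is_compliant": [e.is_compliant for e in epochs],
            "mean_daily_steps": [e.mean_daily_steps for e in epochs],
        }
    )
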