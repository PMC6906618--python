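"""In-clinic assessment extraction, agreement statistics, and ecological
validity pairing of clinic walk tests with real-world bouts.

The clinic reference speed of a walk test is distance / elapsed time; the
accelerometer-derived speed is the step-weighted mean of window speed
predictions over the assessment interval (extracted with a +/-2 s pad
around the recorded start/stop timestamps).  Agreement is an OLS fit of
estimate on reference with residual standard error and Pearson r.  For
ecological validity, each assessment is paired with real-world gait speed
in bouts of comparable length (4mWT with [5, 20)-step bouts; 6MWT and
400mWT with [80, 640)-step bouts) inside the compliant visit epoch,
excluding the assessment days themselves.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bouts import Bout
from .compliance import VisitEpoch
from .detect import PlausibilityConfig, analyze_recording
from .gait import GaitSpeedRegressor, parameterize_windows
from .io import AccelRecording, AssessmentRecord, ObservationPeriod

__all__ = [
    "AgreementStats",
    "ValidityPair",
    "DEFAULT_BIN_MAPPING",
    "extract_assessment_window",
    "assessment_speed",
    "agreement",
    "build_validity_pairs",
    "pairs_to_frame",
]

#: Default assessment-type -> half-open step-count bout-length range.
DEFAULT_BIN_MAPPING = {
    "4mWT": (5, 20),
    "6MWT": (80, 640),
    "400mWT": (80, 640),
}


@dataclass
class AgreementStats:
    """OLS agreement of estimated vs reference speed."""

    n: int
    slope: float
    intercept: float
    pearson_r: float
    residual_standard_error: float


@dataclass
class ValidityPair:
    """One clinic assessment matched with same-context real-world speed."""

    subject_id: str
    visit_id: str
    assessment_type: str
    clinic_speed_mps: float
    realworld_speed_mps: float
    bin_label: str
    n_bouts: int


class GapError(ValueError):
    """An assessment interval is not covered by a recording."""


def extract_assessment_window(
    period: ObservationPeriod, a: AssessmentRecord, pad_s: float = 2.0
) -> AccelRecording:
    """Sample-exact slice covering [start - pad_s, stop + pad_s]."""
    t0 = a.start_time - pd.Timedelta(seconds=pad_s)
    t1 = a.stop_time + pd.Timedelta(seconds=pad_s)
    rec = period.covering_recording(t0, t1)
    if rec is None:
        raise GapError(
            f"assessment {a.assessment_type} at visit {a.visit_id} "
            f"({t0} .. {t1}) spans a recording gap"
        )
    return rec.slice_time(t0, t1)


def assessment_speed(
    rec_slice: AccelRecording,
    model: GaitSpeedRegressor,
    cfg: PlausibilityConfig | None = None,
    min_windows: int = 3,
) -> float | None:
    """Estimated mean gait speed over an extracted assessment interval.

    Step-weighted mean of per-window speed predictions; None (absent, not
    an error) when fewer than ``min_windows`` walking windows are detected.
    """
    cfg = cfg or PlausibilityConfig()
    windows, filtered = analyze_recording(rec_slice, cfg)
    gws = parameterize_windows(rec_slice, windows, filtered, cfg, model=model)
    if len(gws) < min_windows:
        return None
    w = np.array([gw.step_contribution for gw in gws])
    v = np.array([gw.speed_mps for gw in gws])
    if w.sum() <= 0:
        return float(v.mean())
    return float((w * v).sum() / w.sum())


def agreement(pairs: list[tuple[float, float]]) -> AgreementStats:
    """OLS of estimate on reference with residual standard error.

    RSE = sqrt(SSR / (n - 2)); raises on fewer than 3 pairs or a
    zero-variance reference.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 (reference, estimate) pairs")
    ref = np.array([p[0] for p in pairs], dtype=float)
    est = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(ref) == 0:
        raise ValueError("reference speeds have zero variance")
    fit = stats.linregress(ref, est)
    resid = est - (fit.intercept + fit.slope * ref)
    rse = float(np.sqrt(resid @ resid / (len(ref) - 2)))
    return AgreementStats(
        n=len(ref),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        residual_standard_error=rse,
    )


def _assessment_days(
    assessments: list[AssessmentRecord], visit_id: str, tz_offset_hours: float
) -> set[_dt.date]:
    off = pd.Timedelta(hours=tz_offset_hours)
    return {
        (a.start_time + off).date()
        for a in assessments
        if a.visit_id == visit_id
    }


def build_validity_pairs(
    epochs: list[VisitEpoch],
    bouts_by_day: dict[_dt.date, list[Bout]],
    assessments: list[AssessmentRecord],
    mapping: dict[str, tuple[float, float]] | None = None,
    step_weighted: bool = True,
    tz_offset_hours: float = 0.0,
) -> list[ValidityPair]:
    """Pair each assessment in a compliant epoch with real-world bout speed.

    The real-world side is the step-weighted mean speed over all bouts
    whose step count falls in the assessment type's half-open bin range,
    on epoch days excluding every calendar day containing any assessment
    for that visit.  A pair is omitted when no bouts land in the range.
    Only compliant epochs should be passed in.
    """
    mapping = mapping or DEFAULT_BIN_MAPPING
    by_visit: dict[tuple[str, str], list[AssessmentRecord]] = {}
    for a in assessments:
        if a.assessment_type not in mapping:
            raise ValueError(f"no bout-length mapping for {a.assessment_type!r}")
        by_visit.setdefault((a.subject_id, a.visit_id), []).append(a)

    out: list[ValidityPair] = []
    for ep in epochs:
        visit_assessments = by_visit.get((ep.subject_id, ep.visit_id), [])
        if not visit_assessments:
            continue
        excluded = _assessment_days(assessments, ep.visit_id, tz_offset_hours)
        epoch_days = {d.date for d in ep.dailies} - excluded
        for a in visit_assessments:
            lo, hi = mapping[a.assessment_type]
            sel = [
                b
                for day in sorted(epoch_days)
                for b in bouts_by_day.get(day, [])
                if lo <= b.step_count < hi
            ]
            if not sel:
                continue
            steps = np.array([b.step_count for b in sel])
            speeds = np.array([b.mean_speed_mps for b in sel])
            if step_weighted:
                rw = float((steps * speeds).sum() / steps.sum())
            else:
                rw = float(speeds.mean())
            out.append(
                ValidityPair(
                    subject_id=ep.subject_id,
                    visit_id=ep.visit_id,
                    assessment_type=a.assessment_type,
                    clinic_speed_mps=a.reference_speed_mps,
                    realworld_speed_mps=rw,
                    bin_label=f"[{lo},{hi})",
                    n_bouts=len(sel),
                )
            )
    return out


def pairs_to_frame(pairs: list[ValidityPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in pairs],
            "visit_id": [p.visit_id for p in pairs],
            "assessment_type": [p.assessment_type for p in pairs],
            "clinic_speed_mps": [p.clinic_speed_mps for p in pairs],
            "realworld_speed_mps": [p.realworld_speed_mps for p in pairs],
            "bin_label": [p.bin_label for p in pairs],
            "n_bouts": [p.n_bouts for p in pairs],
        }
    )
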