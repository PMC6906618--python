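"""Reading, writing, merging and time-aligning raw accelerometry and study metadata.

Acceleration is stored in units of g throughout (device-native range is
+/-6 g); axis convention is x = vertical, y = lateral, z = longitudinal.
Timestamps are UTC internally; local-time day boundaries are derived from a
per-subject timezone offset downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "AccelRecording",
    "ObservationPeriod",
    "AssessmentRecord",
    "FormatError",
    "read_accel_hdf5",
    "write_accel_hdf5",
    "merge_recordings",
    "read_assessments",
    "write_assessments",
    "ASSESSMENT_TYPES",
]

#: Walk tests understood by the pipeline: 4 m walk test, 6-minute walk test,
#: 400 m walk test.
ASSESSMENT_TYPES = ("4mWT", "6MWT", "400mWT")

ACCEL_RANGE_G = 6.0


class FormatError(ValueError):
    """A file does not match any supported on-disk layout."""


def _as_utc(ts) -> pd.Timestamp:
    ts = pd.Timestamp(ts)
    if ts.tzinfo is None:
        return ts.tz_localize("UTC")
    return ts.tz_convert("UTC")


@dataclass
class AccelRecording:
    """A contiguous triaxial acceleration recording from one device.

    Parameters
    ----------
    subject_id, device_id : str
        Opaque identifiers.
    start_time : timestamp
        Absolute UTC time of the first sample.
    sampling_rate_hz : float
        Nominal sampling rate (100 Hz for the supported device).
    samples : ndarray of shape (n, 3)
        Acceleration in g; columns are (vertical, lateral, longitudinal).
    """

    subject_id: str
    device_id: str
    start_time: pd.Timestamp
    sampling_rate_hz: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.start_time = _as_utc(self.start_time)
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise FormatError(
                f"expected 3 axes, got array of shape {self.samples.shape}"
            )
        bad = np.flatnonzero(~np.isfinite(self.samples).all(axis=1))
        if bad.size:
            raise ValueError(f"non-finite acceleration at sample index {bad[0]}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + pd.Timedelta(seconds=self.duration_s)

    def time_of_sample(self, i: int) -> pd.Timestamp:
        return self.start_time + pd.Timedelta(seconds=i / self.sampling_rate_hz)

    def slice_time(self, t0, t1) -> "AccelRecording":
        """Sample-exact sub-recording covering [t0, t1)."""
        t0, t1 = _as_utc(t0), _as_utc(t1)
        i0 = int(round((t0 - self.start_time).total_seconds() * self.sampling_rate_hz))
        i1 = int(round((t1 - self.start_time).total_seconds() * self.sampling_rate_hz))
        i0 = max(i0, 0)
        i1 = min(i1, self.n_samples)
        if i1 <= i0:
            raise ValueError("empty slice")
        return AccelRecording(
            subject_id=self.subject_id,
            device_id=self.device_id,
            start_time=self.time_of_sample(i0),
            sampling_rate_hz=self.sampling_rate_hz,
            samples=self.samples[i0:i1],
        )


@dataclass
class ObservationPeriod:
    """All recordings for one subject merged onto a single timeline.

    Recordings are sorted and non-overlapping after the merge; gaps between
    them are annotated explicitly and never imputed.
    """

    subject_id: str
    recordings: list[AccelRecording]
    gaps: list[tuple[pd.Timestamp, pd.Timestamp]] = field(default_factory=list)
    n_dropped_samples: int = 0

    @property
    def start_time(self) -> pd.Timestamp:
        return self.recordings[0].start_time

    @property
    def end_time(self) -> pd.Timestamp:
        return self.recordings[-1].end_time

    @property
    def span_s(self) -> float:
        return (self.end_time - self.start_time).total_seconds()

    @property
    def recorded_s(self) -> float:
        return sum(r.duration_s for r in self.recordings)

    @property
    def gap_s(self) -> float:
        return sum((g1 - g0).total_seconds() for g0, g1 in self.gaps)

    def covering_recording(self, t0, t1) -> AccelRecording | None:
        """The recording fully containing [t0, t1), or None."""
        t0, t1 = _as_utc(t0), _as_utc(t1)
        for rec in self.recordings:
            if rec.start_time <= t0 and t1 <= rec.end_time:
                return rec
        return None


@dataclass
class AssessmentRecord:
    """One timed in-clinic walk test with reference distance and timestamps."""

    subject_id: str
    visit_id: str
    assessment_type: str
    start_time: pd.Timestamp
    stop_time: pd.Timestamp
    distance_m: float

    def __post_init__(self) -> None:
        if self.assessment_type not in ASSESSMENT_TYPES:
            raise ValueError(
                f"unknown assessment_type {self.assessment_type!r}; "
                f"allowed: {', '.join(ASSESSMENT_TYPES)}"
            )
        self.start_time = _as_utc(self.start_time)
        self.stop_time = _as_utc(self.stop_time)
        if not self.stop_time > self.start_time:
            raise ValueError(
                f"stop_time must be after start_time for "
                f"{self.subject_id}/{self.visit_id}/{self.assessment_type}"
            )
        self.distance_m = float(self.distance_m)
        if not self.distance_m >= 0:
            raise ValueError("distance_m must be nonnegative")

    @property
    def elapsed_s(self) -> float:
        return (self.stop_time - self.start_time).total_seconds()

    @property
    def reference_speed_mps(self) -> float:
        """Average speed over the test: distance travelled / elapsed time."""
        v = self.distance_m / self.elapsed_s
        if not np.isfinite(v) or v <= 0:
            raise ValueError("reference speed must be finite and positive")
        return v


# ---------------------------------------------------------------------------
# HDF5 layout
#
# Canonical layout: group "/accel" with dataset "data" (N x 3 float32, g,
# columns vertical/lateral/longitudinal), attributes start_time (ISO-8601),
# sampling_rate_hz, subject_id, device_id.  The reader additionally maps
# common alternative spellings (dataset "acceleration" or "acc", a root-level
# dataset, a per-sample "timestamps" vector instead of start+rate) onto it.
# ---------------------------------------------------------------------------

_DATASET_NAMES = ("data", "acceleration", "acc")


def write_accel_hdf5(path, rec: AccelRecording) -> None:
    """Write a recording in the canonical HDF5 layout."""
    with h5py.File(path, "w") as f:
        g = f.create_group("accel")
        g.create_dataset("data", data=rec.samples.astype(np.float32))
        g.attrs["start_time"] = rec.start_time.isoformat()
        g.attrs["sampling_rate_hz"] = float(rec.sampling_rate_hz)
        g.attrs["subject_id"] = rec.subject_id
        g.attrs["device_id"] = rec.device_id


def _find_dataset(f: h5py.File):
    containers = [f]
    if "accel" in f and isinstance(f["accel"], h5py.Group):
        containers.insert(0, f["accel"])
    for c in containers:
        for name in _DATASET_NAMES:
            if name in c and isinstance(c[name], h5py.Dataset):
                return c, c[name]
    raise FormatError(
        "no acceleration dataset found (looked for "
        + "/".join(_DATASET_NAMES)
        + " under /accel or the file root)"
    )


def _attr(container, f, name):
    if name in container.attrs:
        return container.attrs[name]
    if name in f.attrs:
        return f.attrs[name]
    return None


def read_accel_hdf5(path) -> AccelRecording:
    """Read a recording, tolerating common layout variants.

    Raises
    ------
    FormatError
        If the acceleration dataset or the timing information is missing,
        naming the missing element.
    ValueError
        If samples are non-finite (with the offending sample index).
    """
    with h5py.File(path, "r") as f:
        container, dset = _find_dataset(f)
        data = np.asarray(dset, dtype=np.float64)
        if data.ndim != 2 or data.shape[1] != 3:
            raise FormatError(f"expected 3 axes, got dataset of shape {data.shape}")

        rate = _attr(container, f, "sampling_rate_hz")
        start = _attr(container, f, "start_time")
        if (rate is None or start is None) and "timestamps" in container:
            ts = np.asarray(container["timestamps"], dtype=np.float64)
            if ts.size != data.shape[0]:
                raise FormatError("timestamps length does not match data")
            if rate is None:
                rate = 1.0 / float(np.median(np.diff(ts)))
            if start is None:
                start = pd.Timestamp(ts[0], unit="s", tz="UTC")
        if rate is None:
            raise FormatError("missing attribute 'sampling_rate_hz'")
        if start is None:
            raise FormatError("missing attribute 'start_time'")
        if isinstance(start, bytes):
            start = start.decode()

        def _str_attr(name, default):
            v = _attr(container, f, name)
            if v is None:
                return default
            return v.decode() if isinstance(v, bytes) else str(v)

        return AccelRecording(
            subject_id=_str_attr("subject_id", "unknown"),
            device_id=_str_attr("device_id", "unknown"),
            start_time=start,
            sampling_rate_hz=float(rate),
            samples=data,
        )


# ---------------------------------------------------------------------------
# Merging device recordings into one observation period
# ---------------------------------------------------------------------------


def merge_recordings(recs: list[AccelRecording]) -> ObservationPeriod:
    """Merge recordings (possibly from several devices) into one timeline.

    Recordings are sorted by start time; where two overlap, the earlier
    recording's samples are kept and the later recording's overlapping head
    is dropped (deterministic and order-independent after sorting).  A
    recording fully contained in an earlier one is dropped with a warning.
    Gaps between consecutive recordings are annotated, never filled.
    """
    if not recs:
        raise ValueError("no recordings to merge")
    subject_ids = {r.subject_id for r in recs}
    if len(subject_ids) > 1:
        raise ValueError(f"mixed subject_ids in merge: {sorted(subject_ids)}")

    ordered = sorted(recs, key=lambda r: (r.start_time, r.end_time))
    kept: list[AccelRecording] = []
    gaps: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    n_dropped = 0
    for rec in ordered:
        if not kept:
            kept.append(rec)
            continue
        prev = kept[-1]
        if rec.end_time <= prev.end_time:
            warnings.warn(
                f"recording from device {rec.device_id} fully contained in an "
                "earlier recording; dropped",
                stacklevel=2,
            )
            n_dropped += rec.n_samples
            continue
        overlap_s = (prev.end_time - rec.start_time).total_seconds()
        if overlap_s > 0.5 / rec.sampling_rate_hz:
            n_drop = int(round(overlap_s * rec.sampling_rate_hz))
            n_drop = min(n_drop, rec.n_samples)
            n_dropped += n_drop
            rec = AccelRecording(
                subject_id=rec.subject_id,
                device_id=rec.device_id,
                start_time=rec.time_of_sample(n_drop),
                sampling_rate_hz=rec.sampling_rate_hz,
                samples=rec.samples[n_drop:],
            )
        else:
            gap_s = (rec.start_time - prev.end_time).total_seconds()
            if gap_s > 1.5 / rec.sampling_rate_hz:
                gaps.append((prev.end_time, rec.start_time))
        kept.append(rec)

    return ObservationPeriod(
        subject_id=ordered[0].subject_id,
        recordings=kept,
        gaps=gaps,
        n_dropped_samples=n_dropped,
    )


# ---------------------------------------------------------------------------
# Assessment metadata tables (comma-separated canonical; tabs tolerated)
# ---------------------------------------------------------------------------

_ASSESSMENT_COLUMNS = [
    "subject_id",
    "visit_id",
    "assessment_type",
    "start_time",
    "stop_time",
    "distance_m",
]


def read_assessments(path) -> list[AssessmentRecord]:
    """Read walk-test metadata from a delimited text table."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _ASSESSMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"assessments table missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                AssessmentRecord(
                    subject_id=str(row["subject_id"]),
                    visit_id=str(row["visit_id"]),
                    assessment_type=str(row["assessment_type"]),
                    start_time=row["start_time"],
                    stop_time=row["stop_time"],
                    distance_m=row["distance_m"],
                )
            )
        except ValueError as e:
            raise ValueError(f"assessments row {i}: {e}") from e
    return records


def write_assessments(path, records: list[AssessmentRecord]) -> None:
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "visit_id": [r.visit_id for r in records],
            "assessment_type": [r.assessment_type for r in records],
            "start_time": [r.start_time.isoformat() for r in records],
            "stop_time": [r.stop_time.isoformat() for r in records],
            "distance_m": [r.distance_m for r in records],
        }
    )
    df.to_csv(path, index=False)
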