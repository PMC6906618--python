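"""Walking detection: short-time Fourier analysis over ~2.5 s windows.

The raw signal is band-pass filtered to the gait band (0.7-3 Hz), divided
into overlapping windows, and each window is kept as candidate walking only
if (a) the mean acceleration vector points close enough to the vertical
axis (the subject is upright), (b) overall activity is plausible for
walking, and (c) the vertical axis carries a dominant in-band frequency.
Rejection reasons are recorded in that order so false-positive, non-walking
motion is removed before step parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum

import numpy as np
from scipy import signal

from .io import AccelRecording

__all__ = [
    "PlausibilityConfig",
    "AnalysisWindow",
    "RejectionReason",
    "bandpass",
    "window_indices",
    "dominant_frequency",
    "classify_window",
    "analyze_recording",
]


class RejectionReason(str, Enum):
    NONE = "none"
    GRAVITY_ANGLE = "gravity_angle"
    ACTIVITY = "activity"
    NO_DOMINANT_FREQUENCY = "no_dominant_frequency"


@dataclass
class PlausibilityConfig:
    """Windowing, filtering and plausibility thresholds.

    Defaults: 2.5 s windows with 50% overlap, 0.7-3 Hz gait band, upright
    tolerance of 45 degrees to the vertical, activity (sd of the vector
    magnitude) between 0.02 g and 2.0 g, and a dominant spectral peak at
    least ``prominence_ratio`` times the median in-band magnitude.
    """

    window_s: float = 2.5
    overlap_fraction: float = 0.5
    band_low_hz: float = 0.7
    band_high_hz: float = 3.0
    angle_max_deg: float = 45.0
    act_min_g: float = 0.02
    act_max_g: float = 2.0
    prominence_ratio: float = 3.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PlausibilityConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class AnalysisWindow:
    """One ~2.5 s analysis window (half-open sample-index range)."""

    start_index: int
    end_index: int
    dom_freq_hz: np.ndarray = field(default=None)  # (3,), nan where absent
    dom_mag: np.ndarray = field(default=None)  # (3,)
    mean_accel_g: np.ndarray = field(default=None)  # (3,), from the raw signal
    activity_g: float = float("nan")
    is_walking: bool = False
    rejection_reason: RejectionReason = RejectionReason.NONE

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index


def bandpass(
    x: np.ndarray,
    low_hz: float,
    high_hz: float,
    rate_hz: float,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, no group delay).

    Accepts a 1-D signal or an (n, k) array filtered along axis 0.
    """
    if not (0 < low_hz < high_hz < rate_hz / 2):
        raise ValueError("need 0 < low_hz < high_hz < rate_hz/2")
    x = np.asarray(x, dtype=np.float64)
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rate_hz, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    n = x.shape[0]
    if n <= padlen:
        raise ValueError(
            f"signal of length {n} too short for zero-phase filtering; "
            f"need more than {padlen} samples"
        )
    return signal.sosfiltfilt(sos, x, axis=0)


def window_indices(
    n_samples: int,
    rate_hz: float,
    window_s: float = 2.5,
    overlap_fraction: float = 0.5,
) -> list[tuple[int, int]]:
    """Half-open index ranges of overlapping analysis windows.

    Consecutive windows advance by ``window_s * (1 - overlap_fraction)``;
    a final partial window is discarded.
    """
    if not (0 <= overlap_fraction <= 0.9):
        raise ValueError("overlap_fraction must be in [0, 0.9]")
    wlen = int(round(window_s * rate_hz))
    hop = int(round(window_s * (1 - overlap_fraction) * rate_hz))
    if hop < 1:
        raise ValueError("hop shorter than one sample")
    out = []
    start = 0
    while start + wlen <= n_samples:
        out.append((start, start + wlen))
        start += hop
    return out


def dominant_frequency(
    win: np.ndarray,
    rate_hz: float,
    band_low_hz: float = 0.7,
    band_high_hz: float = 3.0,
    prominence_ratio: float = 3.0,
    pad_factor: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis dominant in-band frequency from a Hann-tapered FFT.

    Returns ``(freq, mag)`` arrays of shape (3,); ``freq`` is nan where the
    largest in-band peak fails the prominence criterion (magnitude at least
    ``prominence_ratio`` times the median in-band magnitude), i.e. where
    there is no dominant frequency.
    """
    win = np.atleast_2d(np.asarray(win, dtype=np.float64))
    if win.shape[0] == 1 and win.shape[1] != 3:
        win = win.T
    n = win.shape[0]
    taper = signal.get_window("hann", n)[:, None]
    detrended = win - win.mean(axis=0, keepdims=True)
    nfft = pad_factor * n
    spec = np.abs(np.fft.rfft(detrended * taper, n=nfft, axis=0))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate_hz)
    in_band = (freqs >= band_low_hz) & (freqs <= band_high_hz)
    band_spec = spec[in_band]
    band_freqs = freqs[in_band]

    peak_idx = np.argmax(band_spec, axis=0)
    peak_mag = band_spec[peak_idx, np.arange(band_spec.shape[1])]
    med = np.median(band_spec, axis=0)
    ok = peak_mag > prominence_ratio * np.maximum(med, 1e-300)
    freq = np.where(ok, band_freqs[peak_idx], np.nan)
    return freq, peak_mag


def classify_window(w: AnalysisWindow, cfg: PlausibilityConfig) -> AnalysisWindow:
    """Set ``is_walking`` and ``rejection_reason`` on a parameterized window.

    Checks run in the order gravity angle -> activity -> dominant frequency
    (on the vertical axis); the first failure is recorded.
    """
    mean_vec = w.mean_accel_g
    norm = np.linalg.norm(mean_vec)
    if norm == 0:
        angle_deg = 90.0
    else:
        cosang = np.clip(abs(mean_vec[0]) / norm, -1.0, 1.0)
        angle_deg = float(np.degrees(np.arccos(cosang)))

    if angle_deg > cfg.angle_max_deg:
        w.is_walking = False
        w.rejection_reason = RejectionReason.GRAVITY_ANGLE
    elif not (cfg.act_min_g <= w.activity_g <= cfg.act_max_g):
        w.is_walking = False
        w.rejection_reason = RejectionReason.ACTIVITY
    elif not np.isfinite(w.dom_freq_hz[0]):
        w.is_walking = False
        w.rejection_reason = RejectionReason.NO_DOMINANT_FREQUENCY
    else:
        w.is_walking = True
        w.rejection_reason = RejectionReason.NONE
    return w


def analyze_recording(
    rec: AccelRecording,
    cfg: PlausibilityConfig | None = None,
) -> tuple[list[AnalysisWindow], np.ndarray]:
    """Run the full window-level detection pass over one recording.

    Returns the classified windows and the band-pass-filtered signal (so
    downstream step parameterization reuses it without re-filtering).
    Recordings shorter than one window yield no windows.
    """
    cfg = cfg or PlausibilityConfig()
    idx = window_indices(
        rec.n_samples, rec.sampling_rate_hz, cfg.window_s, cfg.overlap_fraction
    )
    if not idx:
        return [], np.empty((0, 3))
    filtered = bandpass(
        rec.samples, cfg.band_low_hz, cfg.band_high_hz, rec.sampling_rate_hz
    )
    windows = []
    for start, end in idx:
        raw = rec.samples[start:end]
        filt = filtered[start:end]
        mag = np.linalg.norm(raw, axis=1)
        freq, pmag = dominant_frequency(
            filt,
            rec.sampling_rate_hz,
            cfg.band_low_hz,
            cfg.band_high_hz,
            cfg.prominence_ratio,
        )
        w = AnalysisWindow(
            start_index=start,
            end_index=end,
            dom_freq_hz=freq,
            dom_mag=pmag,
            mean_accel_g=raw.mean(axis=0),
            activity_g=float(mag.std()),
        )
        windows.append(classify_window(w, cfg))
    return windows, filtered
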