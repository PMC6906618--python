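"""Walking-bout segmentation and bout-length binning.

Contiguous walking windows are combined into a single bout of continuous
walking provided the vertical step frequency F_x does not vary by more than
an empirical factor (default 1.6-fold) between windows.  Bouts are then
grouped by length in steps — short bouts of everyday shuffling versus long
sustained walks carry different behavioral context.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gait import GaitWindow

__all__ = [
    "Bout",
    "BoutConfig",
    "segment_bouts",
    "bin_bouts",
    "bin_label",
    "bout_speed_summary",
    "bouts_to_frame",
    "DEFAULT_BIN_EDGES",
]

#: Step-count bin edges (half-open bins [e_i, e_{i+1})).
DEFAULT_BIN_EDGES = (1, 5, 10, 20, 40, 80, 160, 320, 640)


@dataclass
class BoutConfig:
    merge_factor: float = 1.6
    max_gap_s: float = 1.25  # one window hop at the 2.5 s / 50% defaults
    min_steps: float = 3.0
    running_mean: bool = False  # compare F_x to the bout running mean instead
    bin_edges: tuple = DEFAULT_BIN_EDGES


@dataclass
class Bout:
    """A maximal run of contiguous walking windows with stable cadence."""

    start_time_s: float
    end_time_s: float
    windows: list[GaitWindow] = field(repr=False, default_factory=list)
    step_count: float = 0.0
    mean_speed_mps: float = float("nan")
    mean_Fx_hz: float = float("nan")
    length_bin: str = ""

    @property
    def duration_s(self) -> float:
        return self.end_time_s - self.start_time_s

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def _finalize(windows: list[GaitWindow]) -> Bout:
    steps = np.array([gw.step_contribution for gw in windows], dtype=float)
    speeds = np.array([gw.speed_mps for gw in windows], dtype=float)
    fx = np.array([gw.F_x for gw in windows], dtype=float)
    total = steps.sum()
    # step-weighted mean speed, aligned with per-step speed projection
    if total > 0 and np.isfinite(speeds).all():
        mean_speed = float((steps * speeds).sum() / total)
    else:
        mean_speed = float(np.nanmean(speeds)) if np.isfinite(speeds).any() else float("nan")
    return Bout(
        start_time_s=windows[0].start_time_s,
        end_time_s=windows[-1].start_time_s + windows[-1].duration_s,
        windows=list(windows),
        step_count=float(total),
        mean_speed_mps=mean_speed,
        mean_Fx_hz=float(fx.mean()),
    )


def segment_bouts(
    windows: list[GaitWindow],
    merge_factor: float = 1.6,
    max_gap_s: float = 1.25,
    min_steps: float = 3.0,
    running_mean: bool = False,
) -> tuple[list[Bout], float]:
    """Greedy left-to-right combination of walking windows into bouts.

    A window extends the current bout iff its start follows the previous
    window's start within ``max_gap_s`` (plus numerical slack) and its F_x
    is within ``merge_factor``-fold of the previous window's F_x (or of the
    bout's running-mean F_x when ``running_mean``).  Bouts with fewer than
    ``min_steps`` steps are discarded; their step total is returned so step
    accounting stays conserved.

    Returns ``(bouts, discarded_steps)``.
    """
    starts = [gw.start_time_s for gw in windows]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("windows must be time-ordered")

    raw: list[list[GaitWindow]] = []
    current: list[GaitWindow] = []
    eps = 1e-9
    for gw in windows:
        if not current:
            current = [gw]
            continue
        prev = current[-1]
        gap_ok = gw.start_time_s - prev.start_time_s <= max_gap_s + eps
        ref_fx = (
            float(np.mean([w.F_x for w in current])) if running_mean else prev.F_x
        )
        pair = sorted((ref_fx, gw.F_x))
        freq_ok = pair[0] > 0 and pair[1] / pair[0] <= merge_factor + eps
        if gap_ok and freq_ok:
            current.append(gw)
        else:
            raw.append(current)
            current = [gw]
    if current:
        raw.append(current)

    bouts, discarded = [], 0.0
    for run in raw:
        b = _finalize(run)
        if b.step_count < min_steps:
            discarded += b.step_count
        else:
            bouts.append(b)
    return bouts, discarded


def bin_label(edges, steps: float) -> str:
    """Half-open bin label for a step count (e.g. ``"[10,20)"``)."""
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    if steps < edges[0]:
        return f"[0,{edges[0]})"
    for lo, hi in zip(edges, edges[1:]):
        if lo <= steps < hi:
            return f"[{lo},{hi})"
    return f"[{edges[-1]},inf)"


def bin_bouts(bouts: list[Bout], edges=DEFAULT_BIN_EDGES) -> dict[str, list[Bout]]:
    """Group bouts into half-open step-count bins; labels are set in place."""
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    out: dict[str, list[Bout]] = {}
    for b in bouts:
        label = bin_label(edges, b.step_count)
        b.length_bin = label
        out.setdefault(label, []).append(b)
    return out


def bout_speed_summary(
    bouts: list[Bout], edges=DEFAULT_BIN_EDGES
) -> pd.DataFrame:
    """Per-bin speed distribution summary and fraction of total bouts.

    Columns: bin, n, fraction, median_speed_mps, q25, q75.  Empty input
    yields an empty frame.
    """
    cols = ["bin", "n", "fraction", "median_speed_mps", "q25", "q75"]
    if not bouts:
        return pd.DataFrame(columns=cols)
    grouped = bin_bouts(bouts, edges)
    total = len(bouts)
    rows = []
    for label, bs in grouped.items():
        speeds = np.array([b.mean_speed_mps for b in bs], dtype=float)
        rows.append(
            {
                "bin": label,
                "n": len(bs),
                "fraction": len(bs) / total,
                "median_speed_mps": float(np.nanmedian(speeds)),
                "q25": float(np.nanpercentile(speeds, 25)),
                "q75": float(np.nanpercentile(speeds, 75)),
            }
        )
    df = pd.DataFrame(rows, columns=cols)
    key = df["bin"].map(lambda s: float(s.strip("[").split(",")[0]))
    return df.assign(_k=key).sort_values("_k").drop(columns="_k").reset_index(drop=True)


def bouts_to_frame(
    bouts: list[Bout], subject_id: str, t0: pd.Timestamp
) -> pd.DataFrame:
    """Bout-level export table (delimited-text friendly)."""
    rows = []
    for b in bouts:
        rows.append(
            {
                "subject_id": subject_id,
                "bout_start": (t0 + pd.Timedelta(seconds=b.start_time_s)).isoformat(),
                "bout_end": (t0 + pd.Timedelta(seconds=b.end_time_s)).isoformat(),
                "n_steps": b.step_count,
                "mean_speed_mps": b.mean_speed_mps,
                "mean_fx": b.mean_Fx_hz,
                "length_bin": b.length_bin,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "bout_start",
            "bout_end",
            "n_steps",
            "mean_speed_mps",
            "mean_fx",
            "length_bin",
        ],
    )
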