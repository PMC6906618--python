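"""Step parameterization and gait-speed prediction.

For each walking window the band-passed signal is turned into an analytic
signal via the Hilbert transform, yielding per-axis instantaneous frequency
F, phase phi and amplitude envelope A.  F on the vertical axis is the step
frequency (cadence), phi the relative position within a step, and the
amplitude envelope summaries (A_x, A_y, A_z) reflect the force involved in
a step independent of its exact timing.  Gait speed is projected per window
by an ordinary-least-squares linear model on the three amplitudes and their
pairwise interaction terms.

The packaged default model coefficients were calibrated on the built-in
synthetic-gait generator (they are synthetic-calibrated, not population
estimates); retraining on labeled real data is a single call to
:func:`fit_speed_model`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .detect import AnalysisWindow, PlausibilityConfig
from .io import AccelRecording

__all__ = [
    "GaitWindow",
    "hilbert_params",
    "parameterize_windows",
    "step_contribution",
    "assign_step_contributions",
    "GaitSpeedRegressor",
    "fit_speed_model",
    "predict_speed",
    "save_model",
    "load_model",
    "load_default_model",
]

#: Physiological speed ceiling (m/s) for this slow-walking population;
#: predictions are clamped to [0, V_MAX] to avoid extrapolation artifacts.
V_MAX = 3.0

#: Fraction trimmed from each end of a window before averaging the Hilbert
#: envelope / instantaneous frequency, to suppress finite-window edge
#: artifacts of the analytic signal.
_EDGE_TRIM = 0.1


@dataclass
class GaitWindow:
    """Hilbert step parameters for one walking analysis window."""

    window: AnalysisWindow
    start_time_s: float  # seconds from recording start
    duration_s: float
    F_hz: np.ndarray  # (3,) mean instantaneous frequency per axis
    A_g: np.ndarray  # (3,) mean envelope per axis
    phi: np.ndarray | None = None  # (n, 3) unwrapped phase, optional payload
    step_contribution: float = 0.0
    speed_mps: float = float("nan")

    @property
    def F_x(self) -> float:
        """Vertical-axis step frequency in Hz."""
        return float(self.F_hz[0])


def hilbert_params(
    win: np.ndarray, rate_hz: float, keep_phase: bool = False
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Analytic-signal parameters (F, phi, A) per axis of a band-passed window.

    A is the mean Hilbert envelope, F the mean instantaneous frequency
    (unwrapped-phase derivative / 2 pi); both are averaged over the central
    part of the window to avoid edge effects.  phi is the unwrapped phase
    (returned only when ``keep_phase``), monotone nondecreasing for a clean
    periodic signal.
    """
    win = np.asarray(win, dtype=np.float64)
    if win.ndim == 1:
        win = win[:, None]
    n = win.shape[0]
    if not np.any(win):
        raise ValueError("all-zero window has no analytic-signal parameters")
    analytic = hilbert(win, axis=0)
    envelope = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic), axis=0)

    lo = int(np.floor(_EDGE_TRIM * n))
    hi = n - lo
    A = envelope[lo:hi].mean(axis=0)
    inst_freq = np.diff(phase, axis=0) * rate_hz / (2 * np.pi)
    F = inst_freq[lo : hi - 1].mean(axis=0)
    return F, (phase if keep_phase else None), A


def step_contribution(
    F_x_hz: float, window_s: float, overlap_fraction: float, contiguous_prev: bool
) -> float:
    """Steps attributed to one window.

    A window whose predecessor walking window is contiguous contributes
    only over the hop ``window_s * (1 - overlap_fraction)`` so overlapping
    windows are not double-counted; an isolated window (or the first of a
    contiguous run) contributes over its full length.  Summed over a bout
    this gives approximately F_x times the bout duration.
    """
    share_s = window_s * (1 - overlap_fraction) if contiguous_prev else window_s
    return F_x_hz * share_s


def assign_step_contributions(
    gait_windows: list[GaitWindow],
    window_s: float = 2.5,
    overlap_fraction: float = 0.5,
) -> None:
    """Set per-window step contributions over a time-ordered window list.

    Each window is credited with the time it newly covers — the advance
    since the previous walking window, capped at the window length — so a
    run of overlapping windows contributes F_x times the run duration with
    no double counting, and an isolated window contributes F_x * window_s.
    """
    prev_start = None
    for gw in gait_windows:
        if prev_start is None:
            share_s = window_s
        else:
            share_s = min(max(gw.start_time_s - prev_start, 0.0), window_s)
        gw.step_contribution = gw.F_x * share_s
        prev_start = gw.start_time_s


def parameterize_windows(
    rec: AccelRecording,
    windows: list[AnalysisWindow],
    filtered: np.ndarray,
    cfg: PlausibilityConfig | None = None,
    model: "GaitSpeedRegressor | None" = None,
) -> list[GaitWindow]:
    """Compute Hilbert parameters (and optionally speed) for walking windows."""
    cfg = cfg or PlausibilityConfig()
    rate = rec.sampling_rate_hz
    out: list[GaitWindow] = []
    for w in windows:
        if not w.is_walking:
            continue
        F, _, A = hilbert_params(filtered[w.start_index : w.end_index], rate)
        # instantaneous frequency can drift out of band on noisy windows;
        # fall back to the STFT dominant frequency, which is in band by
        # construction
        if not (cfg.band_low_hz <= F[0] <= cfg.band_high_hz):
            F = F.copy()
            F[0] = w.dom_freq_hz[0]
        gw = GaitWindow(
            window=w,
            start_time_s=w.start_index / rate,
            duration_s=w.n_samples / rate,
            F_hz=np.asarray(F, dtype=float),
            A_g=np.asarray(A, dtype=float),
        )
        out.append(gw)
    assign_step_contributions(out, cfg.window_s, cfg.overlap_fraction)
    if model is not None:
        amps = np.array([gw.A_g for gw in out])
        if len(out):
            speeds = model.predict(amps)
            for gw, v in zip(out, speeds):
                gw.speed_mps = float(v)
    return out


# ---------------------------------------------------------------------------
# Linear gait-speed model
# ---------------------------------------------------------------------------

_BASE_TERMS = ["A_x", "A_y", "A_z", "A_xA_y", "A_xA_z", "A_yA_z"]


class GaitSpeedRegressor(BaseEstimator, RegressorMixin):
    """OLS gait-speed model on Hilbert amplitudes and their interactions.

    The design is (1, A_x, A_y, A_z, A_x*A_y, A_x*A_z, A_y*A_z), optionally
    extended with the three-way product and/or the vertical step frequency
    F_x.  Predictions are clamped to [0, ``v_max``] m/s.

    Parameters
    ----------
    include_threeway : bool
        Add the A_x*A_y*A_z term.
    include_freq : bool
        Add F_x as a predictor (X then needs a fourth column).
    v_max : float
        Physiological ceiling for the clamp, in m/s.
    """

    def __init__(
        self,
        include_threeway: bool = False,
        include_freq: bool = False,
        v_max: float = V_MAX,
    ):
        self.include_threeway = include_threeway
        self.include_freq = include_freq
        self.v_max = v_max

    @property
    def term_names_(self) -> list[str]:
        terms = list(_BASE_TERMS)
        if self.include_threeway:
            terms.append("A_xA_yA_z")
        if self.include_freq:
            terms.append("F_x")
        return terms

    def _design(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-D: columns A_x, A_y, A_z[, F_x]")
        need = 4 if self.include_freq else 3
        if X.shape[1] != need:
            raise ValueError(f"expected {need} feature columns, got {X.shape[1]}")
        ax, ay, az = X[:, 0], X[:, 1], X[:, 2]
        cols = [ax, ay, az, ax * ay, ax * az, ay * az]
        if self.include_threeway:
            cols.append(ax * ay * az)
        if self.include_freq:
            cols.append(X[:, 3])
        return np.column_stack([np.ones(len(X))] + cols)

    def fit(self, X, y):
        D = self._design(X)
        y = np.asarray(y, dtype=np.float64)
        if len(y) != D.shape[0]:
            raise ValueError("X and y length mismatch")
        beta, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
        if rank < D.shape[1]:
            raise ValueError(
                "rank-deficient design (collinear amplitudes); provide more "
                "diverse training data"
            )
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        resid = y - D @ beta
        self.n_train_ = len(y)
        dof = max(len(y) - D.shape[1], 1)
        self.residual_std_ = float(np.sqrt(resid @ resid / dof))
        self.train_speed_range_ = (float(y.min()), float(y.max()))
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        D = self._design(X)
        pred = D @ np.concatenate([[self.intercept_], self.coef_])
        return np.clip(pred, 0.0, self.v_max)


@dataclass
class _Training:
    n: int
    speed_range: tuple[float, float]
    seed: int | None = None


def fit_speed_model(
    training: list[tuple[GaitWindow, float]],
    seed: int | None = None,
    min_windows: int = 50,
    min_speed_range: float = 0.4,
    **model_kwargs,
) -> GaitSpeedRegressor:
    """Fit the linear speed model from (window, true speed) pairs.

    Requires at least ``min_windows`` windows spanning at least
    ``min_speed_range`` m/s of true speed; the fit itself is deterministic
    given the inputs (``seed`` is recorded as training metadata only).
    """
    if len(training) < min_windows:
        raise ValueError(
            f"need at least {min_windows} training windows, got {len(training)}"
        )
    speeds = np.array([v for _, v in training], dtype=float)
    if speeds.max() - speeds.min() < min_speed_range:
        raise ValueError(
            f"training speeds must span at least {min_speed_range} m/s "
            f"(got {speeds.max() - speeds.min():.3f})"
        )
    model = GaitSpeedRegressor(**model_kwargs)
    feats = [gw.A_g for gw, _ in training]
    if model.include_freq:
        feats = [np.r_[gw.A_g, gw.F_x] for gw, _ in training]
    model.fit(np.array(feats), speeds)
    model.training_seed_ = seed
    return model


def predict_speed(model: GaitSpeedRegressor, gw: GaitWindow) -> float:
    """Clamped linear speed prediction for a single walking window."""
    x = np.r_[gw.A_g, gw.F_x] if model.include_freq else gw.A_g
    return float(model.predict(x[None, :])[0])


# ---------------------------------------------------------------------------
# Model serialization: diffable term,coefficient delimited text
# ---------------------------------------------------------------------------


def save_model(path, model: GaitSpeedRegressor) -> None:
    check_is_fitted(model, "coef_")
    lines = [
        "# gaitmon linear speed model",
        f"# n_train = {getattr(model, 'n_train_', 'unknown')}",
        f"# speed_range_mps = {getattr(model, 'train_speed_range_', 'unknown')}",
        f"# residual_std_mps = {getattr(model, 'residual_std_', 'unknown')}",
        f"# seed = {getattr(model, 'training_seed_', 'unknown')}",
        "term,coefficient",
        f"intercept,{float(model.intercept_)!r}",
        f"v_max,{float(model.v_max)!r}",
        f"include_threeway,{int(model.include_threeway)}",
        f"include_freq,{int(model.include_freq)}",
    ]
    lines += [
        f"{t},{float(c)!r}" for t, c in zip(model.term_names_, model.coef_)
    ]
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


def load_model(path) -> GaitSpeedRegressor:
    vals: dict[str, float] = {}
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line or line.startswith("#") or line == "term,coefficient":
                continue
            term, val = line.split(",", 1)
            vals[term] = float(val)
    model = GaitSpeedRegressor(
        include_threeway=bool(vals.pop("include_threeway", 0)),
        include_freq=bool(vals.pop("include_freq", 0)),
        v_max=vals.pop("v_max", V_MAX),
    )
    model.intercept_ = vals.pop("intercept")
    model.coef_ = np.array([vals[t] for t in model.term_names_])
    return model


def load_default_model() -> GaitSpeedRegressor:
    """The packaged synthetic-calibrated default model."""
    ref = importlib.resources.files("gaitmon.data") / "default_speed_model.csv"
    with importlib.resources.as_file(ref) as path:
        return load_model(path)
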