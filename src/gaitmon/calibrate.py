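"""Calibration of the linear speed model on the built-in simulator.

Runs synthetic walks at known speeds through the real detection and
Hilbert-parameterization pipeline and fits the amplitude model to the
measured window features, so the packaged default model reflects what the
pipeline actually measures (including band-pass attenuation and envelope
edge effects) rather than the generator's latent amplitudes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .detect import PlausibilityConfig, analyze_recording
from .gait import GaitSpeedRegressor, GaitWindow, fit_speed_model, parameterize_windows
from .io import AccelRecording
from .simulate import SimulationConfig, simulate_walk

__all__ = ["walk_windows", "training_windows", "train_synthetic_model"]

_T0 = pd.Timestamp("2018-01-01 12:00:00", tz="UTC")


def walk_windows(
    speed_mps: float,
    duration_s: float,
    sim_cfg: SimulationConfig,
    rng: np.random.Generator,
    cfg: PlausibilityConfig | None = None,
    model: GaitSpeedRegressor | None = None,
) -> list[GaitWindow]:
    """Pipeline-measured walking windows of one simulated walk."""
    cfg = cfg or PlausibilityConfig()
    samples, _ = simulate_walk(speed_mps, duration_s, sim_cfg, rng)
    rec = AccelRecording(
        subject_id="train",
        device_id="sim",
        start_time=_T0,
        sampling_rate_hz=sim_cfg.sampling_rate_hz,
        samples=samples,
    )
    windows, filtered = analyze_recording(rec, cfg)
    return parameterize_windows(rec, windows, filtered, cfg, model=model)


def training_windows(
    seed: int = 0,
    n_walks: int = 120,
    walk_s: float = 30.0,
    speed_range: tuple[float, float] = (0.3, 1.2),
    sim_cfg: SimulationConfig | None = None,
) -> list[tuple[GaitWindow, float]]:
    """(window, true speed) pairs over walks with speeds uniform in range."""
    sim_cfg = sim_cfg or SimulationConfig(seed=seed)
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_walks):
        v = float(rng.uniform(*speed_range))
        for gw in walk_windows(v, walk_s, sim_cfg, rng):
            pairs.append((gw, v))
    return pairs


def train_synthetic_model(
    seed: int = 0,
    n_walks: int = 120,
    walk_s: float = 30.0,
    speed_range: tuple[float, float] = (0.3, 1.2),
    **model_kwargs,
) -> GaitSpeedRegressor:
    """Fit the speed model on simulator output (synthetic-calibrated)."""
    pairs = training_windows(seed, n_walks, walk_s, speed_range)
    return fit_speed_model(pairs, seed=seed, **model_kwargs)
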