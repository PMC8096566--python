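"""Synthetic breakthrough-curve generator.

Emulates fixed-bed adsorption data: within each operating condition
(c0, h0, u) the outlet ratio C/C0 rises sigmoidally with time as the bed
saturates.  The front is a logistic

    C/C0(t) = 1 / (1 + exp(−k (t − t50))),   t50 = a·h0 / (u · c0^β),

so the midpoint shifts later for taller beds and earlier for faster flow and
(for β > 0) higher feed concentration — the qualitative behaviour of a real
column without any mass-balance PDE.  Additive Gaussian noise on C/C0 is
truncated to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .dataset import FEATURE_ORDER, TARGET, Dataset


@dataclass
class SyntheticConfig:
    """Condition grid, time grid, logistic-front parameters and noise level.

    Defaults give the Cartesian grid 2 × 2 × 3 conditions × 17 time points
    = 204 records, matching the scale of a typical breakthrough study.
    """

    c0_values: tuple[float, ...] = (8.0, 24.0)
    h0_values: tuple[float, ...] = (7.0, 11.0)
    u_values: tuple[float, ...] = (80.0, 160.0, 240.0)
    t_start: float = 0.0
    t_end: float = 120.0
    n_points: int = 17
    scale_a: float = 700.0
    conc_exponent_beta: float = 0.5
    steepness_k: float = 0.05
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.scale_a > 0 and self.steepness_k > 0 and self.conc_exponent_beta >= 0):
            raise ValueError("front parameters must be positive (beta >= 0)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_points < 2:
            raise ValueError("need at least two time points")
        if not (self.c0_values and self.h0_values and self.u_values):
            raise ValueError("empty condition grid")

    @property
    def n_conditions(self) -> int:
        return len(self.c0_values) * len(self.h0_values) * len(self.u_values)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("c0_values", "h0_values", "u_values"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def midpoint_time(c0: float, h0: float, u: float, config: SyntheticConfig) -> float:
    """t50 = a·h0 / (u·c0^β): later for tall beds, earlier for fast flow."""
    return config.scale_a * h0 / (u * c0**config.conc_exponent_beta)


def true_curve(t, c0: float, h0: float, u: float, config: SyntheticConfig) -> np.ndarray:
    """Noise-free logistic breakthrough front, monotone increasing in t."""
    t = np.asarray(t, float)
    t50 = midpoint_time(c0, h0, u, config)
    return expit(config.steepness_k * (t - t50))


def generate(config: SyntheticConfig) -> Dataset:
    """Cartesian product of condition grid × time grid, with truncated noise.

    Bitwise-deterministic per seed; record count = n_conditions × n_points.
    """
    rng = np.random.default_rng(config.seed)
    t_grid = np.linspace(config.t_start, config.t_end, config.n_points)
    rows = []
    for c0 in config.c0_values:
        for h0 in config.h0_values:
            for u in config.u_values:
                clean = true_curve(t_grid, c0, h0, u, config)
                noise = rng.normal(0.0, config.noise_sd, size=clean.shape) if config.noise_sd > 0 else 0.0
                ratio = np.clip(clean + noise, 0.0, 1.0)
                for t, r in zip(t_grid, ratio):
                    rows.append((c0, h0, u, t, r))
    frame = pd.DataFrame(rows, columns=list(FEATURE_ORDER) + [TARGET])
    return Dataset(frame)
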