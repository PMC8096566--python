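"""Particle swarm optimization of the LSSVM hyperparameters (γ, σ²).

Standard global-best PSO: velocities are updated with inertia, cognitive and
social terms, positions are clamped to the search box (velocity zeroed at the
boundary), and the best-so-far value is recorded each iteration.  The LSSVM
objective is the validation mean squared error; the search runs on
(log10 γ, log10 σ²) because useful γ values span many decades.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import lssvm
from .dataset import Dataset, NormalizationSpec

logger = logging.getLogger(__name__)

#: objective value substituted when the LSSVM solver fails on a candidate
PENALTY = 1e12

#: default search box: log10 γ ∈ [−2, 8], log10 σ² ∈ [−3, 3]
DEFAULT_BOUNDS: tuple[tuple[float, float], ...] = ((-2.0, 8.0), (-3.0, 3.0))


@dataclass
class PSOConfig:
    swarm_size: int = 80
    iterations: int = 1000
    inertia: float = 0.7298
    cognitive: float = 1.49618
    social: float = 1.49618
    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS
    velocity_clamp_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"invalid bounds ({lo}, {hi})")


@dataclass
class PSOResult:
    best_position: np.ndarray
    best_value: float
    trace: pd.DataFrame  # iteration, best_value, and best position per dim


def optimize(objective: Callable[[np.ndarray], float], config: PSOConfig) -> PSOResult:
    """Minimize ``objective`` over the configured box.

    The trace of best-so-far values is non-increasing, and the whole
    trajectory is a deterministic function of (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    bounds = np.asarray(config.bounds, float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    ndim = len(bounds)
    vmax = config.velocity_clamp_frac * span

    pos = lo + rng.random((config.swarm_size, ndim)) * span
    vel = (rng.random((config.swarm_size, ndim)) - 0.5) * span * 0.1

    values = np.array([float(objective(p)) for p in pos])
    if not np.any(np.isfinite(values)):
        raise RuntimeError("objective unevaluable on bounds")
    pbest = pos.copy()
    pbest_val = values.copy()
    g = int(np.argmin(pbest_val))
    gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])

    rows = []
    for it in range(config.iterations):
        r1 = rng.random((config.swarm_size, ndim))
        r2 = rng.random((config.swarm_size, ndim))
        vel = (
            config.inertia * vel
            + config.cognitive * r1 * (pbest - pos)
            + config.social * r2 * (gbest - pos)
        )
        np.clip(vel, -vmax, vmax, out=vel)
        pos = pos + vel
        below, above = pos < lo, pos > hi
        vel[below | above] = 0.0
        np.clip(pos, lo, hi, out=pos)

        values = np.array([float(objective(p)) for p in pos])
        improved = values < pbest_val
        pbest[improved] = pos[improved]
        pbest_val[improved] = values[improved]
        g = int(np.argmin(pbest_val))
        if pbest_val[g] < gbest_val:
            gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])
        rows.append((it, gbest_val, *gbest))

    trace = pd.DataFrame(
        rows, columns=["iteration", "best_value"] + [f"x{i}" for i in range(ndim)]
    )
    return PSOResult(best_position=gbest, best_value=gbest_val, trace=trace)


def objective_mse(
    candidate: Sequence[float],
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
) -> float:
    """Validation MSE of an LSSVM with hyperparameters (γ, σ²) — natural scale."""
    gamma, sigma2 = float(candidate[0]), float(candidate[1])
    try:
        model = lssvm.fit(X_train, y_train, gamma, lssvm.KernelParams(sigma2))
        pred = model.predict(X_val)
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("LSSVM solve failed for gamma=%g sigma2=%g: %s", gamma, sigma2, exc)
        return PENALTY
    mse = float(np.mean((pred - y_val) ** 2))
    return mse if np.isfinite(mse) else PENALTY


@dataclass
class TuneResult:
    gamma: float
    sigma2: float
    best_mse: float
    trace: pd.DataFrame  # iteration, best_mse, best_gamma, best_sigma2


def tune_lssvm(
    train: Dataset,
    normalizer: NormalizationSpec,
    config: PSOConfig,
    objective_mode: str = "validation",
    val_fraction: float = 0.2,
    val_seed: int = 0,
    normalize_target: bool = False,
) -> TuneResult:
    """PSO search for (γ, σ²) minimizing LSSVM mean squared error.

    ``objective_mode="validation"`` (default) holds out an inner fold of the
    training set, which avoids the degenerate γ → ∞ optimum of a pure
    training-error objective; ``"train"`` scores on the training points
    themselves.
    """
    Xn = normalizer.transform(train.X)
    y = train.y
    if normalize_target:
        y = normalizer.transform_column(y, "ratio")

    if objective_mode == "validation":
        rng = np.random.default_rng(val_seed)
        n = len(y)
        n_val = max(1, int(round(n * val_fraction)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        X_tr, y_tr, X_val, y_val = Xn[tr_idx], y[tr_idx], Xn[val_idx], y[val_idx]
    elif objective_mode == "train":
        X_tr = X_val = Xn
        y_tr = y_val = y
    else:
        raise ValueError(f"unknown objective mode {objective_mode!r}")

    def log_objective(p: np.ndarray) -> float:
        return objective_mse((10.0 ** p[0], 10.0 ** p[1]), X_tr, y_tr, X_val, y_val)

    result = optimize(log_objective, config)
    trace = result.trace.rename(columns={"best_value": "best_mse"})
    trace["best_gamma"] = 10.0 ** trace.pop("x0")
    trace["best_sigma2"] = 10.0 ** trace.pop("x1")
    return TuneResult(
        gamma=10.0 ** result.best_position[0],
        sigma2=10.0 ** result.best_position[1],
        best_mse=result.best_value,
        trace=trace,
    )


def grid_baseline(
    train: Dataset,
    normalizer: NormalizationSpec,
    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS,
    n_per_dim: int = 10,
    val_fraction: float = 0.2,
    val_seed: int = 0,
) -> tuple[float, float, float]:
    """Coarse log-grid search over the same box; PSO should never do worse."""
    Xn = normalizer.transform(train.X)
    y = train.y
    rng = np.random.default_rng(val_seed)
    n = len(y)
    n_val = max(1, int(round(n * val_fraction)))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    best = (np.nan, np.nan, np.inf)
    for lg in np.linspace(*bounds[0], n_per_dim):
        for ls in np.linspace(*bounds[1], n_per_dim):
            mse = objective_mse(
                (10.0 ** lg, 10.0 ** ls), Xn[tr_idx], y[tr_idx], Xn[val_idx], y[val_idx]
            )
            if mse < best[2]:
                best = (10.0 ** lg, 10.0 ** ls, mse)
    return best
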