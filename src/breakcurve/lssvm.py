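"""RBF-kernel least-squares support vector machine regression.

LSSVM replaces the inequality constraints of the classical ε-SVM with
equality constraints and a squared-error loss, so training reduces to one
symmetric linear system.  With kernel matrix K on the training points, the
stationarity conditions of the Lagrangian

    L = ½ wᵀw + ½ γ Σ e_k² − Σ a_k (wᵀφ(x_k) + b + e_k − y_k)

are ∂L/∂w = 0 (w = Σ a_k φ(x_k)), ∂L/∂b = 0 (Σ a_k = 0), ∂L/∂e_k = 0
(a_k = γ e_k) and ∂L/∂a_k = 0 (the model equations).  Eliminating w and e
gives the bordered system

    [ 0   1ᵀ        ] [ b ]   [ 0 ]
    [ 1   K + I/γ   ] [ a ] = [ y ]

solved densely here (a few hundred training points at most).  Predictions
are f(x) = Σ a_k K(x, x_k) + b.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

#: condition-number threshold above which the solver falls back to lstsq
COND_THRESHOLD = 1e12


@dataclass(frozen=True)
class KernelParams:
    """RBF width sigma2 (> 0), on normalized features.

    K(x, x') = exp(−‖x − x'‖² / σ²) — no factor of 2 in the denominator.
    """

    sigma2: float

    def __post_init__(self) -> None:
        if not self.sigma2 > 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")


def kernel_matrix(A: np.ndarray, B: np.ndarray, params: KernelParams) -> np.ndarray:
    """Gram matrix of the RBF kernel between the rows of A and B."""
    A = np.atleast_2d(np.asarray(A, float))
    B = np.atleast_2d(np.asarray(B, float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"feature-count mismatch: {A.shape[1]} vs {B.shape[1]}")
    d2 = cdist(A, B, metric="sqeuclidean")
    return np.exp(-d2 / params.sigma2)


@dataclass
class LSSVMModel:
    """Fitted LSSVM: support values a_k, bias b, and the training set.

    KKT by-products: sum(alphas) ≈ 0, and a_k = γ·e_k where e_k is the
    training residual — both are checked by the test suite rather than
    enforced post hoc.
    """

    alphas: np.ndarray
    bias: float
    gamma: float
    kernel: KernelParams
    training_inputs: np.ndarray
    training_targets: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        """f(x) = Σ a_k K(x, x_k) + b for each row of X."""
        X = np.atleast_2d(np.asarray(X, float))
        K = kernel_matrix(X, self.training_inputs, self.kernel)
        return K @ self.alphas + self.bias

    # --- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "alphas": self.alphas.tolist(),
            "bias": float(self.bias),
            "gamma": float(self.gamma),
            "sigma2": float(self.kernel.sigma2),
            "training_inputs": self.training_inputs.tolist(),
            "training_targets": self.training_targets.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LSSVMModel":
        return cls(
            alphas=np.asarray(d["alphas"], float),
            bias=float(d["bias"]),
            gamma=float(d["gamma"]),
            kernel=KernelParams(float(d["sigma2"])),
            training_inputs=np.asarray(d["training_inputs"], float),
            training_targets=np.asarray(d["training_targets"], float),
        )

    def save(self, path, extra: dict | None = None) -> None:
        payload = self.to_dict()
        if extra:
            payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "LSSVMModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit(X: np.ndarray, y: np.ndarray, gamma: float, params: KernelParams) -> LSSVMModel:
    """Train an LSSVM by a dense direct solve of the KKT system.

    Falls back to least squares (with a logged warning) when the bordered
    matrix is ill-conditioned.
    """
    if not gamma > 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n = X.shape[0]
    if y.shape[0] != n:
        raise ValueError("X and y row counts differ")

    K = kernel_matrix(X, X, params)
    M = np.zeros((n + 1, n + 1))
    M[0, 1:] = 1.0
    M[1:, 0] = 1.0
    M[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate(([0.0], y))

    cond = np.linalg.cond(M)
    if np.isfinite(cond) and cond < COND_THRESHOLD:
        sol = solve(M, rhs, assume_a="sym")
    else:
        logger.warning("KKT system ill-conditioned (cond=%.3g); using least-squares solve", cond)
        sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)

    return LSSVMModel(
        alphas=sol[1:],
        bias=float(sol[0]),
        gamma=float(gamma),
        kernel=params,
        training_inputs=X,
        training_targets=y,
    )
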