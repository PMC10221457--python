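"""Least-squares support vector regression (LS-SVR) baseline.

LS-SVR replaces the epsilon-insensitive loss of classic SVR with a squared
loss and equality constraints, so training reduces to one symmetric linear
system.  With kernel matrix K over the N training inputs, dual coefficients
``a`` and bias ``b`` solve the saddle system

    [ 0   1'          ] [ b ]   [ 0 ]
    [ 1   K + I/gamma ] [ a ] = [ t ]

where ``gamma`` is the regularization constant (larger = less smoothing).
Prediction is y(x) = sum_i a_i k(x, x_i) + b.  Unlike the relevance vector
machine, every training point generically keeps a nonzero coefficient: the
model is dense, which is the contrast the head-to-head comparison exercises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .kernels import MultiKernelSpec, gram_matrix


class NumericallyDegenerateError(RuntimeError):
    """The LS-SVR saddle system could not be solved."""


@dataclass(frozen=True)
class LssvrModel:
    """Fitted LS-SVR: all training inputs with their dual coefficients."""

    support_inputs: np.ndarray
    dual_coefficients: np.ndarray
    bias: float
    reg_gamma: float
    kernel_spec: MultiKernelSpec
    training_summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.dual_coefficients) != len(self.support_inputs):
            raise ValueError("one dual coefficient per support input required")
        if not np.all(np.isfinite(self.dual_coefficients)):
            raise ValueError("dual coefficients must be finite")

    @property
    def n_support_vectors(self) -> int:
        return self.support_inputs.shape[0]


def fit_lssvr(
    X: np.ndarray,
    t: np.ndarray,
    spec: MultiKernelSpec | None = None,
    reg_gamma: float = 100.0,
) -> LssvrModel:
    """Solve the LS-SVR dual system exactly.

    The default ``reg_gamma=100`` and the shared multi-kernel mirror the
    head-to-head comparison configuration; both are overridable.
    """
    spec = spec or MultiKernelSpec()
    if reg_gamma <= 0:
        raise ValueError("reg_gamma must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    t = np.asarray(t, dtype=float).ravel()
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two training samples")
    if len(t) != n:
        raise ValueError("X and t length mismatch")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(t))):
        raise ValueError("inputs must be finite")

    K = gram_matrix(X, X, spec)
    system = np.zeros((n + 1, n + 1))
    system[0, 1:] = 1.0
    system[1:, 0] = 1.0
    system[1:, 1:] = K + np.eye(n) / reg_gamma
    rhs = np.concatenate([[0.0], t])
    try:
        lu = lu_factor(system)
        solution = lu_solve(lu, rhs)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise NumericallyDegenerateError(
            "LS-SVR saddle system is singular; check for duplicate inputs "
            "or lower reg_gamma"
        ) from exc
    if not np.all(np.isfinite(solution)):
        raise NumericallyDegenerateError("LS-SVR solution is not finite")

    residual = float(np.linalg.norm(system @ solution - rhs))
    return LssvrModel(
        support_inputs=X,
        dual_coefficients=solution[1:],
        bias=float(solution[0]),
        reg_gamma=reg_gamma,
        kernel_spec=spec,
        training_summary={"n_train": n, "system_residual": residual},
    )


def predict_lssvr(model: LssvrModel, X_new: np.ndarray) -> np.ndarray:
    """Predictive mean sum_i a_i k(x, x_i) + b at new inputs."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    K = gram_matrix(X_new, model.support_inputs, model.kernel_spec)
    return K @ model.dual_coefficients + model.bias
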