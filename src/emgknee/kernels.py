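"""Base kernels and their fixed-weight convex combination.

The multi-kernel used for knee-angle regression is a weighted sum of a
Gaussian RBF, a polynomial and a sigmoid kernel::

    K_MK(x, z) = w_g exp(-g1 ||x-z||^2)
               + w_p (g2 x.z + c)^d
               + w_s tanh(g3 x.z + c)

with default weights 0.8 / 0.17 / 0.03 and parameters g1 = 0.01,
g2 = g3 = 0.005, c = 0.01, d = 0.02.  The polynomial exponent d is
real-valued, so the base ``g2 x.z + c`` must stay positive; with unit-interval
features and positive g2, c this always holds in normal operation.

The sigmoid kernel (and hence the mixture) is not positive semidefinite in
general; the sparse Bayesian regression built on top uses the kernel purely
as a basis-function generator and does not require PSD kernels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class MultiKernelSpec:
    """Parameters of the three base kernels and their mixture weights."""

    gamma_gaussian: float = 0.01
    gamma_poly: float = 0.005
    gamma_sigmoid: float = 0.005
    c: float = 0.01
    d: float = 0.02
    w_gaussian: float = 0.8
    w_poly: float = 0.17
    w_sigmoid: float = 0.03

    def __post_init__(self) -> None:
        for name in ("gamma_gaussian", "gamma_poly", "gamma_sigmoid"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.c < 0:
            raise ValueError("c must be >= 0")
        weights = (self.w_gaussian, self.w_poly, self.w_sigmoid)
        if any(w < 0 for w in weights):
            raise ValueError("kernel weights must be non-negative")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("kernel weights must sum to 1")

    @classmethod
    def gaussian_only(cls, gamma: float = 0.01) -> "MultiKernelSpec":
        """Single Gaussian RBF kernel (the standard-RVR comparison kernel)."""
        return cls(gamma_gaussian=gamma, w_gaussian=1.0, w_poly=0.0, w_sigmoid=0.0)

    def with_gamma(self, gamma: float) -> "MultiKernelSpec":
        return replace(self, gamma_gaussian=gamma)

    def to_json(self) -> str:
        return json.dumps(
            {
                "gamma_gaussian": self.gamma_gaussian,
                "gamma_poly": self.gamma_poly,
                "gamma_sigmoid": self.gamma_sigmoid,
                "c": self.c,
                "d": self.d,
                "weights": [self.w_gaussian, self.w_poly, self.w_sigmoid],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MultiKernelSpec":
        obj = json.loads(text)
        wg, wp, ws = obj.pop("weights")
        return cls(w_gaussian=wg, w_poly=wp, w_sigmoid=ws, **obj)


def _as_2d(x) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    return arr


def _check_dims(x: np.ndarray, z: np.ndarray) -> None:
    if x.shape[1] != z.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {x.shape[1]} vs {z.shape[1]}"
        )


def k_gaussian(x, z, gamma: float) -> np.ndarray | float:
    """Gaussian RBF kernel exp(-gamma ||x - z||^2)."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    xa, za = _as_2d(x), _as_2d(z)
    _check_dims(xa, za)
    out = np.exp(-gamma * cdist(xa, za, "sqeuclidean"))
    return _maybe_scalar(out, x, z)


def k_polynomial(x, z, gamma: float, c: float, d: float) -> np.ndarray | float:
    """Polynomial kernel (gamma x.z + c)^d with a real-valued exponent d."""
    xa, za = _as_2d(x), _as_2d(z)
    _check_dims(xa, za)
    base = gamma * (xa @ za.T) + c
    if float(d) != int(d) and np.any(base <= 0):
        raise ValueError(
            "polynomial kernel base gamma*x.z + c must be positive "
            "for non-integer degree d"
        )
    out = np.power(base, d)
    return _maybe_scalar(out, x, z)


def k_sigmoid(x, z, gamma: float, c: float) -> np.ndarray | float:
    """Sigmoid kernel tanh(gamma x.z + c)."""
    xa, za = _as_2d(x), _as_2d(z)
    _check_dims(xa, za)
    out = np.tanh(gamma * (xa @ za.T) + c)
    return _maybe_scalar(out, x, z)


def k_multi(x, z, spec: MultiKernelSpec) -> np.ndarray | float:
    """Weighted multi-kernel similarity; a convex combination of the bases."""
    xa, za = _as_2d(x), _as_2d(z)
    _check_dims(xa, za)
    out = np.zeros((xa.shape[0], za.shape[0]))
    # Skip zero-weight terms so e.g. a pure-Gaussian spec never evaluates the
    # polynomial power (whose domain guard is irrelevant then).
    if spec.w_gaussian:
        out += spec.w_gaussian * k_gaussian(xa, za, spec.gamma_gaussian)
    if spec.w_poly:
        out += spec.w_poly * k_polynomial(xa, za, spec.gamma_poly, spec.c, spec.d)
    if spec.w_sigmoid:
        out += spec.w_sigmoid * k_sigmoid(xa, za, spec.gamma_sigmoid, spec.c)
    return _maybe_scalar(out, x, z)


def gram_matrix(X: np.ndarray, Z: np.ndarray, spec: MultiKernelSpec) -> np.ndarray:
    """Kernel matrix with entry (i, j) = k_multi(X[i], Z[j])."""
    Xa, Za = _as_2d(X), _as_2d(Z)
    _check_dims(Xa, Za)
    return np.asarray(k_multi(Xa, Za, spec)).reshape(Xa.shape[0], Za.shape[0])


def _maybe_scalar(out: np.ndarray, x, z):
    if np.asarray(x).ndim == 1 and np.asarray(z).ndim == 1:
        return float(out[0, 0])
    return out
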