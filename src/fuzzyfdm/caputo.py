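"""Caputo L1 memory weights and the mesh ratio of the implicit scheme.

The L1 discretization of the Caputo derivative of order alpha in (0, 1] on a
uniform time grid approximates

    d^alpha u / dt^alpha  ~=  dt^(-alpha) / Gamma(2 - alpha) *
        [ u^{n+1} - u^n + sum_{j=1}^{n} b_j (u^{n+1-j} - u^{n-j}) ]

with weights b_j = (j+1)^(1-alpha) - j^(1-alpha).  The weights satisfy
0 < b_j <= 1, decrease strictly in j (for alpha < 1), and vanish identically
at alpha = 1, where the scheme reduces to the classical backward difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import gamma

import numpy as np

__all__ = ["CaputoWeights", "SchemeParams", "compute_weights", "mesh_ratio"]

#: relative tolerance for mesh commensurability (dt must tile T, dx tile L)
MESH_RTOL = 1e-9


def _check_alpha(alpha: float) -> float:
    alpha = float(alpha)
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"fractional order must satisfy 0 < alpha <= 1, got {alpha}")
    return alpha


@dataclass(frozen=True)
class CaputoWeights:
    """Weights b_1..b_n of the L1 memory term at fractional order alpha."""

    alpha: float
    b: np.ndarray  # shape (n,), b[j-1] = b_j

    def __len__(self) -> int:
        return len(self.b)


@lru_cache(maxsize=256)
def _weights_cached(alpha: float, n: int) -> np.ndarray:
    if alpha == 1.0:
        # (j+1)^0 - j^0 = 0 exactly; short-circuit avoids float noise
        b = np.zeros(n)
    else:
        j = np.arange(1, n + 1, dtype=float)
        b = (j + 1.0) ** (1.0 - alpha) - j ** (1.0 - alpha)
    b.setflags(write=False)
    return b


def compute_weights(alpha: float, n: int) -> CaputoWeights:
    """Caputo L1 weights ``b_j = (j+1)^(1-alpha) - j^(1-alpha)``, j = 1..n.

    Returns an empty weight sequence for ``n = 0`` (the first time step has
    no memory).  Results are cached per ``(alpha, n)`` since every step of a
    march reuses the prefix.
    """
    alpha = _check_alpha(alpha)
    n = int(n)
    if n < 0:
        raise ValueError(f"number of weights must be >= 0, got {n}")
    return CaputoWeights(alpha=alpha, b=_weights_cached(alpha, n))


def mesh_ratio(alpha: float, dt: float, dx: float) -> float:
    """Dimensionless coupling ``tau = Gamma(2-alpha) * dt^alpha / dx^2``.

    This is the factor multiplying the spatial stencil after the scheme is
    normalized by ``dt^alpha * Gamma(2-alpha)``; the same normalization puts
    the factor ``Gamma(2-alpha) * dt^alpha`` on the killing rate.
    """
    alpha = _check_alpha(alpha)
    if dt <= 0 or dx <= 0:
        raise ValueError("time and space steps must be positive")
    return gamma(2.0 - alpha) * dt**alpha / dx**2


def _commensurate(total: float, step: float, what: str) -> int:
    ratio = total / step
    n = round(ratio)
    if n < 1 or abs(ratio - n) > MESH_RTOL * max(ratio, 1.0):
        suggestion = total / max(n, 1)
        raise ValueError(
            f"{what} step {step} does not tile {total} "
            f"(ratio {ratio}); nearest commensurate step is {suggestion}"
        )
    return n


@dataclass(frozen=True)
class SchemeParams:
    """Discretization parameters of one implicit march.

    ``n_steps * dt = t_final`` and ``(n_nodes - 1) * dx = length`` hold to
    rounding tolerance; ``n_nodes`` counts grid nodes including both
    boundaries.
    """

    alpha: float
    dt: float
    dx: float
    n_steps: int
    n_nodes: int

    @property
    def tau(self) -> float:
        return mesh_ratio(self.alpha, self.dt, self.dx)

    @property
    def t_final(self) -> float:
        return self.n_steps * self.dt

    @property
    def length(self) -> float:
        return (self.n_nodes - 1) * self.dx

    @property
    def x(self) -> np.ndarray:
        return np.arange(self.n_nodes) * self.dx

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt

    def weights(self) -> CaputoWeights:
        return compute_weights(self.alpha, self.n_steps)

    @classmethod
    def from_mesh(
        cls, alpha: float, dt: float, dx: float, length: float, t_final: float
    ) -> "SchemeParams":
        """Build scheme parameters, failing fast on non-commensurate meshes."""
        alpha = _check_alpha(alpha)
        if dt <= 0 or dx <= 0:
            raise ValueError("time and space steps must be positive")
        n_steps = _commensurate(t_final, dt, "time")
        n_intervals = _commensurate(length, dx, "space")
        if n_intervals < 2:
            raise ValueError("need at least one interior node (length >= 2*dx)")
        return cls(alpha=alpha, dt=float(dt), dx=float(dx),
                   n_steps=n_steps, n_nodes=n_intervals + 1)
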