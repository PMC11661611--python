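"""Problem descriptions and the defuzzification into crisp branch problems.

The model is a one-dimensional diffusion equation for the tumor-cell
concentration u(x, t) with a Caputo time derivative of order alpha in (0, 1]
and a net cell-killing term:

    d^alpha u / dt^alpha = d^2 u / dx^2 - k(x, t) u,    (x, t) in [0, L] x [0, T]

Uncertainty enters through fuzzy factors: the killing rate is
k = tau1 * s1(x, t) and the initial condition is u(x, 0) = tau2 * s2(x),
with tau1, tau2 fuzzy convex numbers, and the Dirichlet boundary values are
fuzzy-valued samplers.  At a fixed confidence level r the fuzzy problem
decomposes into two decoupled crisp initial-boundary-value problems: the
lower branch uses the lower r-cut endpoints of every fuzzy factor, the upper
branch the upper endpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

from .fuzzy import ParametricFuzzyNumber, _check_r

__all__ = ["ProblemSpec", "CrispProblem", "defuzzify_problem"]

#: relative tolerance for the corner-compatibility warning (IC vs BC at t=0)
CORNER_TOL = 1e-8


@dataclass
class ProblemSpec:
    """A fuzzy time-fractional diffusion problem with a killing term.

    Attributes
    ----------
    length:
        Spatial domain is ``[0, length]``.
    t_final:
        Final time ``T``.
    ic_coefficient:
        Fuzzy factor multiplying the initial-condition shape.
    ic_shape:
        Crisp shape ``s2(x)`` of the initial condition.
    killing_coefficient:
        Fuzzy factor on the killing rate (crisp 1 by default).
    killing_shape:
        Crisp shape ``s1(x, t)`` of the net cell-killing rate, in inverse
        time units.
    bc_left, bc_right:
        Fuzzy-valued Dirichlet samplers: ``(t, r) -> (lower, upper)``.
    """

    length: float
    t_final: float
    ic_coefficient: ParametricFuzzyNumber
    ic_shape: Callable[[float], float]
    bc_left: Callable[[float, float], tuple[float, float]]
    bc_right: Callable[[float, float], tuple[float, float]]
    killing_shape: Callable[[float, float], float] = field(
        default=lambda x, t: 0.0
    )
    killing_coefficient: ParametricFuzzyNumber = field(
        default_factory=lambda: ParametricFuzzyNumber.crisp(1.0)
    )

    def __post_init__(self) -> None:
        if self.length <= 0 or self.t_final <= 0:
            raise ValueError("domain length and final time must be positive")


@dataclass
class CrispProblem:
    """One defuzzified branch: a crisp initial-boundary-value problem."""

    length: float
    t_final: float
    ic: Callable[[float], float]
    killing: Callable[[float, float], float]
    bc_left: Callable[[float], float]
    bc_right: Callable[[float], float]


def _branch(spec: ProblemSpec, r: float, side: int) -> CrispProblem:
    # side 0 -> lower endpoints everywhere, side 1 -> upper endpoints
    tau2 = spec.ic_coefficient.r_cut(r)[side]
    tau1 = spec.killing_coefficient.r_cut(r)[side]
    ic_shape, k_shape = spec.ic_shape, spec.killing_shape
    bcl, bcr = spec.bc_left, spec.bc_right
    return CrispProblem(
        length=spec.length,
        t_final=spec.t_final,
        ic=lambda x: tau2 * ic_shape(x),
        killing=lambda x, t: tau1 * k_shape(x, t),
        bc_left=lambda t: float(bcl(t, r)[side]),
        bc_right=lambda t: float(bcr(t, r)[side]),
    )


def defuzzify_problem(
    spec: ProblemSpec, r: float
) -> tuple[CrispProblem, CrispProblem]:
    """Decompose a fuzzy problem at level ``r`` into (lower, upper) branches.

    Each branch is a crisp problem of the form
    ``d^alpha u/dt^alpha = u_xx - k(x,t) u`` with its own IC and Dirichlet
    BCs, built from the matching r-cut endpoints of the fuzzy factors.

    A warning (not an error) is emitted when the initial condition and the
    boundary samplers disagree at the domain corners ``(0, 0)`` and
    ``(L, 0)`` beyond a small relative tolerance.
    """
    _check_r(r)
    lower = _branch(spec, r, 0)
    upper = _branch(spec, r, 1)
    for name, prob in (("lower", lower), ("upper", upper)):
        for corner, bc in (
            (prob.ic(0.0), prob.bc_left(0.0)),
            (prob.ic(spec.length), prob.bc_right(0.0)),
        ):
            scale = max(abs(corner), abs(bc), 1.0)
            if abs(corner - bc) > CORNER_TOL * scale:
                warnings.warn(
                    f"{name} branch: initial condition and boundary value "
                    f"disagree at a domain corner ({corner} vs {bc})",
                    stacklevel=2,
                )
    return lower, upper
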