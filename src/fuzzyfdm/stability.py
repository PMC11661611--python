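"""Executable von Neumann stability machinery for the implicit scheme.

Substituting a Fourier mode ``eps_i^n = lambda^n e^{i q x_i}`` (phase
``theta = q h``) into the error equation of the implicit scheme yields the
scalar amplification recursion

    lambda^{n+1} = [ (1 - kappa - b_1) lambda^n
                     + sum_{j=1}^{n-1} (b_j - b_{j+1}) lambda^{n-j}
                     + b_n lambda^0 ] / (1 + 4 tau sin^2(theta/2)),

with ``kappa = Gamma(2-alpha) dt^alpha k`` the normalized killing factor
(the first step, whose memory sum is empty, uses
``lambda^1 = (1 - kappa) lambda^0 / (1 + 4 tau sin^2(theta/2))``).  Because
the weights decrease and telescope, the numerator coefficients are
nonnegative and sum to ``1 - kappa`` whenever ``kappa <= 1 - b_1``, giving
``|lambda^n| <= |lambda^0|`` for every mesh ratio — unconditional stability.
This module iterates that recursion, checks the weight inequalities, and
runs perturbation experiments on actual solves, measuring the discrete
error norm ``||eps^n||_2 = sqrt(sum_i h |eps_i^n|^2)`` over interior nodes.

An intentionally minimal explicit marcher (`same spatial stencil, memory and
killing on the right-hand side, no linear solve`) is included as a private
comparator: on coarse meshes with large mesh ratio it diverges where the
implicit scheme does not.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gamma, sin
from typing import Callable, Optional

import numpy as np

from .caputo import SchemeParams, compute_weights
from .fuzzy import _check_r
from .problems import CrispProblem, ProblemSpec, defuzzify_problem
from .solver import solve_branch

__all__ = [
    "AmplificationState",
    "Lemma1Result",
    "PerturbationExperiment",
    "amplification_recursion",
    "lemma1_check",
    "fuzzy_error_norm",
    "perturbation_experiment",
]


@dataclass
class AmplificationState:
    """Result of iterating the amplification recursion for one mode."""

    theta: float
    tau: float
    alpha: float
    killing_factor: float
    lam: np.ndarray  # lambda^0 .. lambda^n (lambda^0 = 1)

    @property
    def magnitudes(self) -> np.ndarray:
        return np.abs(self.lam)

    @property
    def max_amplification(self) -> float:
        return float(np.max(self.magnitudes))


def amplification_recursion(
    theta: float,
    tau: float,
    alpha: float,
    killing_factor: float,
    n_steps: int,
) -> AmplificationState:
    """Iterate the von Neumann recursion from ``lambda^0 = 1``.

    ``killing_factor`` is the normalized killing term
    ``Gamma(2-alpha) dt^alpha k`` (equivalently ``tau dx^2 k``); pass the
    worst case over the time window for a conservative sweep.
    """
    if n_steps < 1:
        raise ValueError("need at least one step")
    if tau <= 0:
        raise ValueError("mesh ratio must be positive")
    b = compute_weights(alpha, n_steps).b
    denom = 1.0 + 4.0 * tau * sin(theta / 2.0) ** 2
    lam = np.empty(n_steps + 1)
    lam[0] = 1.0
    lam[1] = (1.0 - killing_factor) * lam[0] / denom
    for n in range(1, n_steps):
        acc = (1.0 - killing_factor - b[0]) * lam[n]
        # positive-coefficient form of the telescoped memory sum
        for j in range(1, n):
            acc += (b[j - 1] - b[j]) * lam[n - j]
        acc += b[n - 1] * lam[0]
        lam[n + 1] = acc / denom
    return AmplificationState(
        theta=theta, tau=tau, alpha=alpha,
        killing_factor=killing_factor, lam=lam,
    )


@dataclass
class Lemma1Result:
    """Outcome of the weight-inequality suite, with a counterexample slot."""

    alpha: float
    n: int
    passed: bool
    counterexample: Optional[str] = None


def lemma1_check(alpha: float, n: int, atol: float = 1e-12) -> Lemma1Result:
    """Verify the L1 weight inequalities for strictly fractional order.

    Checks 0 < b_j <= 1, strict decrease, and the telescoping identity
    ``sum_{j=1}^{n-1} (b_{j+1} - b_j) = b_n - b_1`` to machine precision.
    Requires ``0 < alpha < 1`` — at ``alpha = 1`` every weight is zero and
    strict positivity fails trivially.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("weight inequalities require 0 < alpha < 1 strictly")
    b = compute_weights(alpha, n).b
    if np.any(b <= 0.0) or np.any(b > 1.0):
        j = int(np.argmax((b <= 0.0) | (b > 1.0)))
        return Lemma1Result(alpha, n, False,
                            f"b_{j+1} = {b[j]} outside (0, 1]")
    if np.any(np.diff(b) >= 0.0):
        j = int(np.argmax(np.diff(b) >= 0.0))
        return Lemma1Result(alpha, n, False,
                            f"b_{j+1} = {b[j]} <= b_{j+2} = {b[j+1]}")
    telescoped = float(np.sum(np.diff(b)))
    if abs(telescoped - (b[-1] - b[0])) > atol:
        return Lemma1Result(
            alpha, n, False,
            f"telescoping defect {telescoped - (b[-1] - b[0])}",
        )
    return Lemma1Result(alpha, n, True)


def fuzzy_error_norm(eps_row: np.ndarray, dx: float) -> float:
    """Discrete L2 norm ``sqrt(sum_i h |eps_i|^2)`` over interior nodes.

    ``eps_row`` covers the full grid including boundary columns (which are
    zero for Dirichlet-matched perturbations and are excluded from the sum).
    """
    interior = np.asarray(eps_row, dtype=float)[1:-1]
    return float(np.sqrt(dx * np.sum(interior**2)))


def _explicit_branch(problem: CrispProblem, scheme: SchemeParams) -> np.ndarray:
    """Minimal explicit comparator: same stencil, no implicit solve.

    Marches ``u^{n+1} = u^n + tau * stencil(u^n) - kappa u^n - memory`` with
    Dirichlet boundaries; conditionally stable only, used to contrast the
    implicit scheme's behaviour on coarse meshes.
    """
    x = scheme.x
    N = scheme.n_steps
    tau = scheme.tau
    kf = gamma(2.0 - scheme.alpha) * scheme.dt**scheme.alpha
    b = scheme.weights().b
    u = np.empty((N + 1, scheme.n_nodes))
    u[0] = [problem.ic(xi) for xi in x]
    x_int = x[1:-1]
    for n in range(N):
        tn = n * scheme.dt
        tnp = (n + 1) * scheme.dt
        killing = kf * np.array([problem.killing(xi, tn) for xi in x_int])
        interior = u[: n + 1, 1:-1]
        stencil = u[n, :-2] - 2.0 * u[n, 1:-1] + u[n, 2:]
        new = (1.0 - killing) * interior[n] + tau * stencil
        if n > 0:
            new = new - b[:n][::-1] @ np.diff(interior, axis=0)
        u[n + 1, 1:-1] = new
        u[n + 1, 0] = problem.bc_left(tnp)
        u[n + 1, -1] = problem.bc_right(tnp)
    return u


@dataclass
class PerturbationExperiment:
    """Base-vs-perturbed runs and the growth of the perturbation norm."""

    r: float
    alpha: float
    tau: float
    seed: Optional[int]
    norms_lower: np.ndarray  # ||eps^n|| for n = 0..N, lower branch
    norms_upper: np.ndarray
    max_ratio: float  # max over branches, n >= 1 of ||eps^n|| / ||eps^0||


def perturbation_experiment(
    spec: ProblemSpec,
    scheme: SchemeParams,
    r: float,
    perturbation: Optional[Callable[[float], float]] = None,
    seed: Optional[int] = None,
    amplitude: float = 1e-3,
    method: str = "implicit",
) -> PerturbationExperiment:
    """Solve with IC and IC + delta; track the error-norm sequence.

    ``perturbation`` is a sampler ``delta(x)``; when omitted, a seeded
    uniform perturbation of the given amplitude is drawn per interior node
    (all Fourier modes populated).  The perturbation vanishes at the
    boundaries so both runs share their Dirichlet data and the error
    satisfies the homogeneous-boundary error equation.  ``method`` selects
    the implicit scheme (default) or the explicit comparator.
    """
    _check_r(r)
    march = {"implicit": solve_branch, "explicit": _explicit_branch}[method]
    x = scheme.x
    if perturbation is not None:
        delta = np.array([perturbation(xi) for xi in x])
    else:
        rng = np.random.default_rng(seed)
        delta = amplitude * rng.uniform(-1.0, 1.0, size=len(x))
    delta[0] = 0.0
    delta[-1] = 0.0

    def perturbed(problem: CrispProblem) -> CrispProblem:
        base_ic = problem.ic
        return CrispProblem(
            length=problem.length,
            t_final=problem.t_final,
            ic=lambda xi: base_ic(xi) + float(np.interp(xi, x, delta)),
            killing=problem.killing,
            bc_left=problem.bc_left,
            bc_right=problem.bc_right,
        )

    norms = []
    for problem in defuzzify_problem(spec, r):
        eps = march(perturbed(problem), scheme) - march(problem, scheme)
        norms.append(
            np.array([fuzzy_error_norm(row, scheme.dx) for row in eps])
        )
    norms_lower, norms_upper = norms
    ratios = [
        float(np.max(seq[1:]) / seq[0])
        for seq in norms
        if seq[0] > 0.0
    ]
    return PerturbationExperiment(
        r=float(r),
        alpha=scheme.alpha,
        tau=scheme.tau,
        seed=seed,
        norms_lower=norms_lower,
        norms_upper=norms_upper,
        max_ratio=max(ratios, default=0.0),
    )
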