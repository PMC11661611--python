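import dataclasses

import numpy as np
import pytest

from fuzzyfdm import SchemeParams, build_benchmark_problem
from fuzzyfdm.problems import CrispProblem


@pytest.fixture
def benchmark_problem():
    """Factory: (alpha, **overrides) -> (fuzzy spec, scheme) for the
    reference benchmark (k(t)=t^2, IC s(r) e^{-x}, L=5, T=0.05)."""

    def make(alpha, **kwargs):
        return build_benchmark_problem(alpha, **kwargs)

    return make


@pytest.fixture
def constant_problem():
    """Pure-diffusion crisp problem with constant IC and matching BCs."""

    def make(value=2.0, length=4.0, t_final=0.1):
        return CrispProblem(
            length=length,
            t_final=t_final,
            ic=lambda x: value,
            killing=lambda x, t: 0.0,
            bc_left=lambda t: value,
            bc_right=lambda t: value,
        )

    return make


@pytest.fixture
def scaled_spec():
    """Helper scaling IC and BCs of a fuzzy spec by a crisp factor."""

    def scale(spec, c):
        bcl, bcr, ic = spec.bc_left, spec.bc_right, spec.ic_shape
        return dataclasses.replace(
            spec,
            ic_shape=lambda x: c * ic(x),
            bc_left=lambda t, r: tuple(c * v for v in bcl(t, r)),
            bc_right=lambda t, r: tuple(c * v for v in bcr(t, r)),
        )

    return scale


def literal_rhs(history, b, killing_factor, tau, bc_next):
    """Independent term-by-term evaluation of the implicit-update RHS:
    (1 - kappa) u^n - sum_{j=1}^{n} b_j (u^{n+1-j} - u^{n-j}), plus the
    Dirichlet contributions.  Kept deliberately naive (scalar loops)."""
    history = np.asarray(history, float)
    n = history.shape[0] - 1
    m = history.shape[1] - 2
    kf = np.broadcast_to(np.asarray(killing_factor, float), (m,))
    out = np.empty(m)
    for col in range(m):
        i = col + 1
        acc = (1.0 - kf[col]) * history[n, i]
        for j in range(1, n + 1):
            acc -= b[j - 1] * (history[n + 1 - j, i] - history[n - j, i])
        out[col] = acc
    out[0] += tau * bc_next[0]
    out[-1] += tau * bc_next[1]
    return out


def scheme_residual(u, problem, scheme):
    """Max residual of the literal implicit relation over all levels:
    each computed row, substituted back, must satisfy the update it was
    solved from."""
    from fuzzyfdm import compute_weights
    from math import gamma

    tau = scheme.tau
    kf = gamma(2.0 - scheme.alpha) * scheme.dt**scheme.alpha
    b = compute_weights(scheme.alpha, scheme.n_steps).b
    x = scheme.x
    worst = 0.0
    for n in range(scheme.n_steps):
        tn = n * scheme.dt
        killing = kf * np.array([problem.killing(xi, tn) for xi in x[1:-1]])
        # boundary terms appear inside the stencil below, so none here
        rhs = literal_rhs(u[: n + 1], b, killing, tau, (0.0, 0.0))
        lhs = (
            -tau * u[n + 1, :-2]
            + (1.0 + 2.0 * tau) * u[n + 1, 1:-1]
            - tau * u[n + 1, 2:]
        )
        worst = max(worst, float(np.max(np.abs(lhs - rhs))))
    return worst


def backward_euler_branch(problem, scheme):
    """Independent classical solver: backward Euler in time (no memory),
    central differences in space, lagged killing term, dense linear solve."""
    assert scheme.alpha == 1.0
    x = scheme.x
    m = scheme.n_nodes - 2
    dt, dx = scheme.dt, scheme.dx
    lam = dt / dx**2
    A = (
        np.diag(np.full(m, 1.0 + 2.0 * lam))
        + np.diag(np.full(m - 1, -lam), 1)
        + np.diag(np.full(m - 1, -lam), -1)
    )
    u = np.empty((scheme.n_steps + 1, scheme.n_nodes))
    u[0] = [problem.ic(xi) for xi in x]
    for n in range(scheme.n_steps):
        tn, tnp = n * dt, (n + 1) * dt
        k = np.array([problem.killing(xi, tn) for xi in x[1:-1]])
        rhs = (1.0 - dt * k) * u[n, 1:-1]
        u[n + 1, 0] = problem.bc_left(tnp)
        u[n + 1, -1] = problem.bc_right(tnp)
        rhs[0] += lam * u[n + 1, 0]
        rhs[-1] += lam * u[n + 1, -1]
        u[n + 1, 1:-1] = np.linalg.solve(A, rhs)
    return u
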