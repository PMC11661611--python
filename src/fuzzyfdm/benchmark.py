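"""The time-dependent-killing benchmark problem and its error report.

The benchmark instance is

    d^alpha u / dt^alpha = u_xx - t^2 u,   u(x, 0) = s(r) e^{k x},

with the triangular initial-condition coefficient s = (0.75, 1.0, 1.25),
i.e. r-cut [0.75 + 0.25 r, 1.25 - 0.25 r].  The companion analytical
solution (for the diffusion-dominated regime probed here, where the killing
correction is below the reported error scale) is

    u(x, t) = s(r) e^{k x} E_alpha(k^2 t^alpha),

with E_alpha the one-parameter Mittag-Leffler function; its three-term
truncation

    s(r) e^{k x} + e^{k x} k^2 t^alpha / Gamma(1+alpha)
                 + t^{2 alpha} e^{k x} k^4 / Gamma(1+2 alpha)

is also available (``form="truncated"``).  The published reference table for
this benchmark reports values at x = 4, t = 0.05 on a dt = 0.01, dx = 0.5
mesh for alpha in {0.2, 0.4, 0.6, 0.8, 1} and r in {0, 0.3, 0.7}; the
reference's implied exact values match the Mittag-Leffler form to ~1e-8,
which is why that form is the default oracle here.

The exponent k of the initial profile is not stated by the reference and is
recovered by :func:`calibrate_ic_exponent` (the result is -1).  The domain
length (L = 5, so x = 4 is an interior node of the dx = 0.5 grid) and
exact-solution Dirichlet boundaries are this package's manufactured-
benchmark conventions; both are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import exp, gamma
from typing import Sequence

import numpy as np
import pandas as pd

from .caputo import SchemeParams, _check_alpha
from .fuzzy import TriangularFuzzyNumber, _check_r
from .problems import ProblemSpec
from .solver import solve_fuzzy

__all__ = [
    "S_TILDE",
    "BenchmarkSpec",
    "ErrorReport",
    "TABLE1_REFERENCE",
    "mittag_leffler",
    "exact_solution",
    "absolute_error",
    "build_benchmark_problem",
    "calibrate_ic_exponent",
    "table1_report",
]

logger = logging.getLogger(__name__)

#: triangular initial-condition coefficient of the benchmark
S_TILDE = TriangularFuzzyNumber(0.75, 1.0, 1.25)

#: published reference values at (x=4, t=0.05):
#: (r, alpha) -> (lower value, lower abs error, upper value, upper abs error)
TABLE1_REFERENCE: dict[tuple[float, float], tuple[float, float, float, float]] = {
    (0.0, 0.2): (0.02070978, 1.11503e-2, 0.03451629, 1.85838e-2),
    (0.0, 0.4): (0.01806187, 2.13199e-3, 0.03010310, 3.55332e-3),
    (0.0, 0.6): (0.01592767, 7.40335e-4, 0.02654611, 1.23389e-3),
    (0.0, 0.8): (0.01487763, 2.84872e-4, 0.02479604, 4.74786e-4),
    (0.0, 1.0): (0.01437086, 7.01618e-5, 0.02395140, 1.16936e-4),
    (0.3, 0.2): (0.02347108, 1.15750e-2, 0.03244532, 1.74688e-2),
    (0.3, 0.4): (0.01986805, 2.34519e-3, 0.02829690, 3.34012e-3),
    (0.3, 0.6): (0.01752043, 8.14369e-4, 0.02495335, 1.15986e-3),
    (0.3, 0.8): (0.01636539, 3.13359e-4, 0.02330828, 4.46299e-4),
    (0.3, 1.0): (0.01580795, 7.71780e-5, 0.02251435, 1.09920e-4),
    (0.7, 0.2): (0.02554206, 1.37520e-2, 0.02968401, 1.59821e-2),
    (0.7, 0.4): (0.02227630, 2.62946e-3, 0.02588868, 3.05585e-3),
    (0.7, 0.6): (0.019644127, 9.13080e-4, 0.02282966, 1.06115e-3),
    (0.7, 0.8): (0.01834907, 3.51342e-4, 0.02132460, 4.08316e-4),
    (0.7, 1.0): (0.01772406, 8.65329e-5, 0.02059824, 1.00565e-4),
}

DEFAULT_ALPHAS: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)
DEFAULT_RS: tuple[float, ...] = (0.0, 0.3, 0.7)


@dataclass(frozen=True)
class BenchmarkSpec:
    """Fixed parameters of the reference benchmark run."""

    k_exp: float = -1.0
    s_tilde: TriangularFuzzyNumber = field(default_factory=lambda: S_TILDE)
    length: float = 5.0
    t_final: float = 0.05
    dt: float = 0.01
    dx: float = 0.5
    report_x: float = 4.0
    report_t: float = 0.05
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    rs: tuple[float, ...] = DEFAULT_RS


def mittag_leffler(alpha: float, z: float, rtol: float = 1e-16,
                   max_terms: int = 400) -> float:
    """One-parameter Mittag-Leffler function E_alpha(z) by its power series.

    Intended for the moderate arguments of this benchmark (|z| of order 1),
    where the series converges in a few dozen terms; E_1(z) = exp(z).
    """
    if alpha <= 0:
        raise ValueError("Mittag-Leffler order must be positive")
    acc = 0.0
    term = 1.0  # z^0 / Gamma(1)
    for k in range(max_terms):
        acc += term
        term = z ** (k + 1) / gamma(1.0 + alpha * (k + 1))
        if abs(term) <= rtol * max(abs(acc), 1.0) and k > 2:
            return acc
    raise ArithmeticError(
        f"Mittag-Leffler series did not converge (alpha={alpha}, z={z})"
    )


def exact_solution(
    x: float,
    t: float,
    alpha: float,
    r: float,
    branch: str,
    k_exp: float = -1.0,
    form: str = "mittag-leffler",
    s_tilde: TriangularFuzzyNumber = S_TILDE,
) -> float:
    """Branch endpoint of the benchmark's analytical solution.

    ``form="mittag-leffler"`` (default) evaluates
    ``s(r) e^{k x} E_alpha(k^2 t^alpha)`` — the closed form the reference
    values are consistent with.  ``form="truncated"`` evaluates the
    three-term series exactly as the reference prints it, with the fuzzy
    coefficient on the first term only.
    """
    _check_alpha(alpha)
    if t < 0:
        raise ValueError("time must be nonnegative")
    s = s_tilde.endpoint(branch, r)
    e = exp(k_exp * x)
    if form == "mittag-leffler":
        return s * e * mittag_leffler(alpha, k_exp**2 * t**alpha)
    if form == "truncated":
        return (
            s * e
            + e * k_exp**2 * t**alpha / gamma(1.0 + alpha)
            + t ** (2.0 * alpha) / gamma(1.0 + 2.0 * alpha) * e * k_exp**4
        )
    raise ValueError(f"unknown exact-solution form {form!r}")


def absolute_error(numerical: float, exact: float) -> float:
    """Absolute error ``|exact - numerical|`` (symmetric, nonnegative)."""
    return abs(exact - numerical)


def build_benchmark_problem(
    alpha: float,
    *,
    k_exp: float = -1.0,
    length: float = 5.0,
    t_final: float = 0.05,
    dt: float = 0.01,
    dx: float = 0.5,
    s_tilde: TriangularFuzzyNumber = S_TILDE,
    form: str = "mittag-leffler",
) -> tuple[ProblemSpec, SchemeParams]:
    """Benchmark instance at one fractional order.

    IC is ``s(r) e^{k x}``, the killing rate is ``t^2``, and the Dirichlet
    boundaries are sampled per branch from :func:`exact_solution` at x = 0
    and x = L (the usual manufactured-benchmark convention).  The fuzzy
    spec covers every r; only the boundary samplers depend on alpha.
    """
    _check_alpha(alpha)

    def bc_at(x0: float):
        def sampler(t: float, r: float) -> tuple[float, float]:
            return (
                exact_solution(x0, t, alpha, r, "lower", k_exp, form, s_tilde),
                exact_solution(x0, t, alpha, r, "upper", k_exp, form, s_tilde),
            )

        return sampler

    spec = ProblemSpec(
        length=length,
        t_final=t_final,
        ic_coefficient=s_tilde,
        ic_shape=lambda x: exp(k_exp * x),
        killing_shape=lambda x, t: t * t,
        bc_left=bc_at(0.0),
        bc_right=bc_at(length),
    )
    scheme = SchemeParams.from_mesh(alpha, dt, dx, length, t_final)
    return spec, scheme


def calibrate_ic_exponent(
    candidates: Sequence[int] = (-3, -2, -1, 1, 2, 3),
    tol: float = 1e-3,
    form: str = "mittag-leffler",
) -> int:
    """Recover the unstated exponent k of the initial profile ``e^{k x}``.

    Scans small integer candidates and keeps the one whose analytical value
    at the report point (x=4, t=0.05, alpha=1, r=0, lower branch) matches
    the reference table's numerical-plus-error to within ``tol``.  The
    decision trace is logged at INFO level; no match, or more than one, is a
    configuration error.
    """
    lo_val, lo_err, _, _ = TABLE1_REFERENCE[(0.0, 1.0)]
    target = lo_val + lo_err
    matches: list[int] = []
    for k in candidates:
        value = exact_solution(4.0, 0.05, 1.0, 0.0, "lower", float(k), form)
        dev = abs(value - target)
        verdict = "accept" if dev <= tol else "reject"
        logger.info(
            "calibrate_ic_exponent: k=%+d -> exact=%.8g, target=%.8g, "
            "|dev|=%.3g: %s", k, value, target, dev, verdict,
        )
        if dev <= tol:
            matches.append(k)
    if len(matches) != 1:
        raise RuntimeError(
            f"initial-condition exponent calibration found {matches or 'no'} "
            f"matches among {tuple(candidates)} at tolerance {tol}"
        )
    logger.info("calibrate_ic_exponent: selected k=%+d", matches[0])
    return matches[0]


@dataclass
class ErrorReport:
    """Numerical vs analytical values with absolute errors.

    ``table`` has one row per (r, alpha, branch) with columns
    ``r, alpha, branch, numerical, exact, abs_error``.
    """

    table: pd.DataFrame
    spec: BenchmarkSpec = field(default_factory=BenchmarkSpec)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.17g")

    def cell(self, r: float, alpha: float, branch: str) -> pd.Series:
        t = self.table
        row = t[(t.r == r) & (t.alpha == alpha) & (t.branch == branch)]
        if len(row) != 1:
            raise KeyError(f"no unique report cell for {(r, alpha, branch)}")
        return row.iloc[0]

    def __str__(self) -> str:
        return self.table.to_string(
            index=False,
            formatters={
                "numerical": "{:.8f}".format,
                "exact": "{:.8f}".format,
                "abs_error": "{:.5e}".format,
            },
        )


def table1_report(
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    rs: Sequence[float] = DEFAULT_RS,
    *,
    k_exp: float = -1.0,
    length: float = 5.0,
    t_final: float = 0.05,
    dt: float = 0.01,
    dx: float = 0.5,
    report_x: float = 4.0,
    report_t: float = 0.05,
    s_tilde: TriangularFuzzyNumber = S_TILDE,
    form: str = "mittag-leffler",
) -> ErrorReport:
    """Reproduce the benchmark error table at the report point.

    Runs :func:`solve_fuzzy` for every (alpha, r) pair, evaluates the
    analytical solution and the absolute error at ``(report_x, report_t)``,
    and returns all lower/upper cells as an :class:`ErrorReport`.
    """
    rows = []
    for alpha in alphas:
        spec, scheme = build_benchmark_problem(
            alpha, k_exp=k_exp, length=length, t_final=t_final,
            dt=dt, dx=dx, s_tilde=s_tilde, form=form,
        )
        for r in rs:
            _check_r(r)
            grid = solve_fuzzy(spec, r, scheme)
            lo_num, up_num = grid.at(report_x, report_t)
            for branch, numerical in (("lower", lo_num), ("upper", up_num)):
                exact = exact_solution(
                    report_x, report_t, alpha, r, branch, k_exp, form, s_tilde
                )
                rows.append(
                    {
                        "r": r,
                        "alpha": alpha,
                        "branch": branch,
                        "numerical": numerical,
                        "exact": exact,
                        "abs_error": absolute_error(numerical, exact),
                    }
                )
    table = pd.DataFrame(rows)
    bench = BenchmarkSpec(
        k_exp=k_exp, s_tilde=s_tilde, length=length, t_final=t_final,
        dt=dt, dx=dx, report_x=report_x, report_t=report_t,
        alphas=tuple(alphas), rs=tuple(rs),
    )
    return ErrorReport(table=table, spec=bench)
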