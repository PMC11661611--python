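"""Fuzzy numbers in single-parametric (r-cut) form.

A fuzzy quantity is carried through its r-cut endpoints only: at confidence
level ``r`` in [0, 1] it is the interval ``[lower(r), upper(r)]``.  The
endpoint curves of a well-formed fuzzy number are nested — ``lower`` is
nondecreasing, ``upper`` nonincreasing, and the two meet at ``r = 1`` for
numbers whose core is a single point (triangular numbers).

Only what the lower/upper branch decomposition of the model needs is
implemented here; there is no general fuzzy arithmetic.
"""

from __future__ import annotations

from typing import Callable

__all__ = ["ParametricFuzzyNumber", "TriangularFuzzyNumber", "r_cut"]


def _check_r(r: float) -> float:
    r = float(r)
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r-level must lie in [0, 1], got {r}")
    return r


class ParametricFuzzyNumber:
    """A fuzzy number represented by its r-cut endpoint functions.

    Parameters
    ----------
    lower, upper:
        Callables mapping ``r`` in [0, 1] to the interval endpoints.
        ``lower(r) <= upper(r)`` is expected for every ``r``; the class does
        not prove it for arbitrary callables, but :meth:`r_cut` checks it at
        every evaluation.
    """

    def __init__(
        self,
        lower: Callable[[float], float],
        upper: Callable[[float], float],
    ) -> None:
        self._lower = lower
        self._upper = upper

    def lower(self, r: float) -> float:
        """Lower r-cut endpoint."""
        return float(self._lower(_check_r(r)))

    def upper(self, r: float) -> float:
        """Upper r-cut endpoint."""
        return float(self._upper(_check_r(r)))

    def r_cut(self, r: float) -> tuple[float, float]:
        """Interval ``[lower(r), upper(r)]`` at confidence level ``r``."""
        lo, up = self.lower(r), self.upper(r)
        if not (lo <= up):
            raise ValueError(
                f"invalid fuzzy number: lower({r}) = {lo} > upper({r}) = {up}"
            )
        return lo, up

    def endpoint(self, branch: str, r: float) -> float:
        """Endpoint selected by branch name (``'lower'`` or ``'upper'``)."""
        if branch == "lower":
            return self.lower(r)
        if branch == "upper":
            return self.upper(r)
        raise ValueError(f"branch must be 'lower' or 'upper', got {branch!r}")

    def is_crisp(self, r_samples: int = 11) -> bool:
        """True when lower and upper coincide on an evenly spaced r grid."""
        return all(
            self.lower(i / (r_samples - 1)) == self.upper(i / (r_samples - 1))
            for i in range(r_samples)
        )

    @classmethod
    def crisp(cls, value: float) -> "ParametricFuzzyNumber":
        """Degenerate fuzzy number equal to ``value`` at every r."""
        v = float(value)
        return cls(lambda r: v, lambda r: v)


class TriangularFuzzyNumber(ParametricFuzzyNumber):
    """Triangular fuzzy number ``(left, peak, right)``.

    Its r-cut is linear in r::

        [left + (peak - left) * r,  right - (right - peak) * r]

    so at ``r = 0`` the cut is the support ``[left, right]`` and at ``r = 1``
    it collapses to the peak.
    """

    def __init__(self, left: float, peak: float, right: float) -> None:
        left, peak, right = float(left), float(peak), float(right)
        if not left <= peak <= right:
            raise ValueError(
                f"need left <= peak <= right, got ({left}, {peak}, {right})"
            )
        self.left, self.peak, self.right = left, peak, right
        super().__init__(
            lambda r: left + (peak - left) * r,
            lambda r: right - (right - peak) * r,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TriangularFuzzyNumber({self.left}, {self.peak}, {self.right})"

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.left, self.peak, self.right)


def r_cut(fz: ParametricFuzzyNumber, r: float) -> tuple[float, float]:
    """Interval endpoints of ``fz`` at confidence level ``r``.

    Free-function form of :meth:`ParametricFuzzyNumber.r_cut`.
    """
    return fz.r_cut(r)
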