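"""Structured run configuration (YAML) with benchmark defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import yaml

from .benchmark import DEFAULT_ALPHAS, DEFAULT_RS, build_benchmark_problem
from .caputo import SchemeParams, _check_alpha
from .fuzzy import TriangularFuzzyNumber, _check_r
from .problems import ProblemSpec

__all__ = ["RunConfig", "parse_config", "serialize_config"]

_KILLING_SHAPES = ("t^2", "zero")


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of a run; defaults reproduce the benchmark.

    ``ic_coefficient`` is the triangular fuzzy factor as ``(left, peak,
    right)``; ``killing`` names the killing-rate shape (``"t^2"`` or
    ``"zero"``); ``exact_form`` selects the analytical oracle used for
    boundary sampling and error reporting.
    """

    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    rs: tuple[float, ...] = DEFAULT_RS
    dt: float = 0.01
    dx: float = 0.5
    t_final: float = 0.05
    length: float = 5.0
    k_exp: float = -1.0
    ic_coefficient: tuple[float, float, float] = (0.75, 1.0, 1.25)
    killing: str = "t^2"
    exact_form: str = "mittag-leffler"
    report_x: float = 4.0
    report_t: float = 0.05
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for a in self.alphas:
            _check_alpha(a)
        for r in self.rs:
            _check_r(r)
        if self.dt <= 0 or self.dx <= 0 or self.t_final <= 0 or self.length <= 0:
            raise ValueError("mesh sizes, final time and length must be positive")
        if self.killing not in _KILLING_SHAPES:
            raise ValueError(
                f"killing shape must be one of {_KILLING_SHAPES}, got {self.killing!r}"
            )
        TriangularFuzzyNumber(*self.ic_coefficient)  # validates ordering

    def s_tilde(self) -> TriangularFuzzyNumber:
        return TriangularFuzzyNumber(*self.ic_coefficient)

    def problem(self, alpha: float) -> tuple[ProblemSpec, SchemeParams]:
        """Materialize the configured problem at one fractional order."""
        spec, scheme = build_benchmark_problem(
            alpha,
            k_exp=self.k_exp,
            length=self.length,
            t_final=self.t_final,
            dt=self.dt,
            dx=self.dx,
            s_tilde=self.s_tilde(),
            form=self.exact_form,
        )
        if self.killing == "zero":
            spec = dataclasses.replace(spec, killing_shape=lambda x, t: 0.0)
        return spec, scheme


def _coerce(name: str, value):
    if name in ("alphas", "rs"):
        return tuple(float(v) for v in value)
    if name == "ic_coefficient":
        triple = tuple(float(v) for v in value)
        if len(triple) != 3:
            raise ValueError("ic_coefficient must be [left, peak, right]")
        return triple
    if name in ("killing", "exact_form", "log_level"):
        return str(value)
    return float(value)


def parse_config(
    path: Optional[Union[str, Path]] = None, **overrides
) -> RunConfig:
    """Load a YAML config (all keys optional) and apply keyword overrides.

    Unknown keys are rejected with a descriptive error; an empty or missing
    file yields the benchmark defaults.
    """
    known = {f.name for f in dataclasses.fields(RunConfig)}
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(raw)
    data.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**{k: _coerce(k, v) for k, v in data.items()})
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc


def serialize_config(cfg: RunConfig) -> str:
    """YAML form of a config; round-trips losslessly through parse."""
    payload = dataclasses.asdict(cfg)
    payload["alphas"] = list(cfg.alphas)
    payload["rs"] = list(cfg.rs)
    payload["ic_coefficient"] = list(cfg.ic_coefficient)
    return yaml.safe_dump(payload, sort_keys=True)
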