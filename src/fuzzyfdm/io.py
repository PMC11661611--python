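"""Tabular and JSON export of fuzzy solution grids.

CSV is long-format with header ``x,t,r,alpha,lower,upper`` and deterministic
row order (t-major, then x).  Floats are written with shortest-round-trip
precision (17 significant digits), so a reread grid equals the original
bit-for-bit.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Union

import numpy as np

from .solver import FuzzySolutionGrid

__all__ = ["write_solution_csv", "read_solution_csv", "write_json_bundle"]

_HEADER = ["x", "t", "r", "alpha", "lower", "upper"]


def write_solution_csv(grid: FuzzySolutionGrid, path: Union[str, Path]) -> None:
    """Write a solution grid as long-format CSV (t-major row order)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for n, t in enumerate(grid.t):
            for i, x in enumerate(grid.x):
                writer.writerow(
                    [
                        repr(float(x)),
                        repr(float(t)),
                        repr(float(grid.r)),
                        repr(float(grid.alpha)),
                        repr(float(grid.lower[n, i])),
                        repr(float(grid.upper[n, i])),
                    ]
                )


def read_solution_csv(path: Union[str, Path]) -> FuzzySolutionGrid:
    """Rebuild a solution grid from :func:`write_solution_csv` output."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != _HEADER:
            raise ValueError(f"unexpected CSV header {header}")
        rows = [[float(v) for v in row] for row in reader]
    if not rows:
        raise ValueError("empty solution CSV")
    data = np.asarray(rows)
    x = np.unique(data[:, 0])
    t = np.unique(data[:, 1])
    r, alpha = data[0, 2], data[0, 3]
    lower = data[:, 4].reshape(len(t), len(x))
    upper = data[:, 5].reshape(len(t), len(x))
    from .caputo import mesh_ratio

    dt = t[1] - t[0] if len(t) > 1 else 1.0
    dx = x[1] - x[0] if len(x) > 1 else 1.0
    return FuzzySolutionGrid(
        x=x, t=t, lower=lower, upper=upper, r=r, alpha=alpha,
        tau=mesh_ratio(alpha, dt, dx),
    )


def write_json_bundle(
    grid: FuzzySolutionGrid, path: Union[str, Path], **metadata
) -> None:
    """Self-describing JSON bundle: metadata plus the full arrays."""
    payload = {
        "r": grid.r,
        "alpha": grid.alpha,
        "tau": grid.tau,
        "envelope_ok": grid.envelope_ok,
        "x": grid.x.tolist(),
        "t": grid.t.tolist(),
        "lower": grid.lower.tolist(),
        "upper": grid.upper.tolist(),
        **metadata,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
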