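"""Exercise the von Neumann stability machinery.

Three checks: (1) the amplification recursion of the implicit scheme over a
grid of Fourier phases, mesh ratios and fractional orders; (2) the weight
inequalities behind the stability proof; (3) a perturbation experiment on a
deliberately coarse mesh (tau >> 1) where an explicit marcher blows up and
the implicit scheme does not.
"""

import dataclasses

import numpy as np

from fuzzyfdm import (
    SchemeParams,
    amplification_recursion,
    build_benchmark_problem,
    lemma1_check,
    perturbation_experiment,
)

worst = 0.0
for tau in (0.01, 0.354, 1.0, 100.0):
    for alpha in (0.2, 0.5, 0.8, 1.0):
        for theta in np.linspace(np.pi / 50, np.pi, 50):
            state = amplification_recursion(theta, tau, alpha, 0.0, 100)
            worst = max(worst, state.max_amplification)
print(f"max |lambda^n/lambda^0| over the sweep: {worst:.12f}  (<= 1: stable)")

result = lemma1_check(0.35, 1000)
print(f"weight inequalities at alpha=0.35, n=1000: passed={result.passed}")

alpha = 0.5
spec, _ = build_benchmark_problem(alpha)
spec = dataclasses.replace(spec, t_final=1.0)
coarse = SchemeParams.from_mesh(alpha, 0.5, 0.1, 5.0, 1.0)
implicit = perturbation_experiment(spec, coarse, 0.3, seed=7)
explicit = perturbation_experiment(spec, coarse, 0.3, seed=7,
                                   method="explicit")
print(f"coarse mesh (tau = {coarse.tau:.1f}):")
print(f"  implicit max ||eps^n||/||eps^0|| = {implicit.max_ratio:.6f}")
print(f"  explicit max ||eps^n||/||eps^0|| = {explicit.max_ratio:.3e}")
print(
    "\nThe implicit scheme damps the seeded initial-condition perturbation "
    "at every\nmesh ratio; the explicit comparator amplifies it by orders "
    "of magnitude."
)
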