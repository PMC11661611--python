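"""March one fuzzy solve and inspect the uncertainty envelope.

At each confidence level r the fuzzy solution is the interval
[lower(x, t; r), upper(x, t; r)]; cuts at higher r nest inside cuts at
lower r and collapse to a single trajectory at r = 1 (the triangular
core).  This script solves the benchmark at alpha = 0.6 for a ladder of r
values and prints the envelope at the report point.
"""

from fuzzyfdm import build_benchmark_problem, solve_fuzzy

alpha = 0.6
spec, scheme = build_benchmark_problem(alpha)

print(f"alpha = {alpha}, mesh ratio tau = {scheme.tau:.4f}")
print(f"{'r':>4} {'lower':>12} {'upper':>12} {'width':>12}")
for r in (0.0, 0.25, 0.5, 0.75, 1.0):
    grid = solve_fuzzy(spec, r, scheme)
    lo, up = grid.at(4.0, 0.05)
    print(f"{r:>4} {lo:>12.8f} {up:>12.8f} {up - lo:>12.8f}")

print(
    "\nThe interval narrows as r rises and closes at r = 1: higher "
    "confidence in the\ninitial tumor burden translates directly into a "
    "tighter concentration forecast."
)
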