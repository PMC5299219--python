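"""Continuous grey wolf search on the sphere benchmark.

Maximizes -sum(x^2) over [-1, 1]^10 (optimum 0 at the origin) with 8 wolves
for 500 iterations.  The printed best fitness should be within ~1e-2 of 0,
and the best-so-far curve is monotone non-decreasing by construction.
"""

import numpy as np

from wolfsel import gwo_maximize

result = gwo_maximize(lambda x: -float(np.sum(x ** 2)), dim=10, pop_size=8,
                      iterations=500, domain=(-1.0, 1.0), seed=0)

print(f"best fitness: {result.best_fitness:.3e} (0 is the optimum)")
print(f"best position norm: {np.linalg.norm(result.best_position):.3e}")
print("monotone best-so-far curve:", bool(np.all(np.diff(result.history) >= 0)))
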