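"""Independent brute-force oracles, kept free of the production code paths."""

import math

import numpy as np


def naive_k(xy, area, grid):
    """Plain double loop over ordered pairs: K(d) = A * count / n^2."""
    n = len(xy)
    k = np.zeros(len(grid))
    for gi, d in enumerate(grid):
        c = 0
        for i in range(n):
            for j in range(n):
                if i != j and math.hypot(xy[i, 0] - xy[j, 0], xy[i, 1] - xy[j, 1]) <= d:
                    c += 1
        k[gi] = area * c / n**2
    return k


def naive_k12(xy1, xy2, area, grid):
    """Directed cross count with denominator n1 * n2."""
    k = np.zeros(len(grid))
    for gi, d in enumerate(grid):
        c = 0
        for p in xy1:
            for q in xy2:
                if math.hypot(p[0] - q[0], p[1] - q[1]) <= d:
                    c += 1
        k[gi] = area * c / (len(xy1) * len(xy2))
    return k
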