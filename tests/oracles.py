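"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own code paths: the Fisher p-value
is computed by exact integer enumeration of all tables with the observed
margins, metal grouping by naive repeated expansion, and angles by direct
vector arithmetic.
"""

from __future__ import annotations

import math

import numpy as np


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by enumeration with exact integer weights.

    All tables with the observed margins are weighted by
    C(r1, x) * C(r2, c1 - x); since the hypergeometric denominator is
    common, tables are compared by integer weight (no rounding) and the
    p-value is the ratio of the qualifying weight sum to the total.
    """
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {x: math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)}
    observed = weights[a]
    numerator = sum(w for w in weights.values() if w <= observed)
    return numerator / sum(weights.values())


def transitive_groups(n: int, shared: set[tuple[int, int]]) -> list[frozenset[int]]:
    """Partition of range(n) by repeated expansion of a sharing relation."""
    groups = [set([i]) for i in range(n)]
    changed = True
    while changed:
        changed = False
        for i, j in shared:
            gi = next(g for g in groups if i in g)
            gj = next(g for g in groups if j in g)
            if gi is not gj:
                gi.update(gj)
                groups.remove(gj)
                changed = True
    return sorted((frozenset(g) for g in groups), key=min)


def vector_angle_deg(vertex: np.ndarray, p: np.ndarray, q: np.ndarray) -> float:
    u, v = np.asarray(p) - vertex, np.asarray(q) - vertex
    cos = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cos))))
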