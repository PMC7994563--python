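"""Brute-force set-based reference for the relation kernel.

Relations are explicit sets of (argument, level) pairs: abstraction is set
union, containment a per-column subset test, entropy evaluated directly
from per-column counts, and reduction's candidate support enumerated
exhaustively. Deliberately naive and independent of the table code path.
"""

import math


def o_abstraction(pairs_f: set, pairs_a: set) -> set:
    return set(pairs_f) | set(pairs_a)


def o_containment(pairs_a: set, pairs_f: set, n_args: int, relax: int = 0):
    failing_cols = {i for (i, v) in pairs_a if (i, v) not in pairs_f}
    return len(failing_cols) <= relax, len(failing_cols)


def o_entropy(pairs: set, n_args: int) -> float:
    total = 0.0
    for i in range(n_args):
        mu = sum(1 for (j, _) in pairs if j == i)
        if mu >= 1:
            total += math.log2(mu)
    return total / n_args


def o_column_support(pairs_f: set, col: int) -> list:
    return sorted(v for (i, v) in pairs_f if i == col)


def o_identity_reduction(assignment: dict, pairs_f: set, n_args: int):
    """Deterministic per-column choice: cue level if marked, else the marked
    level of minimal distance to the center (ties to the lower level); the
    center for an unassigned cue column is the median marked level.
    Columns without marks are left out."""
    out = {}
    for i in range(n_args):
        support = o_column_support(pairs_f, i)
        if not support:
            continue
        if i in assignment:
            c = assignment[i]
        else:
            k = len(support)
            # low median for even counts, matching numpy's interpolated
            # median floored to an int only when it is exact
            mid = (support[(k - 1) // 2] + support[k // 2]) / 2
            c = int(mid)
        out[i] = min(support, key=lambda v: (abs(v - c), v))
    return out


def o_triangular_support(assignment: dict, pairs_f: set, n_args: int):
    """Per-column candidate sets for the stochastic policy: the full marked set."""
    return {i: set(o_column_support(pairs_f, i))
            for i in range(n_args) if o_column_support(pairs_f, i)}
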