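"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: the
correspondence oracle enumerates injective type-consistent pairings by
depth-first search with no graph library, and the GH oracle mirrors the
printed formula in plain arithmetic.
"""

from __future__ import annotations

import math


def _dist(p, q) -> float:
    return math.dist(tuple(p), tuple(q))


def brute_force_correspondences(ref_feats, other_feats, tol):
    """All maximal distance-compatible injective type-consistent pairings.

    Returns a set of frozensets of (ref_index, other_index) pairs.
    Feasible for feature sets of up to ~6 points each.
    """
    nodes = [
        (i, j)
        for i in range(len(ref_feats))
        for j in range(len(other_feats))
        if ref_feats[i].type == other_feats[j].type
    ]

    def compatible(a, b):
        (i, j), (k, l) = a, b
        if i == k or j == l:
            return False
        return abs(
            _dist(ref_feats[i].position, ref_feats[k].position)
            - _dist(other_feats[j].position, other_feats[l].position)
        ) <= tol

    maximal: set[frozenset] = set()

    def extend(start: int, chosen: list) -> None:
        can_grow = False
        for idx, node in enumerate(nodes):
            if node in chosen:
                continue
            if all(compatible(node, c) for c in chosen):
                can_grow = True
                if idx >= start:
                    extend(idx + 1, chosen + [node])
        if chosen and not can_grow:
            maximal.add(frozenset(chosen))

    extend(0, [])
    return maximal


def gh_formula(D: int, A: int, Ht: int, Ha: int) -> float:
    """Goodness-of-hit, straight from the printed formula."""
    return (Ha / (4 * Ht * A)) * (3 * A + Ht) * (1 - (Ht - Ha) / (D - A))
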