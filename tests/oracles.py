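"""Independent reference implementations ("oracles") used by the tests.

These deliberately re-derive expected behaviour by brute force or closed
form, independent of the library code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# span-pairing oracles
# ---------------------------------------------------------------------------

def enumerate_pairings(starts: tuple, ends: tuple) -> list[list[tuple]]:
    """All ways to pair some starts with some ends into disjoint,
    order-consistent spans (brute force)."""
    results = []

    def recurse(s_left, e_left, acc):
        results.append(list(acc))
        for s in s_left:
            for e in e_left:
                if e >= s and (not acc or s > acc[-1][1]):
                    if all(not (s <= b and a <= e) for a, b in acc):
                        recurse(tuple(x for x in s_left if x > e),
                                tuple(x for x in e_left if x > e),
                                acc + [(s, e)])

    recurse(tuple(starts), tuple(ends), [])
    return results


def exhaustive_greedy_oracle(s_vec, e_vec) -> list[tuple]:
    """Select, among all valid pairings, the one the greedy rule prefers:
    lexicographically earliest pair sequence, longer preferred on ties."""
    starts = tuple(i + 1 for i, v in enumerate(s_vec) if v)
    ends = tuple(i + 1 for i, v in enumerate(e_vec) if v)
    candidates = enumerate_pairings(starts, ends)
    inf = float("inf")

    def key(pairing):
        flat = [x for pair in pairing for x in pair]
        return tuple(flat + [inf])

    return min(candidates, key=key)


def recursive_greedy_oracle(s_vec, e_vec) -> list[tuple]:
    """Independent recursive formulation of sequential start/end matching."""
    starts = [i + 1 for i, v in enumerate(s_vec) if v]
    ends = [i + 1 for i, v in enumerate(e_vec) if v]

    def recurse(ss, es):
        if not ss:
            return []
        s = ss[0]
        feasible = [e for e in es if e >= s]
        if not feasible:
            return []
        e = feasible[0]
        return [(s, e)] + recurse([x for x in ss if x > e],
                                  [x for x in es if x > e])

    return recurse(starts, ends)


# ---------------------------------------------------------------------------
# CRF enumeration oracle
# ---------------------------------------------------------------------------

def crf_enumerate(emissions: np.ndarray, transitions: np.ndarray,
                  start: np.ndarray, end: np.ndarray) -> dict[tuple, float]:
    """Score of every tag path, by direct summation."""
    n, T = emissions.shape
    out = {}
    for path in itertools.product(range(T), repeat=n):
        score = start[path[0]] + end[path[-1]]
        score += sum(emissions[i, t] for i, t in enumerate(path))
        score += sum(transitions[path[i - 1], path[i]] for i in range(1, n))
        out[path] = float(score)
    return out
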