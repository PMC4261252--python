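"""Independent brute-force oracles and random-machine generators for the tests.

Everything here avoids the library's composition/path-sum code paths: values
are obtained by explicit recursive enumeration of accepting paths, so the
oracles stay independent of the machinery they check.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

import numpy as np

from prknet.wfst_core import WeightedTransducer


def brute_force_value(t: WeightedTransducer, x: str, y: str) -> float:
    """T(x, y) by direct recursive enumeration of accepting paths."""

    by_state = defaultdict(list)
    for tr in t.transitions:
        by_state[tr[0]].append(tr)

    def rec(q, i, j, depth):
        if depth > 50:  # machines used with this oracle are acyclic
            raise RecursionError("path too long; oracle requires acyclic machines")
        total = t.final_weights.get(q, 0.0) if i == len(x) and j == len(y) else 0.0
        for _, a, b, w, q2 in by_state[q]:
            ni = i + 1 if a is not None and i < len(x) and x[i] == a else (i if a is None else None)
            if ni is None:
                continue
            nj = j + 1 if b is not None and j < len(y) and y[j] == b else (j if b is None else None)
            if nj is None:
                continue
            total += w * rec(q2, ni, nj, depth + 1)
        return total

    return sum(w * rec(q, 0, 0, 0) for q, w in t.initial_weights.items())


def brute_force_table(t: WeightedTransducer, max_len: int) -> dict:
    """All (x, y) -> T(x, y) over strings of length <= max_len (nonzero only)."""
    table = defaultdict(float)
    by_state = defaultdict(list)
    for tr in t.transitions:
        by_state[tr[0]].append(tr)

    # enumerate all paths from initial states (acyclic machines terminate)
    def walk(q, x, y, w):
        if q in t.final_weights and len(x) <= max_len and len(y) <= max_len:
            table[("".join(x), "".join(y))] += w * t.final_weights[q]
        for _, a, b, tw, q2 in by_state[q]:
            nx = x + [a] if a is not None else x
            ny = y + [b] if b is not None else y
            if len(nx) <= max_len and len(ny) <= max_len:
                walk(q2, nx, ny, w * tw)

    for q, w in t.initial_weights.items():
        walk(q, [], [], w)
    return {k: v for k, v in table.items() if v != 0.0}


def brute_force_compose_value(t1, t2, x: str, y: str, max_z: int) -> float:
    """Σ_z T1(x, z) · T2(z, y) over all intermediate strings with |z| <= max_z."""
    alphabet = sorted(t1.output_alphabet)
    total = 0.0
    for n in range(max_z + 1):
        for z in itertools.product(alphabet, repeat=n):
            z = "".join(z)
            v1 = brute_force_value(t1, x, z)
            if v1 != 0.0:
                total += v1 * brute_force_value(t2, z, y)
    return total


def count_accepting_paths(t: WeightedTransducer) -> int:
    """Number of accepting paths of an acyclic machine, by enumeration."""
    by_state = defaultdict(list)
    for tr in t.transitions:
        by_state[tr[0]].append(tr)

    def rec(q):
        n = 1 if q in t.final_weights else 0
        for tr in by_state[q]:
            n += rec(tr[4])
        return n

    return sum(rec(q) for q in t.initial_weights)


def random_acyclic_transducer(
    rng: np.random.Generator,
    n_states: int = 4,
    alphabet: str = "GC",
    n_transitions: int = 6,
    eps_prob: float = 0.2,
) -> WeightedTransducer:
    """Random acyclic machine: transitions only go from lower to higher state."""
    sigma = frozenset(alphabet)
    labels = list(alphabet)
    trans = []
    for _ in range(n_transitions):
        src = int(rng.integers(0, n_states - 1))
        dst = int(rng.integers(src + 1, n_states))
        ilab = None if rng.random() < eps_prob else labels[rng.integers(len(labels))]
        olab = None if rng.random() < eps_prob else labels[rng.integers(len(labels))]
        w = float(rng.integers(1, 5))
        trans.append((src, ilab, olab, w, dst))
    return WeightedTransducer(
        input_alphabet=sigma,
        output_alphabet=sigma,
        states=set(range(n_states)),
        initial_weights={0: 1.0},
        final_weights={n_states - 1: 1.0},
        transitions=trans,
    )


def naive_sliding_count(x: str, z: str) -> int:
    return sum(1 for i in range(len(x) - len(z) + 1) if x[i : i + len(z)] == z)


class TableKernel:
    """Base kernel backed by an explicit symmetric value table (test stub)."""

    def __init__(self, table: dict, default: float = 0.0):
        self._t = {}
        for (a, b), v in table.items():
            self._t[(a, b)] = v
            self._t[(b, a)] = v
        self._default = default

    def value(self, a, b):
        if a == b and (a, b) not in self._t:
            return 1.0
        return self._t.get((a, b), self._default)
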