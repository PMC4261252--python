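"""Weighted finite-state automata and transducers over the real (+, x) semiring.

A weighted transducer assigns each (input string, output string) pair the sum,
over all accepting paths consuming that input and emitting that output, of the
product of the initial weight, the transition weights along the path, and the
final weight.  Rational kernels evaluate such machines on sequence pairs by
composing them with *linear acceptors* (chain machines accepting exactly one
string) and summing accepting-path weights.

Only the operations the kernel machinery needs are provided: construction,
inverse, composition with proper epsilon handling, output projection, trimming
and exact path summation on acyclic machines.  There is no determinization,
minimization or cyclic shortest-distance; every machine whose total weight is
requested here becomes acyclic after composition with linear acceptors.

Epsilon (the empty label) is represented by ``None`` in memory and by the
token ``<eps>`` in the textual machine format.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

#: Token used for the empty label in the textual machine format.
EPS_TOKEN = "<eps>"

# A transition is (src, input label, output label, weight, dst); labels are
# symbols (single-character strings in practice) or None for epsilon.
Transition = tuple[object, object, object, float, object]


@dataclass
class WeightedTransducer:
    """A weighted finite-state transducer: the 8-tuple (Σ, Δ, Q, I, F, δ, λ, ρ).

    ``initial_weights`` is λ restricted to its support I; ``final_weights`` is
    ρ restricted to F.  States are opaque hashable identifiers.
    """

    input_alphabet: frozenset
    output_alphabet: frozenset
    states: set = field(default_factory=set)
    initial_weights: dict = field(default_factory=dict)
    final_weights: dict = field(default_factory=dict)
    transitions: list[Transition] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.input_alphabet = frozenset(self.input_alphabet)
        self.output_alphabet = frozenset(self.output_alphabet)
        self.validate()

    def validate(self) -> None:
        for src, ilab, olab, _, dst in self.transitions:
            if src not in self.states or dst not in self.states:
                raise ValueError(f"transition endpoint {src!r}->{dst!r} not in state set")
            if ilab is not None and ilab not in self.input_alphabet:
                raise ValueError(f"input label {ilab!r} outside input alphabet")
            if olab is not None and olab not in self.output_alphabet:
                raise ValueError(f"output label {olab!r} outside output alphabet")
        for q in itertools.chain(self.initial_weights, self.final_weights):
            if q not in self.states:
                raise ValueError(f"weighted state {q!r} not in state set")

    def is_acyclic(self) -> bool:
        """True when no directed cycle exists among the transitions."""
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.states)
        g.add_edges_from((s, d) for s, _, _, _, d in self.transitions)
        return nx.is_directed_acyclic_graph(g)


@dataclass
class WeightedAutomaton:
    """A weighted automaton: the 7-tuple (Σ, Q, I, F, δ, λ, ρ).

    Transitions are (src, label, weight, dst) with ``None`` as epsilon.
    """

    alphabet: frozenset
    states: set = field(default_factory=set)
    initial_weights: dict = field(default_factory=dict)
    final_weights: dict = field(default_factory=dict)
    transitions: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alphabet = frozenset(self.alphabet)
        for src, lab, _, dst in self.transitions:
            if src not in self.states or dst not in self.states:
                raise ValueError(f"transition endpoint {src!r}->{dst!r} not in state set")
            if lab is not None and lab not in self.alphabet:
                raise ValueError(f"label {lab!r} outside alphabet")

    def is_acyclic(self) -> bool:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.states)
        g.add_edges_from((s, d) for s, _, _, d in self.transitions)
        return nx.is_directed_acyclic_graph(g)

    def as_transducer(self) -> WeightedTransducer:
        """Identity-label transducer T with T(u, u) = A(u) and 0 elsewhere."""
        return WeightedTransducer(
            input_alphabet=self.alphabet,
            output_alphabet=self.alphabet,
            states=set(self.states),
            initial_weights=dict(self.initial_weights),
            final_weights=dict(self.final_weights),
            transitions=[(s, lab, lab, w, d) for s, lab, w, d in self.transitions],
        )


class CyclicMachineError(ValueError):
    """Raised when exact path summation meets a directed cycle."""

    def __init__(self, state: object):
        self.state = state
        super().__init__(f"machine is cyclic: state {state!r} lies on a directed cycle")


def linear_acceptor(x: Sequence, alphabet: Iterable) -> WeightedTransducer:
    """Trivial machine M_x accepting exactly ``x`` with weight 1.

    A chain of ``len(x) + 1`` states; transition i -> i+1 carries label
    (x_i : x_i) with weight 1; the single initial and single final state have
    weight 1.  M_x(x, x) = 1 and M_x(v, w) = 0 for any other pair, which makes
    M_x the evaluation probe of rational kernels: (M_x ∘ U ∘ M_y) has total
    weight U(x, y).
    """
    sigma = frozenset(alphabet)
    for sym in x:
        if sym not in sigma:
            raise ValueError(f"symbol {sym!r} not in declared alphabet")
    n = len(x)
    return WeightedTransducer(
        input_alphabet=sigma,
        output_alphabet=sigma,
        states=set(range(n + 1)),
        initial_weights={0: 1.0},
        final_weights={n: 1.0},
        transitions=[(i, x[i], x[i], 1.0, i + 1) for i in range(n)],
    )


def inverse(t: WeightedTransducer) -> WeightedTransducer:
    """T⁻¹ with input and output labels swapped: T⁻¹(y, x) = T(x, y)."""
    return WeightedTransducer(
        input_alphabet=t.output_alphabet,
        output_alphabet=t.input_alphabet,
        states=set(t.states),
        initial_weights=dict(t.initial_weights),
        final_weights=dict(t.final_weights),
        transitions=[(s, o, i, w, d) for s, i, o, w, d in t.transitions],
    )


def project_output(t: WeightedTransducer) -> WeightedAutomaton:
    """Output projection: automaton A with A(y) = Σ_x T(x, y).

    Input labels are dropped; transitions whose output label is epsilon
    become epsilon moves of the automaton.
    """
    return WeightedAutomaton(
        alphabet=t.output_alphabet,
        states=set(t.states),
        initial_weights=dict(t.initial_weights),
        final_weights=dict(t.final_weights),
        transitions=[(s, o, w, d) for s, _, o, w, d in t.transitions],
    )


def compose(t1: WeightedTransducer, t2: WeightedTransducer) -> WeightedTransducer:
    """Composition (T1 ∘ T2)(x, y) = Σ_z T1(x, z) · T2(z, y).

    Implemented as an on-the-fly product construction with the standard
    three-state epsilon filter, so that every pair of matching paths is
    counted exactly once even when both machines carry epsilons on the
    shared tape.  The filter admits, per block of epsilon moves, a single
    canonical interleaving: simultaneous epsilon moves are taken first
    (filter state 0), then any residual moves of one side alone (filter
    states 1 and 2); a real-symbol match resets the filter.
    """
    if t1.output_alphabet != t2.input_alphabet:
        raise ValueError(
            "alphabet mismatch: T1 output alphabet differs from T2 input alphabet"
        )

    t1_by_state: dict = defaultdict(list)
    for tr in t1.transitions:
        t1_by_state[tr[0]].append(tr)
    t2_by_in: dict = defaultdict(list)
    for src, ilab, olab, w, dst in t2.transitions:
        t2_by_in[(src, ilab)].append((olab, w, dst))

    initial: dict = {}
    for q1, w1 in t1.initial_weights.items():
        for q2, w2 in t2.initial_weights.items():
            initial[(q1, q2, 0)] = w1 * w2

    states: set = set(initial)
    transitions: list[Transition] = []
    stack = list(initial)

    def emit(src, ilab, olab, w, dst):
        transitions.append((src, ilab, olab, w, dst))
        if dst not in states:
            states.add(dst)
            stack.append(dst)

    while stack:
        state = stack.pop()
        q1, q2, f = state
        for _, a, b, w1, q1n in t1_by_state[q1]:
            if b is not None:
                # both sides advance on a real shared symbol
                for c, w2, q2n in t2_by_in[(q2, b)]:
                    emit(state, a, c, w1 * w2, (q1n, q2n, 0))
            else:
                # T1 advances alone on an epsilon-output transition
                if f in (0, 2):
                    emit(state, a, None, w1, (q1n, q2, 2))
                # paired epsilon move: T1 emits eps while T2 consumes eps
                if f == 0:
                    for c, w2, q2n in t2_by_in[(q2, None)]:
                        emit(state, a, c, w1 * w2, (q1n, q2n, 0))
        if f in (0, 1):
            # T2 advances alone on an epsilon-input transition
            for c, w2, q2n in t2_by_in[(q2, None)]:
                emit(state, None, c, w2, (q1, q2n, 1))

    final = {}
    for (q1, q2, f) in states:
        if q1 in t1.final_weights and q2 in t2.final_weights:
            final[(q1, q2, f)] = t1.final_weights[q1] * t2.final_weights[q2]

    return WeightedTransducer(
        input_alphabet=t1.input_alphabet,
        output_alphabet=t2.output_alphabet,
        states=states,
        initial_weights=initial,
        final_weights=final,
        transitions=transitions,
    )


def _edges(machine) -> list[tuple]:
    """Uniform (src, weight, dst) view of transitions of either machine kind."""
    if isinstance(machine, WeightedAutomaton):
        return [(s, w, d) for s, _, w, d in machine.transitions]
    return [(s, w, d) for s, _, _, w, d in machine.transitions]


def trim(machine):
    """Remove states not on some initial -> final path (and their transitions).

    Returns a machine of the same kind.  Trimming never changes the total
    weight; it only discards states that no accepting path visits.
    """
    edges = _edges(machine)
    fwd: dict = defaultdict(list)
    bwd: dict = defaultdict(list)
    for s, _, d in edges:
        fwd[s].append(d)
        bwd[d].append(s)

    def reach(seeds, adj):
        seen = set(seeds)
        stack = list(seeds)
        while stack:
            q = stack.pop()
            for r in adj[q]:
                if r not in seen:
                    seen.add(r)
                    stack.append(r)
        return seen

    accessible = reach(machine.initial_weights, fwd)
    coaccessible = reach(machine.final_weights, bwd)
    keep = accessible & coaccessible

    if isinstance(machine, WeightedAutomaton):
        return WeightedAutomaton(
            alphabet=machine.alphabet,
            states=keep,
            initial_weights={q: w for q, w in machine.initial_weights.items() if q in keep},
            final_weights={q: w for q, w in machine.final_weights.items() if q in keep},
            transitions=[t for t in machine.transitions if t[0] in keep and t[3] in keep],
        )
    return WeightedTransducer(
        input_alphabet=machine.input_alphabet,
        output_alphabet=machine.output_alphabet,
        states=keep,
        initial_weights={q: w for q, w in machine.initial_weights.items() if q in keep},
        final_weights={q: w for q, w in machine.final_weights.items() if q in keep},
        transitions=[t for t in machine.transitions if t[0] in keep and t[4] in keep],
    )


def path_sum(machine) -> float:
    """Exact total weight: Σ over accepting paths of λ(start) · Π weights · ρ(end).

    The machine is trimmed first; the remaining graph must be acyclic (the
    sum would otherwise be an infinite series).  Accumulation runs in
    topological order: forward[q] collects the weight of all partial paths
    from an initial state to q, and the answer is Σ_q forward[q] · ρ(q).
    Returns 0.0 when no accepting path exists.
    """
    m = trim(machine)
    if not m.states or not m.initial_weights or not m.final_weights:
        return 0.0

    edges = _edges(m)
    g = nx.MultiDiGraph()
    g.add_nodes_from(m.states)
    for s, w, d in edges:
        g.add_edge(s, d, weight=w)
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle_state = nx.find_cycle(g)[0][0]
        raise CyclicMachineError(cycle_state) from None

    incoming: dict = defaultdict(list)
    for s, w, d in edges:
        incoming[d].append((s, w))

    forward = {q: m.initial_weights.get(q, 0.0) for q in m.states}
    for q in order:
        for s, w in incoming[q]:
            forward[q] += forward[s] * w
    return sum(forward[q] * w for q, w in m.final_weights.items())


def value(t: WeightedTransducer, x: Sequence, y: Sequence) -> float:
    """T(x, y), evaluated as the total weight of M_x ∘ T ∘ M_y."""
    mx = linear_acceptor(x, t.input_alphabet)
    my = linear_acceptor(y, t.output_alphabet)
    return path_sum(compose(compose(mx, t), my))


def automaton_value(a: WeightedAutomaton, y: Sequence) -> float:
    """A(y): the sum of accepting-path weights of A labelled y."""
    return value(a.as_transducer(), y, y)


def read_machine_text(text: str) -> WeightedTransducer:
    """Parse the textual machine format.

    One line per transition ``src<TAB>in<TAB>out<TAB>weight<TAB>dst`` with
    ``<eps>`` for the empty label, plus ``initial<TAB>state<TAB>weight`` and
    ``final<TAB>state<TAB>weight`` lines.  Blank lines and ``#`` comments are
    ignored.  Alphabets are inferred from the labels present.
    """
    states: set = set()
    initial: dict = {}
    final: dict = {}
    transitions: list[Transition] = []
    in_alpha: set = set()
    out_alpha: set = set()

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] in ("initial", "final"):
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: expected 'initial|final<TAB>state<TAB>weight'")
            _, state, w = parts
            states.add(state)
            (initial if parts[0] == "initial" else final)[state] = float(w)
        else:
            if len(parts) != 5:
                raise ValueError(f"line {lineno}: expected 5 tab-separated fields")
            src, ilab_s, olab_s, w, dst = parts
            ilab = None if ilab_s == EPS_TOKEN else ilab_s
            olab = None if olab_s == EPS_TOKEN else olab_s
            states.update((src, dst))
            if ilab is not None:
                in_alpha.add(ilab)
            if olab is not None:
                out_alpha.add(olab)
            transitions.append((src, ilab, olab, float(w), dst))

    return WeightedTransducer(
        input_alphabet=frozenset(in_alpha),
        output_alphabet=frozenset(out_alpha),
        states=states,
        initial_weights=initial,
        final_weights=final,
        transitions=transitions,
    )


def write_machine_text(t: WeightedTransducer) -> str:
    """Serialize a transducer in the textual machine format (see reader)."""
    lines = []
    for q, w in sorted(t.initial_weights.items(), key=lambda kv: str(kv[0])):
        lines.append(f"initial\t{q}\t{w:.12g}")
    for q, w in sorted(t.final_weights.items(), key=lambda kv: str(kv[0])):
        lines.append(f"final\t{q}\t{w:.12g}")
    for src, ilab, olab, w, dst in t.transitions:
        i = EPS_TOKEN if ilab is None else ilab
        o = EPS_TOKEN if olab is None else olab
        lines.append(f"{src}\t{i}\t{o}\t{w:.12g}\t{dst}")
    return "\n".join(lines) + "\n"
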