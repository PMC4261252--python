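"""Metabolic-network graph model, pair labeling and balanced negative sampling.

A metabolic network is represented as a simple undirected graph whose nodes
are enzymes (genes) and whose edges are enzyme-enzyme relations: two enzymes
are related when a product of a reaction catalyzed by one serves as a
substrate of a reaction catalyzed by the other.  Supervised link prediction
labels known related pairs +1 and unrelated pairs -1; because almost all
pairs are unrelated, training uses a balanced sample of negatives whose node
frequencies approximate those of the positive set (degree-matched sampling),
avoiding the bias toward high-degree nodes that uniform sampling introduces.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from prknet.pairwise_kernels import PairwisePoint

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Reaction:
    """A catalyzed reaction: enzyme id, substrate ids and product ids."""

    enzyme: str
    substrates: frozenset
    products: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "substrates", frozenset(self.substrates))
        object.__setattr__(self, "products", frozenset(self.products))
        if not self.substrates or not self.products:
            raise ValueError(f"reaction of {self.enzyme!r}: substrate and product sets must be non-empty")


class MetabolicGraph:
    """Simple undirected graph of enzyme-enzyme relations (no self-loops)."""

    def __init__(self, nodes: Iterable[str] = (), edges: Iterable[tuple] = ()):
        self._g = nx.Graph()
        self._g.add_nodes_from(str(n) for n in nodes)
        n_dup = 0
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                raise ValueError(f"self-loop on node {a!r} is not allowed")
            if self._g.has_edge(a, b):
                n_dup += 1
            self._g.add_edge(a, b)
        if n_dup:
            logger.info("collapsed %d duplicate/reversed edges", n_dup)

    @property
    def nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self._g.edges}

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def degree(self, node: str) -> int:
        return self._g.degree[node]

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "MetabolicGraph":
        return cls(g.nodes, g.edges)


def reactions_to_graph(reactions: Sequence[Reaction]) -> MetabolicGraph:
    """Convert a reaction table to the enzyme-relation graph.

    An edge {e1, e2} is added whenever some product of a reaction catalyzed
    by e1 is a substrate of a reaction catalyzed by e2 (or vice versa);
    self-relations are excluded.
    """
    edges = set()
    enzymes = {r.enzyme for r in reactions}
    for r1 in reactions:
        for r2 in reactions:
            if r1.enzyme != r2.enzyme and r1.products & r2.substrates:
                edges.add(frozenset((r1.enzyme, r2.enzyme)))
    return MetabolicGraph(enzymes, (tuple(sorted(e)) for e in edges))


def label_pairs(g: MetabolicGraph) -> list[PairwisePoint]:
    """All C(n, 2) unordered node pairs, labeled +1 (edge) or -1 (non-edge)."""
    nodes = g.nodes
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes to form pairs")
    out = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            out.append(PairwisePoint(a, b, +1 if g.has_edge(a, b) else -1))
    return out


def count_noninteracting(g: MetabolicGraph) -> int:
    """Number of unordered non-edge pairs: C(n, 2) - |E|."""
    return math.comb(g.n_nodes, 2) - g.n_edges


def balanced_negative_sample(
    g: MetabolicGraph,
    n_neg: int,
    seed: int,
    mode: str = "degree_matched",
) -> list[PairwisePoint]:
    """Sample ``n_neg`` distinct non-edge pairs, labeled -1.

    ``degree_matched`` draws each endpoint with probability proportional to
    its degree in the positive set (rejecting edges, self-pairs and
    duplicates), so sampled negatives reproduce the node-frequency profile
    of the positives -- a balanced negative set in the sense of
    degree-preserving samplers used for interaction networks.  ``uniform``
    draws uniformly over all non-edges.  Fully reproducible under ``seed``.
    """
    if mode not in ("degree_matched", "uniform"):
        raise ValueError(f"unknown sampling mode {mode!r}")
    available = count_noninteracting(g)
    if n_neg > available:
        raise ValueError(f"requested {n_neg} negatives but only {available} non-edges exist")
    if n_neg == 0:
        return []

    rng = np.random.default_rng(seed)
    nodes = np.array(g.nodes)
    chosen: set[frozenset] = set()
    out: list[PairwisePoint] = []

    if mode == "degree_matched":
        deg = np.array([g.degree(n) for n in nodes], dtype=float)
        if deg.sum() > 0:
            probs = deg / deg.sum()
            max_draws = 200 * n_neg + 1000
            draws = 0
            while len(out) < n_neg and draws < max_draws:
                a, b = rng.choice(nodes, size=2, p=probs)
                draws += 2
                if a == b or g.has_edge(a, b):
                    continue
                key = frozenset((a, b))
                if key in chosen:
                    continue
                chosen.add(key)
                out.append(PairwisePoint(a, b, -1))
            if len(out) == n_neg:
                return out
            logger.info(
                "degree-matched sampling saturated at %d/%d; filling uniformly", len(out), n_neg
            )
        else:
            logger.info("graph has no edges; degree-matched mode falls back to uniform")

    # uniform mode, or completion of a saturated degree-matched draw:
    # enumerate all remaining non-edges and sample without replacement
    non_edges = [
        (a, b)
        for i, a in enumerate(nodes)
        for b in nodes[i + 1 :]
        if not g.has_edge(a, b) and frozenset((a, b)) not in chosen
    ]
    idx = rng.choice(len(non_edges), size=n_neg - len(out), replace=False)
    out.extend(PairwisePoint(*non_edges[i], label=-1) for i in sorted(idx))
    return out
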