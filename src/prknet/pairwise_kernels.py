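"""Pairwise rational kernels: similarity between *pairs* of genes.

Given a symmetric base kernel U on genes (here a rational kernel, typically
the normalized 3-gram kernel, or any precomputed PSD gene kernel), four
pairwise kernels between gene pairs (x1, y1) and (x2, y2) are defined:

    direct sum   U(x1,x2) + U(y1,y2) + U(y1,x2) + U(x1,y2)
    tensor       U(x1,x2)·U(y1,y2) + U(x1,y2)·U(y1,x2)
    metric       (U(x1,x2) − U(x1,y2) − U(y1,x2) + U(y1,y2))²
    cartesian    U(x1,x2)·δ(y1=y2) + δ(x1=x2)·U(y1,y2)
                 + U(x1,y2)·δ(y1=x2) + δ(x1=y2)·U(y1,x2)

δ compares gene *identifiers*.  Each value needs at most four base-kernel
evaluations; when U is a rational kernel each evaluation is one transducer
composition plus a path sum, and the base values are cached per unordered id
pair so a Gram matrix over m pairs costs O(m) distinct base evaluations.
All four constructions preserve positive semidefiniteness of the base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from prknet.rational_kernels import GramMatrix, NgramSpec, combine, ngram_kernel, ngram_transducer, pds_kernel_from
from prknet.wfst_core import WeightedTransducer, value as transducer_value

__all__ = [
    "PAIRWISE_KERNEL_TYPES",
    "PairwisePoint",
    "BaseKernel",
    "PrecomputedKernel",
    "SequenceKernel",
    "prk_value",
    "pairwise_gram",
    "combine",
]

#: Closed enumeration of the pairwise kernel constructions.
PAIRWISE_KERNEL_TYPES = ("direct_sum", "tensor", "metric", "cartesian")


@dataclass(frozen=True)
class PairwisePoint:
    """An unordered pair of gene identifiers with an optional ±1 label.

    Network edges are undirected, so the two ids are stored in lexicographic
    order; construction with either orientation yields the same point.
    """

    x: str
    y: str
    label: int | None = None

    def __post_init__(self) -> None:
        a, b = str(self.x), str(self.y)
        if a > b:
            a, b = b, a
        object.__setattr__(self, "x", a)
        object.__setattr__(self, "y", b)
        if self.label is not None and self.label not in (+1, -1):
            raise ValueError(f"label must be +1 or -1, got {self.label!r}")

    @property
    def id(self) -> str:
        return f"{self.x}|{self.y}"


class BaseKernel:
    """Symmetric kernel over gene identifiers; subclasses provide ``value``."""

    def value(self, a: str, b: str) -> float:  # pragma: no cover - interface
        raise NotImplementedError


class PrecomputedKernel(BaseKernel):
    """Base kernel backed by a precomputed Gram matrix (e.g. loaded from TSV).

    This is how non-sequence kernels -- phylogenetic or protein-domain
    similarity matrices -- enter the pairwise pipeline.
    """

    def __init__(self, gram: GramMatrix):
        self.gram = gram
        self._idx = {i: k for k, i in enumerate(gram.ids)}

    def value(self, a: str, b: str) -> float:
        try:
            return float(self.gram.values[self._idx[a], self._idx[b]])
        except KeyError as exc:
            raise KeyError(f"unknown gene identifier {exc.args[0]!r}") from None


class SequenceKernel(BaseKernel):
    """n-gram rational kernel over a store of named sequences, with caching.

    ``route="counts"`` evaluates via sparse n-gram count vectors (the fast
    path); ``route="transducer"`` evaluates value(T_n ∘ T_n⁻¹, x, y) by
    explicit composition and path summation.  The two agree and the test
    suite pins that.  ``normalize`` applies cosine normalization at the base
    level, before any pairwise construction.
    """

    def __init__(
        self,
        sequences: Mapping[str, str],
        spec: NgramSpec | None = None,
        normalize: bool = True,
        route: str = "counts",
    ):
        if route not in ("counts", "transducer"):
            raise ValueError(f"unknown route {route!r}")
        self.sequences = {str(k): str(v) for k, v in sequences.items()}
        self.spec = spec or NgramSpec()
        self.normalize = normalize
        self.route = route
        self._cache: dict[frozenset, float] = {}
        self._raw_cache: dict[frozenset, float] = {}
        self._u: WeightedTransducer | None = None

    def _raw(self, a: str, b: str) -> float:
        key = frozenset((a, b))
        if key in self._raw_cache:
            return self._raw_cache[key]
        v = self._raw_uncached(a, b)
        self._raw_cache[key] = v
        return v

    def _raw_uncached(self, a: str, b: str) -> float:
        if self.route == "counts":
            return ngram_kernel(self.sequences[a], self.sequences[b], self.spec)
        if self._u is None:
            self._u = pds_kernel_from(ngram_transducer(self.spec))
        return transducer_value(
            self._u, self.sequences[a].upper(), self.sequences[b].upper()
        )

    def value(self, a: str, b: str) -> float:
        for g in (a, b):
            if g not in self.sequences:
                raise KeyError(f"unknown gene identifier {g!r}")
        key = frozenset((a, b))
        if key in self._cache:
            return self._cache[key]
        v = self._raw(a, b)
        if self.normalize:
            daa = self._raw(a, a) if a != b else v
            dbb = self._raw(b, b) if a != b else v
            denom = (daa * dbb) ** 0.5
            v = v / denom if denom > 0 else 0.0
        self._cache[key] = v
        return v


def prk_value(kind: str, base: BaseKernel, p1: PairwisePoint, p2: PairwisePoint) -> float:
    """Pairwise kernel value K((x1, y1), (x2, y2)) of the given construction.

    At most four base-kernel evaluations are performed (the Cartesian kernel
    only evaluates the terms whose identifier indicator is nonzero).
    """
    if kind not in PAIRWISE_KERNEL_TYPES:
        raise ValueError(f"unknown pairwise kernel type {kind!r}; expected one of {PAIRWISE_KERNEL_TYPES}")
    x1, y1, x2, y2 = p1.x, p1.y, p2.x, p2.y
    u = base.value
    if kind == "direct_sum":
        return u(x1, x2) + u(y1, y2) + u(y1, x2) + u(x1, y2)
    if kind == "tensor":
        return u(x1, x2) * u(y1, y2) + u(x1, y2) * u(y1, x2)
    if kind == "metric":
        return (u(x1, x2) - u(x1, y2) - u(y1, x2) + u(y1, y2)) ** 2
    total = 0.0
    if y1 == y2:
        total += u(x1, x2)
    if x1 == x2:
        total += u(y1, y2)
    if y1 == x2:
        total += u(x1, y2)
    if x1 == y2:
        total += u(y1, x2)
    return total


def pairwise_gram(pairs: Sequence[PairwisePoint], kind: str, base: BaseKernel) -> GramMatrix:
    """Symmetric pairwise Gram matrix over a list of gene pairs.

    Row/column identifiers are ``"geneA|geneB"`` with the two gene ids in
    lexicographic order.  For the sequence-backed base kernel, caching keeps
    the number of distinct base evaluations linear in the number of distinct
    gene pairs encountered.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    if kind not in PAIRWISE_KERNEL_TYPES:
        raise ValueError(f"unknown pairwise kernel type {kind!r}; expected one of {PAIRWISE_KERNEL_TYPES}")

    genes = sorted({g for p in pairs for g in (p.x, p.y)})
    gi = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    # dense base matrix over the genes involved; caching in the base kernel
    # keeps this at one evaluation per unordered gene pair
    g_mat = np.empty((n, n))
    for i, a in enumerate(genes):
        for j in range(i, n):
            g_mat[i, j] = g_mat[j, i] = base.value(a, genes[j])

    ix = np.array([gi[p.x] for p in pairs])
    iy = np.array([gi[p.y] for p in pairs])
    kxx = g_mat[np.ix_(ix, ix)]
    kyy = g_mat[np.ix_(iy, iy)]
    kxy = g_mat[np.ix_(ix, iy)]  # U(x1, y2)
    kyx = g_mat[np.ix_(iy, ix)]  # U(y1, x2)

    if kind == "direct_sum":
        k = kxx + kyy + kyx + kxy
    elif kind == "tensor":
        k = kxx * kyy + kxy * kyx
    elif kind == "metric":
        k = (kxx - kxy - kyx + kyy) ** 2
    else:  # cartesian: identifier indicators gate each term
        ex = np.equal.outer(ix, ix)
        ey = np.equal.outer(iy, iy)
        exy = np.equal.outer(ix, iy)  # x1 == y2
        eyx = np.equal.outer(iy, ix)  # y1 == x2
        k = kxx * ey + ex * kyy + kxy * eyx + exy * kyx
    k = (k + k.T) / 2.0  # symmetrize away floating-point asymmetry
    return GramMatrix([p.id for p in pairs], k, normalized=False)
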