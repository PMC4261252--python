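"""n-gram rational kernels: counting transducers, kernel values, Gram matrices.

The n-gram (spectrum / k-mer) kernel between sequences x and y is

    k_n(x, y) = Σ_{|z| = n} c_x(z) · c_y(z),

where c_x(z) counts the (possibly overlapping) occurrences of the length-n
substring z in x.  It is a rational kernel: the counting transducer T_n
satisfies T_n(x, z) = c_x(z), and U = T_n ∘ T_n⁻¹ realizes k_n by transducer
composition; by the standard closure result, any U of the form T ∘ T⁻¹ is
positive definite symmetric, which licenses its use inside an SVM.

Two evaluation routes are provided and are required to agree: the transducer
route (composition with linear acceptors, then exact path summation) and a
direct route over sparse n-gram count vectors.  The direct route is the fast
path used to assemble Gram matrices; the transducer route is the defining one.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from prknet.wfst_core import (
    WeightedAutomaton,
    WeightedTransducer,
    compose,
    inverse,
    linear_acceptor,
    path_sum,
    value,
)

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class NgramSpec:
    """Parameters of the n-gram kernel: substring length n and the alphabet."""

    n: int = 3
    alphabet: frozenset = DNA_ALPHABET

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphabet", frozenset(self.alphabet))
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.alphabet:
            raise ValueError("alphabet must be non-empty")


def ngram_transducer(spec: NgramSpec) -> WeightedTransducer:
    """The counting transducer T_n with T_n(x, z) = c_x(z) for |z| = n.

    States 0..n; every alphabet symbol has an epsilon-output self-loop
    (σ : ε / 1) at states 0 and n, which skips a prefix and a suffix of x,
    and a matching transition (σ : σ / 1) from i to i+1, which copies one
    symbol of the occurrence.  Each accepting path picks one occurrence of
    one n-gram, so path multiplicity realizes the count.
    """
    sigma = spec.alphabet
    trans = []
    for s in sigma:
        trans.append((0, s, None, 1.0, 0))
        trans.append((spec.n, s, None, 1.0, spec.n))
    for i in range(spec.n):
        for s in sigma:
            trans.append((i, s, s, 1.0, i + 1))
    return WeightedTransducer(
        input_alphabet=sigma,
        output_alphabet=sigma,
        states=set(range(spec.n + 1)),
        initial_weights={0: 1.0},
        final_weights={spec.n: 1.0},
        transitions=trans,
    )


def _clean(x: str, alphabet: frozenset) -> str:
    return str(x).upper()


def _ngram_counts(x: str, spec: NgramSpec) -> Counter:
    """Sparse count vector of all alphabet-only n-grams of x (overlapping)."""
    x = _clean(x, spec.alphabet)
    n = spec.n
    counts: Counter = Counter()
    skipped = 0
    for i in range(len(x) - n + 1):
        z = x[i : i + n]
        if all(c in spec.alphabet for c in z):
            counts[z] += 1
        else:
            skipped += 1
    if skipped:
        logger.warning("skipped %d n-grams containing out-of-alphabet symbols", skipped)
    return counts


def ngram_count(x: str, z: str, spec: NgramSpec | None = None) -> int:
    """c_x(z): occurrences of z in x, overlaps included.

    ``z`` must have length ``spec.n``.  Computed by direct sliding-window
    scan; the test suite pins agreement with value(T_n, x, z).
    """
    spec = spec or NgramSpec()
    z = _clean(z, spec.alphabet)
    if len(z) != spec.n:
        raise ValueError(f"query length {len(z)} differs from n = {spec.n}")
    x = _clean(x, spec.alphabet)
    return sum(1 for i in range(len(x) - len(z) + 1) if x[i : i + len(z)] == z)


def automaton_ngram_count(a: WeightedAutomaton, z: str, spec: NgramSpec | None = None) -> float:
    """Count of z in a weighted automaton: Σ_u c_u(z) · A(u).

    ``A`` must be acyclic so that the sum over its (finite) language is
    finite.  Evaluated exactly as the total weight of A ∘ T_n ∘ M_z.
    """
    spec = spec or NgramSpec()
    if not a.is_acyclic():
        raise ValueError("automaton must be acyclic (finite language)")
    z = _clean(z, spec.alphabet)
    if len(z) != spec.n:
        raise ValueError(f"query length {len(z)} differs from n = {spec.n}")
    t_a = a.as_transducer()
    t_n = ngram_transducer(spec)
    m_z = linear_acceptor(z, spec.alphabet)
    return path_sum(compose(compose(t_a, t_n), m_z))


def pds_kernel_from(t: WeightedTransducer) -> WeightedTransducer:
    """U = T ∘ T⁻¹, a positive definite symmetric rational kernel."""
    return compose(t, inverse(t))


def ngram_kernel(x: str, y: str, spec: NgramSpec | None = None) -> float:
    """k_n(x, y) = Σ_{|z|=n} c_x(z) · c_y(z), via sparse count vectors.

    Equals value(T_n ∘ T_n⁻¹, x, y); the transducer route is exercised by
    the test suite on short sequences.
    """
    spec = spec or NgramSpec()
    cx = _ngram_counts(x, spec)
    cy = _ngram_counts(y, spec)
    if len(cy) < len(cx):
        cx, cy = cy, cx
    return float(sum(c * cy[z] for z, c in cx.items()))


@dataclass
class GramMatrix:
    """Symmetric kernel matrix with row/column identifiers.

    ``normalized`` records whether cosine normalization
    K'(i, j) = K(i, j) / sqrt(K(i, i) K(j, j)) has been applied.
    """

    ids: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.ids)
        if self.values.shape != (m, m):
            raise ValueError(f"matrix shape {self.values.shape} does not match {m} ids")
        if m and not np.allclose(self.values, self.values.T, rtol=1e-9, atol=1e-9):
            raise ValueError("kernel matrix is not symmetric")

    def index(self, id_: str) -> int:
        try:
            return self.ids.index(id_)
        except ValueError:
            raise KeyError(f"unknown identifier {id_!r}") from None

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def normalize(self) -> "GramMatrix":
        """Cosine-normalized copy; entries with a zero diagonal map to 0."""
        d = np.sqrt(np.clip(np.diag(self.values), 0.0, None))
        denom = np.outer(d, d)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(denom > 0, self.values / denom, 0.0)
        np.fill_diagonal(vals, np.where(d > 0, 1.0, 0.0))
        return GramMatrix(list(self.ids), vals, normalized=True)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh((self.values + self.values.T) / 2.0)[0])

    def to_tsv(self, path) -> None:
        """Full square matrix as TSV, identifiers on the first row and column."""
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        df.to_csv(path, sep="\t", float_format="%.12g", index_label="id")

    @classmethod
    def from_tsv(cls, path, normalized: bool = False) -> "GramMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [str(i) for i in df.index]
        if ids != [str(c) for c in df.columns]:
            raise ValueError("row and column identifiers differ")
        return cls(ids, df.to_numpy(dtype=float), normalized=normalized)


def gram_matrix(
    seqs: Mapping[str, str] | Sequence[str],
    spec: NgramSpec | None = None,
    normalize: bool = True,
) -> GramMatrix:
    """Pairwise n-gram kernel matrix over a collection of sequences.

    ``seqs`` is a mapping id -> sequence (an iterable of sequences gets
    positional ids ``s0, s1, ...``).  Cosine normalization (on by default)
    divides by sqrt(k(x,x) k(y,y)) so that longer sequences, which contain
    more n-grams, do not dominate the similarity scale.
    """
    spec = spec or NgramSpec()
    if not isinstance(seqs, Mapping):
        seqs = {f"s{i}": s for i, s in enumerate(seqs)}
    if not seqs:
        raise ValueError("sequence collection is empty")
    ids = list(seqs)
    counters = [_ngram_counts(seqs[i], spec) for i in ids]
    vocab = sorted(set().union(*[c.keys() for c in counters]))
    col = {z: j for j, z in enumerate(vocab)}
    c_mat = np.zeros((len(ids), max(len(vocab), 1)))
    for r, cnt in enumerate(counters):
        for z, c in cnt.items():
            c_mat[r, col[z]] = c
    k = c_mat @ c_mat.T
    gm = GramMatrix(ids, k, normalized=False)
    return gm.normalize() if normalize else gm


def combine(k1: GramMatrix, k2: GramMatrix, w1: float = 1.0, w2: float = 1.0) -> GramMatrix:
    """Weighted sum w1·K1 + w2·K2 of two Gram matrices over identical ids.

    A sum of PSD kernels with nonnegative weights is PSD, which is how the
    sequence kernel is enriched with precomputed non-sequence kernels
    (phylogenetic profiles, domain content) sharing the same gene ids.
    """
    if k1.ids != k2.ids:
        first = next((a for a, b in zip(k1.ids, k2.ids) if a != b), None)
        if first is None:
            first = (k1.ids + k2.ids)[min(len(k1.ids), len(k2.ids))]
        raise ValueError(f"identifier mismatch between matrices (first difference: {first!r})")
    return GramMatrix(list(k1.ids), w1 * k1.values + w2 * k2.values, normalized=False)
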