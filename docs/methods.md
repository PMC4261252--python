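# Methods

## Weighted-transducer algebra

Machines live over the real `(+, ×)` semiring — the only weights the kernel
constructions need; no log or tropical variants are provided. A transducer
value `T(x, y)` is the sum over accepting paths of initial weight × product
of transition weights × final weight, evaluated as the total weight of
`M_x ∘ T ∘ M_y` with `M_x`, `M_y` linear acceptors.

*Composition* uses the standard three-state epsilon filter. Without it, a
block of epsilon moves on the shared tape admits several interleavings per
pair of matching paths and the identity `(T1∘T2)(x,y) = Σ_z T1(x,z)·T2(z,y)`
breaks. The filter admits exactly one canonical interleaving: paired
epsilon moves first (filter state 0), then residual one-sided moves (states
1/2), with real-symbol matches resetting the filter. The test suite checks
the identity against exhaustive enumeration over intermediate strings on
random machines.

*Path summation* trims inaccessible and non-coaccessible states, then
accumulates forward weights in topological order. Cyclic machines are
rejected with a state on the cycle named — exact summation on cyclic
machines is a geometric-series computation this package deliberately omits.
Every machine whose total weight the pipeline requests is acyclic by
construction: the counting transducer's only cycles are symbol-consuming
self-loops, which composition with linear acceptors unrolls. Weights are
kept as IEEE doubles with no flush-to-zero; numerical comparisons in tests
use 1e-9 relative tolerance.

## n-gram kernel

`T_n` has states `0..n`, symbol-consuming epsilon-output self-loops at
states 0 and n (skipping a prefix/suffix), and copying transitions
`i → i+1`; each accepting path of `M_x ∘ T_n` selects one occurrence of one
n-gram, so path multiplicity is the count, overlaps included. The kernel
`k_n = Σ_z c_x(z)·c_y(z)` is computed two ways: by explicit composition
with `U = T_n ∘ T_n⁻¹` (the defining route) and by sparse count-vector dot
products (the fast route used for Gram matrices, linear in sequence
length). The two are pinned against each other in tests; Gram assembly
vectorizes the count route as `C·Cᵀ`.

Choices:

- **Normalization** is cosine, `k/√(k_xx·k_yy)` with `0/0 ↦ 0`, applied at
  the *base* (gene) level before any pairwise construction; a flag disables
  it. Cosine is the standard correction for longer sequences containing
  more n-grams; normalizing at the pairwise level instead is possible by
  assembling the pairwise Gram and calling its `normalize()`.
- **Out-of-alphabet symbols** (e.g. `N`): n-grams containing them are
  skipped with a logged warning rather than matched or errored — skipping
  avoids silently inflating similarity. Input is uppercased.
- **Default `n = 3`**, alphabet `{A, C, G, T}`.

## Pairwise kernels

The four constructions are implemented exactly as their defining formulas
(see README table). Two deliberate readings:

- The **direct sum** keeps both cross terms `U(y1,x2) + U(x1,y2)`, although
  additive pairwise kernels in the wider literature often omit them.
- The Cartesian **δ compares gene identifiers**, not sequences: two genes
  with identical sequence but different ids are distinct entities.

Network pairs are unordered; `PairwisePoint` canonicalizes the two ids
lexicographically at construction, so every kernel value and file format is
orientation-independent. Base values are cached per unordered id pair —
a pairwise Gram over m pairs costs O(m) distinct base evaluations, and the
assembly is vectorized from a dense base matrix over the genes involved.

## Network model and negative sampling

The graph is simple and undirected (self-loops rejected, duplicate and
reversed edges collapsed with a logged count). Reaction tables convert to
edges by product–substrate sharing between distinct enzymes. Labeling emits
all `C(n,2)` pairs, `+1` for edges.

Because non-edges vastly outnumber edges, training uses a balanced negative
sample. The sampler's `degree_matched` mode draws endpoints with
probability proportional to positive-set degree and rejects edges,
self-pairs and duplicates, so negative node frequencies approximate
positive ones (degree-preserving negative sampling); `uniform` mode draws
uniformly over non-edges. If degree-matched rejection saturates (tiny or
near-complete graphs), the remainder is filled uniformly with a logged
notice. Sampling is exactly reproducible under a seed. Degree matching is
distorted on graphs where a node's neighborhood holds most of the degree
mass (its partners are then mostly rejected); the test suite quantifies the
match on a hub graph where this effect is small.

## Pairwise SVM and evaluation

The soft-margin dual on the precomputed pairwise Gram is solved by the SMO
solver behind scikit-learn's `SVC(kernel="precomputed")`; the model stores
dense `α ∈ [0, C]`, labels, and offset `b`, so
`f(q) = Σ_p α_p d_p K(p,q) + b` is reproducible from the serialized JSON
alone, and tests verify KKT conditions and agreement with an independent
quadratic-program solve. `C` defaults to 1.0 with no grid search. The
classification rule maps `f = 0` to `+1`.

ROC AUC uses the Mann–Whitney midrank form (ties count one half); a
trapezoidal computation and an external reference pin it in tests.
Cross-validation is stratified (both classes in every fold on balanced
data), seeded, and bit-reproducible; the report carries per-fold AUCs,
their mean, the error count at the `f ≥ 0` threshold, and a confidence
interval.

**AUC confidence interval.** The interval is a normal approximation
`AUC ± z·σ̂` clipped to `[0,1]`, with `σ̂²` the distribution-free bound on
the Mann–Whitney variance, `Â(1−Â)/min(m,n)` for `m` positives and `n`
negatives — deliberately conservative and assumption-free. When `Â ∈ {0,1}`
the bound degenerates, and the error rate `k/(m+n)` (floored at `1/(m+n)`)
supplies the spread so the interval never collapses on finite data. The
signature `(auc, n_pos, n_neg, n_errors, level)` is the extension point for
error-count-based interval estimators of the same shape.

**McNemar comparison.** `z = (n_fs − n_sf)/√(n_fs + n_sf)`, signed so that
positive z favors the second classifier, zero at symmetric disagreement,
undefined (rejected) when both counts are zero. A flag applies the
continuity correction `(|d|−1)` while keeping the sign.

## Synthetic data: what it emulates, what it does not

The generator partitions genes into near-equal modules (pathway groups),
makes every within-module pair an edge, and plants module-private motifs
into i.i.d. uniform background sequence. Motif copies *replace* background
characters at non-overlapping positions (an exact block construction, so
any occupancy the config admits is feasible), keeping sequence length
invariant and isolating kernel-normalization effects. An optional GC-bias
parameter skews the background; it defaults off.

Defaults — 60 genes × 300 nt, 6 modules, 4 private 6-mers × 6 copies per
gene (48% footprint) — are a deliberately *strong* shared-motif condition,
comparable to pathway members sharing conserved domain content. Under a
uniform background, cosine 3-gram similarity between unrelated 300-mers is
already ≈0.85 with spread ≈0.07, so a weak planted signal (e.g. 2 motifs ×
3 copies, 12% footprint) is recoverable only by the metric construction,
whose double difference cancels the shared background; at the default
strength, tensor and Cartesian kernels also separate modules cleanly while
the direct sum stays near chance.

What passing tests show: the full pipeline — counting transducers, pairwise
constructions, SVM, cross-validation — recovers planted co-membership
signal from raw sequence and stays at chance when no signal is planted.
What they do not show: performance on real genomes, where background
composition is non-uniform, homology is partial and noisy, modules overlap,
and interaction graphs are far from unions of cliques.

A note on the null calibration: with module-structured labels the
zero-signal cross-validated AUC averages ≈0.41–0.42, slightly *below* 0.5.
This is the shared-entity leakage characteristic of pairwise
cross-validation (pairs in different folds share genes); shuffling labels
on the same kernels restores ≈0.5. It is a property of the evaluation
design, not of the kernels.

## Problem sizes used in the evaluation suite

The signal-recovery study uses the generator defaults with 100 positive and
100 degree-matched negative pairs per seed, 10-fold cross-validation, and
10 seeds per condition; exhaustive path-enumeration oracles run on machines
with ≤6 states and strings of length ≤3; PSD checks use 10–15 sequences or
pairs. These sizes make every check exact or statistically stable while the
whole suite runs in seconds.

## Known limitations

- Exact path summation only on acyclic machines; kernels over cyclic
  automata (infinite languages) are out of scope, as are gappy/mismatch
  kernels, determinization and weight pushing.
- The Cartesian kernel is informative only where query pairs share genes
  with training pairs.
- The confidence interval is conservative by construction; it over-covers.
- Construction of phylogenetic or domain-content gene kernels is out of
  scope; they enter only as precomputed TSV matrices.
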