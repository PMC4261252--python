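"""Seeded generator of gene sequences with a planted interaction network.

The generator emulates the kind of data the pipeline consumes -- a set of
genes with nucleotide sequences plus a partially known interaction graph --
while giving the n-gram kernel a controllable signal: genes are partitioned
into modules (stand-ins for pathway groups), every within-module pair is an
interacting (+1) edge, and each module owns a few private sequence motifs
inserted into every member's otherwise uniform random background.  Member
genes therefore share exact k-mers, so n-gram similarity is informative
about co-membership; with ``motif_copies = 0`` the sequences carry no signal
at all, which serves as the null model for calibration.

``worked_examples`` returns the small hand-checkable fixtures used across
the documentation and tests: a five-transition weighted transducer with
exactly two accepting paths for the pair (GGC, CCG), and four short
nucleotide sequences with known 3-gram counts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from prknet.network_model import MetabolicGraph
from prknet.wfst_core import WeightedTransducer, write_machine_text


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the planted-motif generator.

    Defaults describe 60 genes of length 300 nt in 6 equal modules, each
    module carrying 4 private 6-mer motifs inserted 6 times per member gene
    (144 planted positions out of 300, a 48% signal footprint over an
    i.i.d. uniform background -- a strong shared-motif signal, in the way
    genes of one pathway share conserved domain content).
    """

    n_genes: int = 60
    seq_length: int = 300
    alphabet: str = "ACGT"
    n_modules: int = 6
    motif_length: int = 6
    motifs_per_module: int = 4
    motif_copies: int = 6
    gc_bias: float | None = None  # P(G or C); None means uniform
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules > self.n_genes:
            raise ValueError("n_modules cannot exceed n_genes")
        if self.seq_length <= self.motif_length * self.motif_copies * self.motifs_per_module:
            raise ValueError("sequence too short for the requested motif insertions")
        if self.gc_bias is not None and not (0.0 < self.gc_bias < 1.0):
            raise ValueError("gc_bias must lie strictly between 0 and 1")


def _module_sizes(n_genes: int, n_modules: int) -> list[int]:
    # as equal as possible; the remainder goes to the earliest modules
    base, rem = divmod(n_genes, n_modules)
    return [base + (1 if i < rem else 0) for i in range(n_modules)]


def _insert_motifs(seq: list, motifs: list[str], copies: int, rng) -> None:
    """Overwrite background characters with motif copies at non-overlapping spots.

    All blocks are placed at once: k non-overlapping blocks of length L fit
    uniformly into a sequence of length S by drawing k sorted anchors from
    S - k(L-1) positions and spreading them, so placement succeeds for any
    occupancy the config invariant admits.
    """
    if not motifs or copies == 0:
        return
    mlen = len(motifs[0])
    k = len(motifs) * copies
    s = len(seq)
    anchors = np.sort(rng.choice(s - k * (mlen - 1), size=k, replace=False))
    starts = anchors + np.arange(k) * (mlen - 1)
    blocks = [m for m in motifs for _ in range(copies)]
    rng.shuffle(blocks)
    for start, motif in zip(starts, blocks):
        seq[start : start + mlen] = list(motif)


def generate(config: SyntheticConfig) -> tuple[dict[str, str], MetabolicGraph]:
    """Generate (sequences, interaction graph) under the given conditions.

    Returns an id -> sequence mapping (ids ``g000, g001, ...`` in order) and
    the module co-membership graph.  Identical configs (including the seed)
    give byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    letters = list(config.alphabet)
    if config.gc_bias is None:
        probs = None
    else:
        gc = {"G", "C"}
        n_gc = sum(1 for c in letters if c in gc)
        n_at = len(letters) - n_gc
        probs = [
            (config.gc_bias / n_gc) if c in gc else ((1 - config.gc_bias) / n_at)
            for c in letters
        ]

    sizes = _module_sizes(config.n_genes, config.n_modules)
    width = max(3, len(str(config.n_genes - 1)))
    gene_ids = [f"g{i:0{width}d}" for i in range(config.n_genes)]

    module_of: list[int] = []
    for m, size in enumerate(sizes):
        module_of.extend([m] * size)

    motifs = [
        [
            "".join(rng.choice(letters, size=config.motif_length))
            for _ in range(config.motifs_per_module)
        ]
        for _ in range(config.n_modules)
    ]

    sequences: dict[str, str] = {}
    for gid, m in zip(gene_ids, module_of):
        seq = list(rng.choice(letters, size=config.seq_length, p=probs))
        if config.motif_copies > 0:
            _insert_motifs(seq, motifs[m], config.motif_copies, rng)
        sequences[gid] = "".join(seq)

    edges = [
        (gene_ids[i], gene_ids[j])
        for i in range(config.n_genes)
        for j in range(i + 1, config.n_genes)
        if module_of[i] == module_of[j]
    ]
    return sequences, MetabolicGraph(gene_ids, edges)


def write_dataset(config: SyntheticConfig, outdir) -> dict[str, Path]:
    """Generate and write genes.fasta, edges.tsv and manifest.json."""
    from prknet.interface_io import write_edge_list, write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sequences, graph = generate(config)
    paths = {
        "fasta": outdir / "genes.fasta",
        "edges": outdir / "edges.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_fasta(paths["fasta"], sequences)
    write_edge_list(paths["edges"], graph.edges)
    with open(paths["manifest"], "w") as fh:
        json.dump({"config": asdict(config)}, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


# -- worked-example fixtures -------------------------------------------------

#: Short nucleotide sequences with hand-countable 3-gram content:
#: x1 and y1 each contain TCT twice; y2 contains TCT three times.
EXAMPLE_SEQUENCES = {
    "x1": "GCTAAATTGGACAAATCTCAATGAAATTGTCTTGG",
    "y1": "ATGTCCTCGTCTTCGTCTACCGGGTACAGAAAA",
    "x2": "CATGACTAAAGAAACGATTCGGGTAGTTATTTGGCGG",
    "y2": "ATCTACAAGCGAACCAGAGTCTTCTGCAGGCTTAGAT",
}


def example_transducer() -> WeightedTransducer:
    """Four-state transducer over {G, C} with T(GGC, CCG) = 48.

    Exactly two paths accept input GGC with output CCG:
    0->0->1->3 with transition weights 2·3·6 and 0->1->2->3 with 3·1·4;
    initial and final weights are 1, so the value is 36 + 12 = 48.
    """
    sigma = frozenset("GC")
    return WeightedTransducer(
        input_alphabet=sigma,
        output_alphabet=sigma,
        states={0, 1, 2, 3},
        initial_weights={0: 1.0},
        final_weights={3: 1.0},
        transitions=[
            (0, "G", "C", 2.0, 0),
            (0, "G", "C", 3.0, 1),
            (1, "G", "C", 1.0, 2),
            (1, "C", "G", 6.0, 3),
            (2, "C", "G", 4.0, 3),
        ],
    )


@dataclass(frozen=True)
class FixtureBundle:
    """The worked-example transducer plus the four example sequences."""

    transducer: WeightedTransducer
    sequences: dict[str, str]

    def machine_text(self) -> str:
        """The transducer in the textual machine format."""
        return write_machine_text(self.transducer)

    def fasta_text(self) -> str:
        return "".join(f">{k}\n{v}\n" for k, v in self.sequences.items())


def worked_examples() -> FixtureBundle:
    """Fixture bundle backing the documentation examples and the test suite."""
    return FixtureBundle(example_transducer(), dict(EXAMPLE_SEQUENCES))
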