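"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA for sequences, TSV for edge lists, labeled pairs, Gram matrices,
predictions and reports, JSON for model documents and simulation manifests.
All numeric output uses 12 significant digits so files diff cleanly and
round-trip through the corresponding readers.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from prknet.inference_eval import EvalReport
from prknet.pairwise_kernels import PairwisePoint

logger = logging.getLogger(__name__)


def read_fasta(path) -> dict[str, str]:
    """FASTA -> ordered id -> sequence map (uppercased).

    Duplicate record ids and empty sequences are rejected by name.
    """
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValueError(f"duplicate FASTA record id {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for FASTA record {record.id!r}")
        out[record.id] = seq
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    """Write sequences one record per ``>id`` line, sequence on a single line."""
    with open(path, "w") as fh:
        for gid, seq in sequences.items():
            fh.write(f">{gid}\n{seq.upper()}\n")


def read_edge_list(path) -> list[tuple[str, str]]:
    """Two-column TSV of gene pairs; a ``gene_a``/``gene_b`` header is optional."""
    edges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            if lineno == 1 and parts[0] in ("gene_a", "source", "from"):
                continue
            edges.append((parts[0], parts[1]))
    return edges


def write_edge_list(path, edges: Iterable) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for e in sorted(tuple(sorted(e)) for e in edges):
            fh.write(f"{e[0]}\t{e[1]}\n")


def read_labeled_pairs(path) -> list[PairwisePoint]:
    """TSV ``gene_a<TAB>gene_b<TAB>label`` with label in {+1, -1}."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    for col in ("gene_a", "gene_b", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return [
        PairwisePoint(row.gene_a, row.gene_b, int(row.label))
        for row in df.itertuples()
    ]


def write_labeled_pairs(path, pairs: Iterable[PairwisePoint]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tlabel\n")
        for p in pairs:
            fh.write(f"{p.x}\t{p.y}\t{p.label:+d}\n")


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    for col in ("gene_a", "gene_b", "score", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


def write_predictions(path, rows: Iterable[tuple[str, str, float, int]]) -> None:
    """TSV ``gene_a<TAB>gene_b<TAB>score<TAB>label`` (label is the ±1 call)."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tscore\tlabel\n")
        for a, b, score, label in rows:
            fh.write(f"{a}\t{b}\t{score:.12g}\t{label:+d}\n")


def write_report(path_prefix, report: EvalReport) -> tuple[Path, Path]:
    """Write an evaluation report as TSV (per-fold) and a plain-text summary."""
    prefix = Path(path_prefix)
    tsv_path = prefix.with_suffix(".tsv")
    txt_path = prefix.with_suffix(".txt")
    pd.DataFrame(report.summary_rows()).to_csv(
        tsv_path, sep="\t", index=False, float_format="%.12g"
    )
    lines = [
        f"folds\t{report.folds}",
        f"seed\t{report.seed}",
        f"n_pos\t{report.n_pos}",
        f"n_neg\t{report.n_neg}",
        f"mean_auc\t{report.mean_auc:.12g}",
        f"ci_low\t{report.ci[0]:.12g}",
        f"ci_high\t{report.ci[1]:.12g}",
        f"n_errors\t{report.n_errors}",
    ]
    txt_path.write_text("\n".join(lines) + "\n")
    return tsv_path, txt_path
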