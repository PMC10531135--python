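"""Validation metrics for simulated (or real) metabarcoding runs.

The fidelity of a simulation is judged by comparing, between real and
simulated data: the alignment-derived sequencing error rate, the percentage
of unmapped reads, the identity mean/SD, species-level precision and recall
against a known community, and the read-length mean/SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import AlignmentSummary, parse_sam, read_truth_table

__all__ = [
    "EvalMetrics",
    "error_rate",
    "pct_unmapped",
    "identity_stats",
    "precision_recall",
    "length_summary",
    "assignments_from_alignments",
    "evaluate",
    "length_histogram",
]


@dataclass
class EvalMetrics:
    error_rate: float
    pct_unmapped: float
    identity_mean: float
    identity_sd: float
    precision: float
    recall: float
    length_mean: float
    length_sd: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.recall <= self.precision <= 1.0):
            raise ValueError(
                f"need 0 <= recall <= precision <= 1, got precision="
                f"{self.precision}, recall={self.recall}"
            )

    def report_rows(self) -> list[tuple[str, float]]:
        return [
            ("error_rate", self.error_rate),
            ("pct_unmapped", self.pct_unmapped),
            ("identity_mean", self.identity_mean),
            ("identity_sd", self.identity_sd),
            ("precision", self.precision),
            ("recall", self.recall),
            ("length_mean", self.length_mean),
            ("length_sd", self.length_sd),
        ]


def error_rate(alignments: Iterable[AlignmentSummary]) -> float:
    """Pooled percent error over mapped primary alignments:
    100 * (mismatch + ins + del) / aligned columns."""
    err = cols = 0
    for a in alignments:
        if a.mapped:
            err += a.n_mismatch + a.n_ins + a.n_del
            cols += a.n_match + a.n_mismatch + a.n_ins + a.n_del
    if cols == 0:
        raise ValueError("no mapped alignments")
    return 100.0 * err / cols


def pct_unmapped(alignments: Sequence[AlignmentSummary]) -> float:
    if not alignments:
        raise ValueError("no alignment records")
    unmapped = sum(1 for a in alignments if not a.mapped)
    return 100.0 * unmapped / len(alignments)


def identity_stats(alignments: Iterable[AlignmentSummary]) -> tuple[float, float]:
    """Mean and population SD of per-read percent identity (mapped reads)."""
    idents = np.array([a.identity for a in alignments if a.mapped])
    if idents.size == 0:
        raise ValueError("no mapped alignments")
    return float(idents.mean()), float(idents.std())


def precision_recall(
    assignments: Mapping[str, str | None], truth_species: set[str]
) -> tuple[float, float]:
    """Species-level precision and recall.

    True positives are reads assigned to one of the community species;
    precision = TP / assigned reads, recall = TP / total reads.
    """
    if not assignments:
        raise ValueError("no reads")
    assigned = [s for s in assignments.values() if s is not None]
    if not assigned:
        raise ValueError("no read is assigned; precision is undefined")
    tp = sum(1 for s in assigned if s in truth_species)
    return tp / len(assigned), tp / len(assignments)


def length_summary(
    lengths: Sequence[int], population_sd: bool = True
) -> tuple[float, float]:
    """Mean and SD of read lengths (population SD by default)."""
    arr = np.asarray(lengths, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 reads for an SD")
    return float(arr.mean()), float(arr.std(ddof=0 if population_sd else 1))


def assignments_from_alignments(
    alignments: Sequence[AlignmentSummary],
    target_to_species: Mapping[str, str] | None = None,
) -> dict[str, str | None]:
    """Read -> species from best primary alignments.

    The species is the (mapped) target's label; unmapped reads are
    unassigned.  Ties between multiple primary records for one read are
    broken by first occurrence.
    """
    out: dict[str, str | None] = {}
    for a in alignments:
        if a.read_id in out:
            continue
        if not a.mapped:
            out[a.read_id] = None
        elif target_to_species is None:
            out[a.read_id] = a.target_id
        else:
            out[a.read_id] = target_to_species.get(a.target_id, a.target_id)
    return out


def length_histogram(
    lengths: Sequence[int], bin_width: int = 10
) -> list[tuple[int, int]]:
    """(bin start, count) pairs for plotting a read-length distribution."""
    arr = np.asarray(lengths)
    if arr.size == 0:
        return []
    top = int(arr.max()) + bin_width
    edges = np.arange(0, top + bin_width, bin_width)
    counts, _ = np.histogram(arr, bins=edges)
    return [(int(e), int(c)) for e, c in zip(edges[:-1], counts) if c]


def evaluate(
    sam: str | Path | Sequence[AlignmentSummary],
    truth: str | Path | Mapping[str, str],
    target_to_species: Mapping[str, str] | None = None,
) -> EvalMetrics:
    """Compute the full metric panel from an alignment and a truth table."""
    alignments = parse_sam(sam) if isinstance(sam, (str, Path)) else list(sam)
    truth_map = (
        read_truth_table(truth) if isinstance(truth, (str, Path)) else dict(truth)
    )
    truth_species = set(truth_map.values())
    assignments = assignments_from_alignments(alignments, target_to_species)
    prec, rec = precision_recall(assignments, truth_species)
    ident_mean, ident_sd = identity_stats(alignments)
    lengths = [a.read_length for a in alignments if a.mapped]
    length_mean, length_sd = length_summary(lengths)
    return EvalMetrics(
        error_rate=error_rate(alignments),
        pct_unmapped=pct_unmapped(alignments),
        identity_mean=ident_mean,
        identity_sd=ident_sd,
        precision=prec,
        recall=rec,
        length_mean=length_mean,
        length_sd=length_sd,
    )


def write_report(metrics: EvalMetrics, path: str | Path) -> None:
    """TSV metric report mirroring the standard evaluation-row layout."""
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for name, value in metrics.report_rows():
            fh.write(f"{name}\t{value:.4f}\n")
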