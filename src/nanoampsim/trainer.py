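"""Training an error model from real aligned data.

Given a SAM alignment of real reads against reference sequences, the trainer
estimates everything the simulator needs:

* the error-type split (pooled insertion/deletion/substitution fractions),
* the per-read identity histogram (1000 bins over [0, 100] by default),
* the exponentiated Weibull parameters of the per-read error rate, fitted
  by maximum likelihood to the sample reconstructed from the histogram, and
* the six length-category percentages from the read lengths (the second
  Gaussian share cannot be told apart from the long-deletion range by
  boundaries alone, so it is user-declared and subtracted from longDel).

``train_and_simulate`` chains training with the simulator to reproduce a
real run's error and length profile on synthetic community reads.
Simulated reads can also stand in for real ones without an aligner: their
edit logs give exact per-read error counts (``alignments_from_logs``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .error_model import ErrorTypeSplit, ExpWeibullParams, rates_to_profile, sample_error_rates
from .length_model import LengthParams, classify_length
from .pipeline import SimulatedRead, SimulationConfig, simulate_to_fastq
from .seqio import (
    AlignmentSummary,
    ProfileEntry,
    read_annotated_fastq,
    parse_sam,
    write_profile,
)

__all__ = [
    "IdentityHistogram",
    "TrainedModel",
    "error_type_split_from_sam",
    "identity_histogram",
    "fit_exp_weibull",
    "length_params_from_reads",
    "alignments_from_logs",
    "train",
    "train_and_simulate",
]


@dataclass
class IdentityHistogram:
    """Binned per-read percent identities over [0, 100]."""

    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.edges) != len(self.counts) + 1:
            raise ValueError("edges must have one more element than counts")
        if (self.counts < 0).any():
            raise ValueError("bin counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def n_reads(self) -> int:
        return int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def error_rate_sample(self) -> np.ndarray:
        """Per-read error rates (100 - identity) reconstructed at bin centers."""
        return np.repeat(100.0 - self.centers, self.counts)


@dataclass
class TrainedModel:
    split: ErrorTypeSplit
    ew: ExpWeibullParams
    length_params: LengthParams
    n_reads: int

    def log_lines(self) -> list[str]:
        return [
            f"n_reads = {self.n_reads}",
            f"split = ins:{self.split.p_ins:.4f} del:{self.split.p_del:.4f} "
            f"sub:{self.split.p_sub:.4f}",
            f"exp_weibull = a:{self.ew.a:.6g} c:{self.ew.c:.6g} "
            f"loc:{self.ew.loc:.6g} scale:{self.ew.scale:.6g}",
            f"exp_weibull_mean = {self.ew.mean:.4f}",
            f"length_params = {self.length_params}",
        ]


def error_type_split_from_sam(
    alignments: Iterable[AlignmentSummary],
) -> ErrorTypeSplit:
    """Pooled error-type fractions over all mapped primary alignments."""
    ins = dele = sub = 0
    any_mapped = False
    for a in alignments:
        if not a.mapped:
            continue
        any_mapped = True
        ins += a.n_ins
        dele += a.n_del
        sub += a.n_mismatch
    if not any_mapped:
        raise ValueError("no mapped alignments")
    total = ins + dele + sub
    if total == 0:
        raise ValueError("all alignments are error-free; cannot normalize a split")
    return ErrorTypeSplit(ins / total, dele / total, sub / total)


def identity_histogram(
    alignments: Iterable[AlignmentSummary], n_bins: int = 1000
) -> IdentityHistogram:
    """Histogram per-read identities of mapped alignments over [0, 100]."""
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    idents = [a.identity for a in alignments if a.mapped]
    if not idents:
        warnings.warn("no mapped alignments; identity histogram is empty", stacklevel=2)
    counts, edges = np.histogram(idents, bins=n_bins, range=(0.0, 100.0))
    return IdentityHistogram(edges, counts)


def fit_exp_weibull(hist: IdentityHistogram) -> ExpWeibullParams:
    """Maximum-likelihood exponentiated Weibull fit of the error-rate sample.

    The sample is reconstructed from the histogram as (100 - bin center)
    repeated per count (bias at most half a bin width).  ``loc`` is
    constrained to [0, min(sample)]; the fit must reproduce the sample mean
    within 5% or an error is raised.
    """
    if hist.n_reads < 100:
        raise ValueError(
            f"need at least 100 reads to fit the error-rate distribution, "
            f"got {hist.n_reads}"
        )
    sample = hist.error_rate_sample()
    m = float(sample.mean())
    lo = float(sample.min())
    if np.ptp(sample) < 1e-9:
        # Degenerate histogram: all mass in one bin.
        return ExpWeibullParams(1.0, 1.0, loc=max(lo - 1e-6, 0.0), scale=1e-6)

    candidates: list[ExpWeibullParams] = []
    failures: list[str] = []
    for kwargs in ({}, {"floc": 0.0}, {"floc": max(lo - 1e-6, 0.0)}):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                a, c, loc, scale = stats.exponweib.fit(sample, **kwargs)
            except Exception as exc:  # scipy raises several optimizer errors
                failures.append(f"{kwargs}: {exc}")
                continue
        if not (a > 0 and c > 0 and scale > 0 and 0.0 <= loc <= lo):
            failures.append(f"{kwargs}: out-of-bound params {(a, c, loc, scale)}")
            continue
        params = ExpWeibullParams(a, c, loc, scale)
        if abs(params.mean - m) <= 0.05 * max(m, 1e-12):
            candidates.append(params)
        else:
            failures.append(
                f"{kwargs}: fitted mean {params.mean:.4f} vs sample {m:.4f}"
            )
    if not candidates:
        raise RuntimeError(
            "exponentiated Weibull fit failed; attempts: " + "; ".join(failures)
        )
    return candidates[0]


def length_params_from_reads(
    lengths: Sequence[int], second_gauss_pct: int | None = None
) -> LengthParams:
    """Length-category percentages from observed read lengths.

    Reads are classified by the boundary rules (<200 veryShort, <1000 short,
    <1450 longDel, <=1600 gauss, else longRead); percentages are rounded to
    integers summing to 100 by largest remainder.  A user-declared second
    Gaussian share is moved out of the long-deletion bucket.
    """
    lengths = np.asarray(lengths)
    if lengths.size == 0:
        raise ValueError("need at least one read length")
    order = ("gauss", "longDel", "longRead", "short", "veryShort")
    counts = {name: 0 for name in order}
    for L in lengths:
        counts[classify_length(int(L))] += 1
    raw = np.array([counts[name] for name in order], dtype=float)
    raw = 100.0 * raw / raw.sum()
    ints = _largest_remainder(raw, 100)
    vec = dict(zip(order, ints))
    sg = 0
    if second_gauss_pct is not None:
        if second_gauss_pct > vec["longDel"]:
            raise ValueError(
                f"secondGauss share {second_gauss_pct} exceeds the computed "
                f"long-deletion share {vec['longDel']}"
            )
        vec["longDel"] -= second_gauss_pct
        sg = second_gauss_pct
    return LengthParams(
        gauss=vec["gauss"], longDel=vec["longDel"], longRead=vec["longRead"],
        short=vec["short"], veryShort=vec["veryShort"], secondGauss=sg,
    )


def _largest_remainder(values: np.ndarray, total: int) -> list[int]:
    floors = np.floor(values).astype(int)
    remainder = total - floors.sum()
    order = np.argsort(-(values - floors), kind="stable")
    for i in range(remainder):
        floors[order[i]] += 1
    return floors.tolist()


def alignments_from_logs(sim: Iterable[SimulatedRead]) -> list[AlignmentSummary]:
    """Exact alignment summaries from simulated reads' edit logs.

    The injected counts define the alignment: mismatches are the
    substitutions, matches the remaining aligned columns of the original
    template.  This bypasses an external aligner for round-trip training;
    random reads (no log) are treated as unmapped.
    """
    out = []
    for s in sim:
        if s.log is None:
            out.append(AlignmentSummary(read_id=s.record.id, mapped=False))
            continue
        n_ins, n_del, n_sub = s.annotation.n_ins, s.annotation.n_del, s.annotation.n_sub
        out.append(
            AlignmentSummary(
                read_id=s.record.id,
                mapped=True,
                target_id=s.annotation.source_taxon or "template",
                read_length=s.source_length + n_ins - n_del,
                n_match=s.source_length - n_del - n_sub,
                n_mismatch=n_sub,
                n_ins=n_ins,
                n_del=n_del,
            )
        )
    return out


def train(
    alignments: Sequence[AlignmentSummary],
    read_lengths: Sequence[int] | None = None,
    n_reads: int | None = None,
    second_gauss_pct: int | None = None,
    n_bins: int = 1000,
) -> TrainedModel:
    """Estimate split, error-rate distribution and length mixture."""
    split = error_type_split_from_sam(alignments)
    hist = identity_histogram(alignments, n_bins=n_bins)
    ew = fit_exp_weibull(hist)
    if read_lengths is None:
        read_lengths = [a.read_length for a in alignments if a.mapped]
    length_params = length_params_from_reads(read_lengths, second_gauss_pct)
    return TrainedModel(
        split=split, ew=ew, length_params=length_params,
        n_reads=n_reads if n_reads is not None else len(alignments),
    )


def train_and_simulate(
    real_sam: str | Path | Sequence[AlignmentSummary],
    error_free_fastq: str | Path,
    out_dir: str | Path,
    seed: int = 0,
    length_params_override: LengthParams | None = None,
    random_fraction: float = 0.0,
    quality: int = 8,
    second_gauss_pct: int | None = None,
) -> tuple[TrainedModel, list[SimulatedRead]]:
    """The full training pipeline: estimate the model from real aligned
    reads, write the per-read profile, then simulate.

    Writes ``profile.csv`` (one line per input read), ``simulated.fastq``
    and ``train.log`` into ``out_dir``.  Overrides replace the corresponding
    trained values (a manual length vector, the random-read
    fraction and output quality).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(real_sam, (str, Path)):
        alignments = parse_sam(real_sam)
    else:
        alignments = list(real_sam)
    reads = read_annotated_fastq(error_free_fastq)
    n = len(reads)

    model = train(alignments, n_reads=n, second_gauss_pct=second_gauss_pct)
    if length_params_override is not None:
        model.length_params = length_params_override

    # Independent substreams for rate drawing and read simulation.
    rate_seed, sim_seed = (
        int(s) for s in np.random.SeedSequence(seed).generate_state(2)
    )
    rates = sample_error_rates(n, model.ew, rate_seed)
    profile = rates_to_profile(rates, model.split)
    write_profile(profile, out_dir / "profile.csv")

    config = SimulationConfig(
        quality=quality,
        random_fraction=random_fraction,
        length_params=model.length_params,
        split=model.split,
        ew=model.ew,
        seed=sim_seed,
    )
    sim = simulate_to_fastq(
        reads, profile, out_dir / "simulated.fastq", config=config,
        log_path=out_dir / "train.log",
    )
    with open(out_dir / "train.log", "a") as fh:
        fh.write("\n".join(model.log_lines()) + "\n")
    return model, sim
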