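"""Read-length modelling.

Real nanopore 16S metabarcoding runs show a characteristic length profile:
a main Gaussian peak at the amplicon length (~1500 bp), a shoulder of reads
carrying one long internal deletion (1000-1450 bp), small fractions of short
(<1000 bp) and very short (<200 bp) fragments, a tail of overlong reads
(>1600 bp), and in some runs a second Gaussian peak near 1100 bp.  Each
simulated read is assigned to one of these six categories according to a
six-integer percentage vector, in the order

    (gauss, longDel, longRead, short, veryShort, secondGauss)

with default (67, 21, 1, 9, 2, 0), and its sequence is reshaped to a length
drawn from the category's law.  Fully random reads (uniform bases, lengths
through the same mixture) can be added on top to emulate noise reads.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .seqio import ReadAnnotation, SeqRecord

__all__ = [
    "LengthParams",
    "DEFAULT_LENGTH_PARAMS",
    "sample_category",
    "sample_categories",
    "draw_target_length",
    "apply_length",
    "generate_random_reads",
    "classify_length",
    "parse_length_vector",
]

logger = logging.getLogger(__name__)

_FIELD_ORDER = ("gauss", "longDel", "longRead", "short", "veryShort", "secondGauss")

# Category laws and boundaries.
GAUSS_MEAN, GAUSS_SD = 1500.0, 30.0
SECOND_GAUSS_MEAN, SECOND_GAUSS_SD = 1100.0, 30.0
VERY_SHORT_MIN, VERY_SHORT_MAX = 20, 199  # inclusive
SHORT_MIN, SHORT_MAX = 200, 999
LONG_READ_MIN = 1601
LONG_READ_SCALE = 200.0
LONG_DEL_OFFSET, LONG_DEL_SCALE = 50.0, 150.0
LONG_DEL_FINAL_LOW, LONG_DEL_FINAL_HIGH = 1000, 1450  # exclusive bounds


@dataclass(frozen=True)
class LengthParams:
    """Integer percentages of the six length categories (sum 100)."""

    gauss: int = 67
    longDel: int = 21
    longRead: int = 1
    short: int = 9
    veryShort: int = 2
    secondGauss: int = 0

    def __post_init__(self) -> None:
        vec = self.as_tuple()
        for name, v in zip(_FIELD_ORDER, vec):
            if not (isinstance(v, int) and 0 <= v <= 100):
                raise ValueError(f"{name} must be an integer in [0, 100], got {v!r}")
        if sum(vec) != 100:
            raise ValueError(f"length percentages must sum to 100, got {sum(vec)}")

    def as_tuple(self) -> tuple[int, int, int, int, int, int]:
        return (self.gauss, self.longDel, self.longRead,
                self.short, self.veryShort, self.secondGauss)

    def __str__(self) -> str:
        return "[" + ",".join(str(v) for v in self.as_tuple()) + "]"


DEFAULT_LENGTH_PARAMS = LengthParams()


def parse_length_vector(text: str) -> LengthParams:
    """Parse the bracketed six-integer form, e.g. ``[70,10,1,15,0,4]``."""
    cleaned = re.sub(r"[\[\]\s]", "", text)
    parts = cleaned.split(",")
    if len(parts) != 6:
        raise ValueError(
            f"length vector needs 6 comma-separated integers, got {text!r}"
        )
    return LengthParams(*(int(p) for p in parts))


def sample_categories(
    n: int, params: LengthParams, rng: np.random.Generator | int
) -> list[str]:
    """Draw ``n`` category labels from the mixture."""
    rng = np.random.default_rng(rng)
    probs = np.asarray(params.as_tuple(), dtype=float) / 100.0
    idx = rng.choice(6, size=n, p=probs)
    return [_FIELD_ORDER[i] for i in idx]


def sample_category(params: LengthParams, rng: np.random.Generator | int) -> str:
    return sample_categories(1, params, rng)[0]


def draw_target_length(
    category: str, rng: np.random.Generator, template_length: int = 1500
) -> int:
    """Draw a read length from a category's law.

    For ``longDel`` the law is defined relative to a template length (the
    deletion size is exponential); other categories are absolute.
    """
    if category == "gauss":
        while True:
            t = int(round(rng.normal(GAUSS_MEAN, GAUSS_SD)))
            if t >= 1:
                return t
    if category == "secondGauss":
        while True:
            t = int(round(rng.normal(SECOND_GAUSS_MEAN, SECOND_GAUSS_SD)))
            if t >= 1:
                return t
    if category == "veryShort":
        return int(rng.integers(VERY_SHORT_MIN, VERY_SHORT_MAX + 1))
    if category == "short":
        return int(rng.integers(SHORT_MIN, SHORT_MAX + 1))
    if category == "longRead":
        return LONG_READ_MIN + int(round(rng.exponential(LONG_READ_SCALE)))
    if category == "longDel":
        for _ in range(100):
            d = int(round(LONG_DEL_OFFSET + rng.exponential(LONG_DEL_SCALE)))
            t = template_length - d
            if LONG_DEL_FINAL_LOW < t < LONG_DEL_FINAL_HIGH:
                return t
        return template_length
    raise ValueError(f"unknown length category {category!r}")


def apply_length(
    record: SeqRecord,
    annotation: ReadAnnotation,
    category: str,
    rng: np.random.Generator | int,
    pad_strategy: str = "pad-random",
) -> tuple[SeqRecord, ReadAnnotation]:
    """Reshape a read to a length drawn from ``category``'s law.

    Categories other than ``longDel`` draw a target length T and either
    truncate the 3' end (early pore exit) or extend the read to T; the
    ``longDel`` category instead removes one contiguous internal block whose
    size is exponential, resampled until the final length lands in
    (1000, 1450).  The drawn category is recorded in the annotation.
    """
    rng = np.random.default_rng(rng)
    L = len(record.sequence)

    if category == "longDel":
        return _apply_long_deletion(record, annotation, rng)

    t = draw_target_length(category, rng, template_length=L)
    if t < L:
        seq = record.sequence[:t]
    elif t > L:
        seq = record.sequence + _extension(record.sequence, t - L, rng, pad_strategy)
    else:
        seq = record.sequence
    return (
        replace(record, sequence=seq),
        replace(annotation, category=category),
    )


def _apply_long_deletion(
    record: SeqRecord, annotation: ReadAnnotation, rng: np.random.Generator
) -> tuple[SeqRecord, ReadAnnotation]:
    L = len(record.sequence)
    if L <= LONG_DEL_FINAL_LOW:
        fallback = classify_length(L)
        logger.warning(
            "read %s (%d bp) too short for a long deletion; annotated as %s",
            record.id, L, fallback,
        )
        return record, replace(annotation, category=fallback)
    for _ in range(100):
        d = int(round(LONG_DEL_OFFSET + rng.exponential(LONG_DEL_SCALE)))
        final = L - d
        if LONG_DEL_FINAL_LOW < final < LONG_DEL_FINAL_HIGH:
            start = int(rng.integers(0, L - d + 1))
            seq = record.sequence[:start] + record.sequence[start + d:]
            return (
                replace(record, sequence=seq),
                replace(annotation, category="longDel"),
            )
    fallback = classify_length(L)
    logger.warning(
        "no feasible long-deletion size for read %s (%d bp); annotated as %s",
        record.id, L, fallback,
    )
    return record, replace(annotation, category=fallback)


def _extension(
    sequence: str, n: int, rng: np.random.Generator, strategy: str
) -> str:
    if strategy == "pad-random":
        return codes_to_str(rng.integers(0, 4, size=n))
    if strategy == "duplicate-tail":
        reps = -(-n // len(sequence))
        return (sequence * reps)[-n:]
    raise ValueError(f"unknown pad strategy {strategy!r}")


def codes_to_str(codes: np.ndarray) -> str:
    return np.frombuffer(b"ACGT", dtype=np.uint8)[
        np.asarray(codes, dtype=np.uint8)
    ].tobytes().decode("ascii")


def generate_random_reads(
    k: int,
    params: LengthParams,
    rng: np.random.Generator | int,
    id_prefix: str = "random",
) -> list[tuple[SeqRecord, ReadAnnotation]]:
    """``k`` fully random reads: uniform ACGT bases, lengths through the
    category mixture, annotated ``cat=random`` with zero error counts."""
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    rng = np.random.default_rng(rng)
    out = []
    categories = sample_categories(k, params, rng) if k else []
    for i, cat in enumerate(categories):
        t = draw_target_length(cat, rng)
        seq = codes_to_str(rng.integers(0, 4, size=t))
        rec = SeqRecord(id=f"{id_prefix}_{i}", sequence=seq)
        ann = ReadAnnotation(0, 0, 0, category="random")
        out.append((rec, ann))
    return out


def classify_length(length: int) -> str:
    """Category of a read length by the boundary rules (no secondGauss:
    that peak sits inside the long-deletion range and is user-declared)."""
    if length < 200:
        return "veryShort"
    if length < 1000:
        return "short"
    if length < 1450:
        return "longDel"
    if length <= 1600:
        return "gauss"
    return "longRead"
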