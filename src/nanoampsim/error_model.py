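"""Per-read error-rate model.

The per-read sequencing error rate (in percent of read length) is modelled
with a four-parameter exponentiated Weibull distribution,

    F(x) = [1 - exp(-((x - loc)/scale)^c)]^a        for x >= loc,

with two shape parameters ``a`` (often written alpha) and ``c`` (often
written kappa) plus location and scale.  This family captures the heavy,
skewed per-read error-rate distributions of nanopore metabarcoding runs
(typically 8-15% mean error) better than a plain Weibull.

A drawn rate r is split into insertion/deletion/substitution percentages by
a fixed error-type composition; the default split of 28% insertions, 42%
deletions and 30% substitutions reflects R9.4.1 flowcell 16S runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .seqio import ProfileEntry

__all__ = [
    "ExpWeibullParams",
    "ErrorTypeSplit",
    "DEFAULT_SPLIT",
    "exp_weibull_cdf",
    "exp_weibull_pdf",
    "sample_error_rates",
    "make_profile",
]


@dataclass(frozen=True)
class ExpWeibullParams:
    """Parameters of the exponentiated Weibull error-rate distribution.

    ``a`` and ``c`` are the two dimensionless shape parameters; ``loc`` and
    ``scale`` are in percent error rate.
    """

    a: float
    c: float
    loc: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.c > 0 and self.scale > 0):
            raise ValueError(
                f"shape and scale parameters must be positive: a={self.a}, "
                f"c={self.c}, scale={self.scale}"
            )
        if self.loc < 0:
            raise ValueError(f"loc must be >= 0, got {self.loc}")

    def frozen(self) -> stats.rv_continuous:
        """The corresponding frozen scipy distribution."""
        return stats.exponweib(self.a, self.c, loc=self.loc, scale=self.scale)

    @property
    def mean(self) -> float:
        return float(self.frozen().mean())


@dataclass(frozen=True)
class ErrorTypeSplit:
    """Fractions of total errors that are insertions, deletions, substitutions."""

    p_ins: float = 0.28
    p_del: float = 0.42
    p_sub: float = 0.30

    def __post_init__(self) -> None:
        for name in ("p_ins", "p_del", "p_sub"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(self.p_ins + self.p_del + self.p_sub - 1.0) > 1e-9:
            raise ValueError("error-type fractions must sum to 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_ins, self.p_del, self.p_sub)


DEFAULT_SPLIT = ErrorTypeSplit()


def exp_weibull_cdf(x, params: ExpWeibullParams):
    """CDF of the error-rate distribution; 0 below ``loc``."""
    return params.frozen().cdf(x)


def exp_weibull_pdf(x, params: ExpWeibullParams):
    return params.frozen().pdf(x)


def sample_error_rates(
    n: int, params: ExpWeibullParams, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw ``n`` i.i.d. per-read error rates (percent), clipped to [0, 100].

    Draws are taken by inverse-CDF on uniform variates so the stream is
    reproducible given the generator state.  Clipping (rather than rejection)
    keeps the draw count exact when a fitted distribution puts small mass
    outside the physical range.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(rng)
    u = rng.uniform(size=n)
    rates = params.frozen().ppf(u)
    return np.clip(rates, 0.0, 100.0)


def make_profile(
    n: int,
    params: ExpWeibullParams,
    split: ErrorTypeSplit = DEFAULT_SPLIT,
    rng: np.random.Generator | int = 0,
) -> list[ProfileEntry]:
    """Generate the per-read profile: one (ins%, del%, sub%) entry per read.

    Entry i is the i-th drawn rate multiplied by the split fractions, so each
    entry's percentages sum exactly to its drawn rate.
    """
    rates = sample_error_rates(n, params, rng)
    return rates_to_profile(rates, split)


def rates_to_profile(
    rates: Sequence[float], split: ErrorTypeSplit = DEFAULT_SPLIT
) -> list[ProfileEntry]:
    return [
        ProfileEntry(r * split.p_ins, r * split.p_del, r * split.p_sub)
        for r in np.asarray(rates, dtype=float)
    ]
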