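"""Synthetic reference communities and error-free amplicon reads.

Stands in for a community amplicon simulator: builds a set of full-length
16S-like marker references (one per taxon, ~1500 bp, mutually divergent so
species stay distinguishable) and draws error-free reads from an abundance
profile with no length bias, no copy bias and no truncation — each read is
the full, unmutated reference sequence of its taxon.  The default profile is
an eight-species mock community.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .length_model import codes_to_str
from .seqio import ReadAnnotation, SeqRecord

__all__ = [
    "AbundanceProfile",
    "MOCK8_ABUNDANCES",
    "generate_references",
    "generate_amplicons",
]

#: Eight-species mock-community simulation abundances (lot V2-style mixture).
MOCK8_ABUNDANCES: dict[str, float] = {
    "Lactobacillus_fermentum": 0.10,
    "Listeria_monocytogenes": 0.13,
    "Bacillus_subtilis": 0.18,
    "Staphylococcus_aureus": 0.18,
    "Salmonella_enterica": 0.15,
    "Enterococcus_faecalis": 0.08,
    "Escherichia_coli": 0.16,
    "Pseudomonas_aeruginosa": 0.02,
}


@dataclass(frozen=True)
class AbundanceProfile:
    """Relative abundance fractions per taxon (sum to 1)."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.fractions:
            raise ValueError("abundance profile must not be empty")
        vals = np.asarray(list(self.fractions.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("abundance fractions must be >= 0")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"abundance fractions must sum to 1, got {vals.sum():.12g}"
            )

    @property
    def taxa(self) -> list[str]:
        return list(self.fractions)

    def as_arrays(self) -> tuple[list[str], np.ndarray]:
        taxa = self.taxa
        return taxa, np.asarray([self.fractions[t] for t in taxa], dtype=float)


def generate_references(
    n_taxa: int,
    length: int = 1500,
    divergence: float = 0.05,
    rng: np.random.Generator | int = 0,
    max_identity: float = 0.97,
    taxon_ids: Sequence[str] | None = None,
) -> list[SeqRecord]:
    """One synthetic marker sequence per taxon.

    A random ancestor is mutated independently per taxon at the given
    per-site substitution fraction.  Regenerated (up to 100 attempts) until
    every pair of references is below the identity ceiling.
    """
    if n_taxa < 1:
        raise ValueError(f"n_taxa must be >= 1, got {n_taxa}")
    if not 0.0 < divergence < 0.5:
        raise ValueError(f"divergence must be in (0, 0.5), got {divergence}")
    if taxon_ids is None:
        taxon_ids = [f"taxon{i + 1}" for i in range(n_taxa)]
    elif len(taxon_ids) != n_taxa:
        raise ValueError("taxon_ids length must equal n_taxa")
    rng = np.random.default_rng(rng)

    for _ in range(100):
        ancestor = rng.integers(0, 4, size=length).astype(np.uint8)
        seqs = []
        for _t in range(n_taxa):
            mutant = ancestor.copy()
            hit = rng.uniform(size=length) < divergence
            # substitute to one of the other three bases
            mutant[hit] = (mutant[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
            seqs.append(mutant)
        if n_taxa == 1 or _max_pairwise_identity(seqs) < max_identity:
            return [
                SeqRecord(id=tid, sequence=codes_to_str(s))
                for tid, s in zip(taxon_ids, seqs)
            ]
    raise RuntimeError(
        f"could not generate {n_taxa} references below {max_identity:.0%} "
        f"pairwise identity at divergence {divergence} after 100 attempts"
    )


def _max_pairwise_identity(seqs: list[np.ndarray]) -> float:
    best = 0.0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            ident = float(np.mean(seqs[i] == seqs[j]))
            best = max(best, ident)
    return best


def generate_amplicons(
    references: Sequence[SeqRecord],
    abundances: AbundanceProfile | Mapping[str, float],
    n_reads: int,
    rng: np.random.Generator | int = 0,
    id_prefix: str = "read",
) -> list[tuple[SeqRecord, ReadAnnotation]]:
    """Draw error-free full-length amplicon reads from the profile.

    Taxa are sampled i.i.d. from the abundance fractions; each read is an
    exact copy of its taxon's reference with zero error counts and the
    source taxon recorded.
    """
    if n_reads <= 0:
        raise ValueError(f"n_reads must be > 0, got {n_reads}")
    if not isinstance(abundances, AbundanceProfile):
        abundances = AbundanceProfile(abundances)
    by_id = {rec.id: rec for rec in references}
    missing = set(abundances.taxa) - by_id.keys()
    if missing:
        raise ValueError(f"abundance taxa missing from references: {sorted(missing)}")
    rng = np.random.default_rng(rng)
    taxa, probs = abundances.as_arrays()
    draws = rng.choice(len(taxa), size=n_reads, p=probs)
    out = []
    for i, t in enumerate(draws):
        taxon = taxa[t]
        ref = by_id[taxon]
        rec = SeqRecord(id=f"{id_prefix}_{i}", sequence=ref.sequence)
        ann = ReadAnnotation(0, 0, 0, category="gauss", source_taxon=taxon)
        out.append((rec, ann))
    return out
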