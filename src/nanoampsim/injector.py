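"""Sequencing-error injection with homopolymer-biased indels.

Nanopore basecalling miscounts homopolymer lengths, so indels concentrate in
long runs of identical bases.  The injector reproduces this: indel events are
placed one at a time, each event choosing a homopolymer run with probability
proportional to its *current* length (runs shrink and grow as events land), a
deletion removing one base of the chosen run and an insertion duplicating the
run's base.  Substitutions are then drawn uniformly over distinct positions
of the post-indel sequence and replaced by one of the other three bases.

Every injection returns an :class:`ErrorLog` whose replay on the source
sequence reproduces the output exactly, which makes simulated reads usable
as alignment ground truth without running an aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from .seqio import ReadAnnotation, SeqRecord, ProfileEntry

__all__ = [
    "HomopolymerRun",
    "EditOp",
    "ErrorLog",
    "find_homopolymers",
    "inject_errors",
    "replay_log",
    "verify_edit_counts",
]

_BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def seq_to_codes(sequence: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = sequence[int(np.argmax(codes == 255))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


class HomopolymerRun(NamedTuple):
    """A maximal run of one repeated base: [start, start+length)."""

    start: int
    length: int
    base: str


def find_homopolymers(sequence: str) -> list[HomopolymerRun]:
    """Decompose a sequence into its maximal homopolymer runs.

    The runs tile the sequence left to right without gaps or overlap.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    codes = seq_to_codes(sequence)
    starts, lengths, bases = _run_structure(codes)
    return [
        HomopolymerRun(int(s), int(l), _BASES[b])
        for s, l, b in zip(starts, lengths, bases)
    ]


def _run_structure(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(run starts, run lengths, run base codes) of a code array."""
    boundaries = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(codes)]))
    return starts, ends - starts, codes[starts]


@dataclass(frozen=True)
class EditOp:
    """One edit applied to the evolving sequence.

    ``position`` refers to the sequence as it stands when the op is applied:
    ins inserts ``base`` before ``position``, del removes the base at
    ``position``, sub replaces it with ``base``.
    """

    kind: str  # 'ins' | 'del' | 'sub'
    position: int
    base: str = ""


@dataclass
class ErrorLog:
    """Ordered edit script; replaying it on the source gives the output."""

    ops: list[EditOp]

    def tallies(self) -> tuple[int, int, int]:
        kinds = [op.kind for op in self.ops]
        return kinds.count("ins"), kinds.count("del"), kinds.count("sub")


def replay_log(source: str, log: ErrorLog) -> str:
    seq = list(source)
    for op in log.ops:
        if op.kind == "ins":
            seq.insert(op.position, op.base)
        elif op.kind == "del":
            del seq[op.position]
        elif op.kind == "sub":
            seq[op.position] = op.base
        else:
            raise ValueError(f"unknown edit kind {op.kind!r}")
    return "".join(seq)


def verify_edit_counts(source: str, output: str, log: ErrorLog,
                       annotation: ReadAnnotation | None = None) -> bool:
    """True iff the log replays source -> output and (optionally) its
    per-kind tallies match the annotation counts."""
    try:
        replayed = replay_log(source, log)
    except (IndexError, ValueError):
        return False
    if replayed != output:
        return False
    if annotation is not None:
        if log.tallies() != (annotation.n_ins, annotation.n_del, annotation.n_sub):
            return False
    return True


def target_counts(length: int, entry: ProfileEntry) -> tuple[int, int, int]:
    """Deterministic error counts for a read: round(L * pct / 100) per kind."""
    return (
        int(np.floor(length * entry.ins_pct / 100.0 + 0.5)),
        int(np.floor(length * entry.del_pct / 100.0 + 0.5)),
        int(np.floor(length * entry.sub_pct / 100.0 + 0.5)),
    )


def inject_errors(
    record: SeqRecord,
    entry: ProfileEntry,
    rng: np.random.Generator | int,
    run_weight_exponent: float = 1.0,
) -> tuple[SeqRecord, ReadAnnotation, ErrorLog]:
    """Introduce the profile-prescribed errors into an error-free read.

    Target counts are ``round(L * pct / 100)`` per kind.  Indels are placed
    first (insertions and deletions interleaved in random order), each event
    selecting a homopolymer run with probability proportional to its current
    length raised to ``run_weight_exponent``; substitutions follow at
    distinct uniform positions of the post-indel sequence.
    """
    rng = np.random.default_rng(rng)
    codes = seq_to_codes(record.sequence)
    L = len(codes)
    k_ins, k_del, k_sub = target_counts(L, entry)
    if k_del >= L:
        raise ValueError(
            f"read {record.id!r}: {k_del} deletions would erase the whole "
            f"{L}-base read"
        )

    starts, lengths, run_bases = _run_structure(codes)
    lengths = lengths.astype(np.int64).copy()
    n_runs = len(lengths)
    d_per_run = np.zeros(n_runs, dtype=np.int64)
    i_per_run = np.zeros(n_runs, dtype=np.int64)

    n_events = k_ins + k_del
    if n_events:
        if run_weight_exponent == 1.0:
            _place_indels_linear(
                rng, lengths, d_per_run, i_per_run, k_ins, k_del
            )
        else:
            _place_indels_weighted(
                rng, lengths, d_per_run, i_per_run, k_ins, k_del,
                run_weight_exponent,
            )

    # Final sequence from net run lengths (all bases within a run are equal,
    # so only the net counts matter for the sequence itself).
    out_codes = np.repeat(run_bases, lengths)

    # Substitutions at distinct uniform positions, each to one of the other
    # three bases.
    L_post = len(out_codes)
    if k_sub > L_post:
        raise ValueError(
            f"read {record.id!r}: cannot place {k_sub} substitutions in a "
            f"{L_post}-base read"
        )
    if k_sub:
        sub_pos = rng.choice(L_post, size=k_sub, replace=False)
        sub_pos.sort()
        offsets = rng.integers(1, 4, size=k_sub).astype(np.uint8)
        new_codes = (out_codes[sub_pos] + offsets) % 4
        out_codes[sub_pos] = new_codes
    else:
        sub_pos = np.empty(0, dtype=np.int64)
        new_codes = np.empty(0, dtype=np.uint8)

    log = _build_log(starts, run_bases, d_per_run, i_per_run, sub_pos, new_codes)

    out = replace(record, sequence=codes_to_seq(out_codes), quality=None)
    ann = ReadAnnotation(
        n_ins=k_ins, n_del=k_del, n_sub=k_sub,
        category="gauss", source_taxon="",
    )
    return out, ann, log


def _place_indels_linear(
    rng: np.random.Generator,
    lengths: np.ndarray,
    d_per_run: np.ndarray,
    i_per_run: np.ndarray,
    k_ins: int,
    k_del: int,
) -> None:
    """Length-proportional run selection via a multiset of per-base run ids.

    Choosing a current base uniformly at random and taking its run is exactly
    length-proportional selection; the bag of run ids supports O(1) insert
    and swap-remove, so each event is constant time.
    """
    bag = np.repeat(np.arange(len(lengths)), lengths).tolist()
    events = np.concatenate(
        (np.zeros(k_del, dtype=np.int8), np.ones(k_ins, dtype=np.int8))
    )
    rng.shuffle(events)
    picks = rng.uniform(size=len(events))
    for ev, u in zip(events, picks):
        idx = int(u * len(bag))
        run = bag[idx]
        if ev:  # insertion duplicates the run base
            lengths[run] += 1
            i_per_run[run] += 1
            bag.append(run)
        else:  # deletion removes one base of the run
            lengths[run] -= 1
            d_per_run[run] += 1
            bag[idx] = bag[-1]
            bag.pop()


def _place_indels_weighted(
    rng: np.random.Generator,
    lengths: np.ndarray,
    d_per_run: np.ndarray,
    i_per_run: np.ndarray,
    k_ins: int,
    k_del: int,
    exponent: float,
) -> None:
    """General run selection with weight = length**exponent (recomputed)."""
    events = np.concatenate(
        (np.zeros(k_del, dtype=np.int8), np.ones(k_ins, dtype=np.int8))
    )
    rng.shuffle(events)
    for ev in events:
        weights = np.where(lengths > 0, lengths.astype(float) ** exponent, 0.0)
        cum = np.cumsum(weights)
        run = int(np.searchsorted(cum, rng.uniform() * cum[-1], side="right"))
        run = min(run, len(lengths) - 1)
        if ev:
            lengths[run] += 1
            i_per_run[run] += 1
        else:
            lengths[run] -= 1
            d_per_run[run] += 1


def _build_log(
    starts: np.ndarray,
    run_bases: np.ndarray,
    d_per_run: np.ndarray,
    i_per_run: np.ndarray,
    sub_pos: np.ndarray,
    new_codes: np.ndarray,
) -> ErrorLog:
    """Sequential edit script equivalent to the net per-run indel counts.

    Runs are emitted right to left so that each run's original start offset
    is still valid in the evolving sequence when its ops are applied; the
    substitutions (post-indel coordinates) follow.
    """
    ops: list[EditOp] = []
    touched = np.flatnonzero((d_per_run > 0) | (i_per_run > 0))
    for r in touched[::-1]:
        start = int(starts[r])
        base = _BASES[run_bases[r]]
        # Insertions before deletions: interleaved events can delete more
        # bases than the run originally had, so grow the segment first.
        ops.extend(EditOp("ins", start, base) for _ in range(int(i_per_run[r])))
        ops.extend(EditOp("del", start) for _ in range(int(d_per_run[r])))
    ops.extend(
        EditOp("sub", int(p), _BASES[c]) for p, c in zip(sub_pos, new_codes)
    )
    return ErrorLog(ops)
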