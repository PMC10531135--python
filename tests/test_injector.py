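"""Error injection: homopolymer decomposition, count realization, edit-log
replay, placement biases."""

import edlib
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanoampsim.injector import (
    find_homopolymers,
    inject_errors,
    replay_log,
    verify_edit_counts,
)
from nanoampsim.seqio import ProfileEntry, SeqRecord

sequences = st.text(alphabet="ACGT", min_size=1, max_size=200)


class TestFindHomopolymers:
    def test_maximal_runs(self):
        runs = find_homopolymers("AAACCG")
        assert [(r.start, r.length, r.base) for r in runs] == [
            (0, 3, "A"), (3, 2, "C"), (5, 1, "G"),
        ]

    def test_no_repeats_gives_unit_runs(self):
        assert [r.length for r in find_homopolymers("ACGT")] == [1, 1, 1, 1]

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError, match="N"):
            find_homopolymers("ACNGT")

    @given(sequences)
    @settings(max_examples=200, deadline=None)
    def test_runs_tile_the_sequence(self, seq):
        runs = find_homopolymers(seq)
        assert sum(r.length for r in runs) == len(seq)
        pos = 0
        for r in runs:
            assert r.start == pos
            assert seq[r.start : r.start + r.length] == r.base * r.length
            pos += r.length


class TestInjectErrors:
    def test_zero_entry_is_identity(self):
        rec = SeqRecord("r", "ACGTACGTAAACCC")
        out, ann, log = inject_errors(rec, ProfileEntry(0, 0, 0), 0)
        assert out.sequence == rec.sequence
        assert (ann.n_ins, ann.n_del, ann.n_sub) == (0, 0, 0)
        assert log.ops == []

    def test_forced_deletion_in_single_run(self):
        rec = SeqRecord("r", "AAAAAA")
        out, ann, _ = inject_errors(rec, ProfileEntry(0, 100 / 6, 0), 0)
        assert out.sequence == "AAAAA"
        assert ann.n_del == 1

    def test_count_rounding(self, rng):
        # 10% rate at the default split on a 1000-base read
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        out, ann, _ = inject_errors(SeqRecord("r", seq), ProfileEntry(2.8, 4.2, 3.0), 1)
        assert (ann.n_ins, ann.n_del, ann.n_sub) == (28, 42, 30)

    def test_whole_read_deletion_rejected(self):
        with pytest.raises(ValueError, match="erase"):
            inject_errors(SeqRecord("r", "ACGT"), ProfileEntry(0, 100, 0), 0)

    def test_length_accounting_and_replay(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        rec = SeqRecord("r", seq)
        for seed in range(20):
            out, ann, log = inject_errors(rec, ProfileEntry(3.0, 4.0, 3.0), seed)
            assert len(out.sequence) == 300 + ann.n_ins - ann.n_del
            assert verify_edit_counts(seq, out.sequence, log, ann)

    def test_tampered_output_detected(self):
        rec = SeqRecord("r", "ACGTACGTACGTACGTACGT")
        out, ann, log = inject_errors(rec, ProfileEntry(5, 5, 5), 3)
        assert not verify_edit_counts(rec.sequence, out.sequence + "A", log, ann)

    def test_empty_log_identity(self):
        from nanoampsim.injector import ErrorLog

        assert verify_edit_counts("ACGT", "ACGT", ErrorLog(ops=[]))

    def test_levenshtein_bounded_by_edit_counts(self, rng):
        # dynamic-programming distance (edlib) never exceeds the edit budget
        for i in range(100):
            L = int(rng.integers(20, 200))
            seq = "".join(rng.choice(list("ACGT"), size=L))
            entry = ProfileEntry(*(float(rng.uniform(0, 6)) for _ in range(3)))
            out, ann, _ = inject_errors(SeqRecord("r", seq), entry, int(rng.integers(2**31)))
            dist = edlib.align(seq, out.sequence, task="distance")["editDistance"]
            assert dist <= ann.n_ins + ann.n_del + ann.n_sub


class TestPlacementBiases:
    def test_single_deletion_is_length_proportional(self):
        # runs of length 5,1,1,1: the A-run should receive ~5/8 of deletions
        rec = SeqRecord("r", "AAAAACGT")
        entry = ProfileEntry(0, 12.5, 0)  # round(8 * 0.125) = 1 deletion
        n = 10_000
        hits = 0
        for seed in range(n):
            out, _, _ = inject_errors(rec, entry, seed)
            if out.sequence == "AAAACGT":
                hits += 1
        p = 5 / 8
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 4 * se

    def test_indel_incidence_monotone_in_run_length(self):
        # template with runs of lengths 1..5; one deletion per injection
        template = "A" + "CC" + "GGG" + "TTTT" + "AAAAA"
        rec = SeqRecord("r", template)
        entry = ProfileEntry(0, 100 / len(template), 0)
        counts = np.zeros(5, dtype=int)
        run_of = np.repeat(np.arange(5), [1, 2, 3, 4, 5])
        for seed in range(10_000):
            _, _, log = inject_errors(rec, entry, seed)
            (op,) = log.ops
            counts[run_of[op.position]] += 1
        assert (np.diff(counts) > 0).all()

    def test_insertion_duplicates_run_base(self):
        rec = SeqRecord("r", "AAAAAAAAAA")
        out, ann, _ = inject_errors(rec, ProfileEntry(10, 0, 0), 5)
        assert ann.n_ins == 1
        assert out.sequence == "A" * 11

    def test_substitution_positions_uniform(self):
        # homopolymer-free template, one substitution per injection
        template = "ACGT" * 5
        rec = SeqRecord("r", template)
        entry = ProfileEntry(0, 0, 5.0)  # round(20 * 0.05) = 1
        counts = np.zeros(len(template), dtype=int)
        for seed in range(10_000):
            _, _, log = inject_errors(rec, entry, seed)
            (op,) = log.ops
            assert op.kind == "sub"
            assert op.base != template[op.position]
            counts[op.position] += 1
        from scipy import stats

        _, pval = stats.chisquare(counts)
        assert pval > 0.001

    def test_substitutions_at_distinct_positions(self):
        rec = SeqRecord("r", "ACGT" * 25)
        out, ann, log = inject_errors(rec, ProfileEntry(0, 0, 20), 9)
        sub_positions = [op.position for op in log.ops if op.kind == "sub"]
        assert len(sub_positions) == len(set(sub_positions)) == ann.n_sub == 20


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=50, deadline=None)
def test_replay_identity_randomized(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 150))))
    entry = ProfileEntry(*(float(rng.uniform(0, 8)) for _ in range(3)))
    out, ann, log = inject_errors(SeqRecord("r", seq), entry, rng)
    assert replay_log(seq, log) == out.sequence
    assert log.tallies() == (ann.n_ins, ann.n_del, ann.n_sub)
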