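"""Model training: split estimation, identity histograms, exp-Weibull fit,
length-category percentages, and the train-then-simulate pipeline."""

import numpy as np
import pytest

from nanoampsim import (
    ExpWeibullParams,
    LengthParams,
    MOCK8_ABUNDANCES,
    exp_weibull_cdf,
    generate_amplicons,
    simulate_reads,
    write_fastq,
)
from nanoampsim.error_model import ErrorTypeSplit, make_profile
from nanoampsim.seqio import AlignmentSummary, read_annotated_fastq, read_profile
from nanoampsim.trainer import (
    IdentityHistogram,
    alignments_from_logs,
    error_type_split_from_sam,
    fit_exp_weibull,
    identity_histogram,
    length_params_from_reads,
    train_and_simulate,
)


def _aln(ins=0, dele=0, mm=0, match=100, read_id="r"):
    return AlignmentSummary(
        read_id=read_id, mapped=True, target_id="t",
        read_length=match + mm + ins,
        n_match=match, n_mismatch=mm, n_ins=ins, n_del=dele,
    )


class TestSplitEstimation:
    def test_single_alignment_default_provenance(self):
        split = error_type_split_from_sam([_aln(ins=28, dele=42, mm=30)])
        assert split.as_tuple() == pytest.approx((0.28, 0.42, 0.30))

    def test_error_free_input_rejected(self):
        with pytest.raises(ValueError, match="error-free"):
            error_type_split_from_sam([_aln()])

    def test_pooling(self):
        split = error_type_split_from_sam([_aln(ins=1), _aln(dele=1)])
        assert split.as_tuple() == pytest.approx((0.5, 0.5, 0.0))

    def test_unmapped_excluded(self):
        alns = [_aln(ins=1), AlignmentSummary(read_id="u", mapped=False)]
        assert error_type_split_from_sam(alns).p_ins == 1.0


class TestIdentityHistogram:
    def test_perfect_read_in_last_bin(self):
        hist = identity_histogram([_aln(match=100)], n_bins=1000)
        assert hist.counts[-1] == 1
        assert hist.n_reads == 1

    def test_identity_formula(self):
        a = _aln(match=90, mm=4, ins=3, dele=3)
        assert a.identity == pytest.approx(90.0)

    def test_count_conservation(self):
        alns = [_aln(match=90 + i, mm=i % 7) for i in range(50)]
        alns.append(AlignmentSummary(read_id="u", mapped=False))
        hist = identity_histogram(alns)
        assert hist.n_reads == 50

    def test_unmapped_only_warns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            hist = identity_histogram([AlignmentSummary(read_id="u", mapped=False)])
        assert hist.n_reads == 0


class TestFitExpWeibull:
    @staticmethod
    def _hist_from_rates(rates, n_bins=1000):
        counts, edges = np.histogram(100.0 - np.asarray(rates), bins=n_bins,
                                     range=(0.0, 100.0))
        return IdentityHistogram(edges, counts)

    def test_degenerate_histogram_preserves_mean(self):
        hist = self._hist_from_rates(np.full(500, 12.0))
        params = fit_exp_weibull(hist)
        assert params.mean == pytest.approx(12.0, abs=0.1)

    def test_refit_of_own_resample_is_stable(self):
        from nanoampsim.error_model import sample_error_rates

        rng = np.random.default_rng(11)
        first = fit_exp_weibull(
            self._hist_from_rates(
                sample_error_rates(30_000, ExpWeibullParams(2, 1.5, 5, 8), rng)
            )
        )
        second = fit_exp_weibull(
            self._hist_from_rates(sample_error_rates(30_000, first, rng))
        )
        assert second.mean == pytest.approx(first.mean, rel=0.05)

    def test_too_few_reads_rejected(self):
        with pytest.raises(ValueError, match="100"):
            fit_exp_weibull(self._hist_from_rates(np.full(50, 10.0)))


class TestLengthParamsFromReads:
    def test_all_gauss(self):
        assert length_params_from_reads([1500] * 10).as_tuple() == (100, 0, 0, 0, 0, 0)

    def test_one_read_per_category(self):
        lp = length_params_from_reads([100, 500, 1200, 1500, 1700])
        assert lp.as_tuple() == (20, 20, 20, 20, 20, 0)

    def test_largest_remainder_sums_to_100(self):
        lp = length_params_from_reads([1500, 1500, 1200, 500, 100, 1700, 1500])
        assert sum(lp.as_tuple()) == 100

    def test_second_gauss_subtracted_from_long_del(self):
        lp = length_params_from_reads([1100] * 50 + [1500] * 50, second_gauss_pct=30)
        assert lp.secondGauss == 30
        assert lp.longDel == 20
        assert lp.gauss == 50

    def test_second_gauss_exceeding_long_del_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            length_params_from_reads([1500] * 10, second_gauss_pct=5)


class TestTrainAndSimulate:
    def test_round_trip_and_conservation(self, mock_refs, tmp_path):
        n = 4000
        reads = generate_amplicons(mock_refs, MOCK8_ABUNDANCES, n, 5)
        split = ErrorTypeSplit(0.35, 0.40, 0.25)
        ew = ExpWeibullParams(2.0, 1.5, 4.0, 5.0)
        profile = make_profile(n, ew, split, 6)
        sim = simulate_reads(reads, profile, LengthParams(95, 5, 0, 0, 0, 0), rng=7)
        alns = alignments_from_logs(sim)

        fastq = tmp_path / "amplicons.fastq"
        write_fastq(reads, fastq)
        out = tmp_path / "trained"
        model, sim2 = train_and_simulate(
            alns, fastq, out, seed=8,
            length_params_override=LengthParams(95, 5, 0, 0, 0, 0),
        )
        # recovered split close to the generating one
        for got, want in zip(model.split.as_tuple(), split.as_tuple()):
            assert abs(got - want) < 0.03
        # profile file has one line per input read
        assert len(read_profile(out / "profile.csv")) == n
        # override propagates: only gauss/longDel categories in the output
        cats = {ann.category for _, ann in read_annotated_fastq(out / "simulated.fastq")}
        assert cats <= {"gauss", "longDel"}
        assert len(sim2) == n

    def test_parameter_log_written(self, mock_refs, tmp_path):
        n = 500
        reads = generate_amplicons(mock_refs, MOCK8_ABUNDANCES, n, 5)
        profile = make_profile(n, ExpWeibullParams(2, 1.5, 4, 5), rng=6)
        sim = simulate_reads(reads, profile, rng=7)
        alns = alignments_from_logs(sim)
        fastq = tmp_path / "a.fastq"
        write_fastq(reads, fastq)
        train_and_simulate(alns, fastq, tmp_path / "t", seed=9)
        log = (tmp_path / "t" / "train.log").read_text()
        for key in ("split", "exp_weibull", "length_params", "quality", "seed"):
            assert key in log
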