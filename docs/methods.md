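# Methods

## Scope and model

`nanoampsim` simulates ONT metabarcoding long reads in three stages —
per-read error budgeting, error injection, length shaping — and provides the
inverse path (training the stage parameters from real aligned reads) plus
the fidelity metrics used to compare simulated and real runs.

### Per-read error rate

The error rate of read *i*, `r_i`, in percent of read length, is an i.i.d.
draw from an exponentiated Weibull distribution,
`F(x) = [1 − exp(−((x−loc)/scale)^c)]^a` for `x ≥ loc`. This family adds a
second shape parameter to the Weibull and accommodates both the sharp peaks
of well-behaved runs and the heavy left-shoulders of noisy ones. Sampling is
by inverse CDF on uniform variates (`scipy.stats.exponweib.ppf`), so a
fixed generator seed fixes the draw sequence. Draws are clipped to
[0, 100] rather than resampled: a fitted distribution may place small mass
outside the physical range, and clipping keeps the draw count exact.

The drawn rate is split deterministically into type percentages,
`(r_i·p_ins, r_i·p_del, r_i·p_sub)`, written as one line of the profile
file. The default split (0.28, 0.42, 0.30) reflects R9.4.1/FLO-MIN106 16S
sequencing; deletions dominate because homopolymer truncation is the main
ONT failure mode.

### Error injection

Target counts per read are `round(L·pct/100)` per error type
(deterministic, round-half-up), so a profile maps reproducibly to counts;
sub-0.5 remainders are dropped rather than dithered. Indels are placed
first, insertions and deletions interleaved in random order. Each event
selects a homopolymer run with probability proportional to its current
length (configurable exponent, default 1 — the weakest bias consistent with
"indels concentrate in longer homopolymers"); a deletion removes one base
of the run, an insertion duplicates the run's base (the classic nanopore
homopolymer miscount). Run weights are updated after every event.
Substitutions are then placed at `k_sub` distinct positions drawn uniformly
over the post-indel sequence, each replaced by one of the other three bases
uniformly; substitutions may hit inserted bases.

Implementation note: run selection uses a multiset of per-base run ids
(uniform choice of a base ≡ length-proportional choice of its run), giving
O(1) per event. Because every base in a run is identical, the output
sequence depends only on each run's net indel counts; the edit log is
emitted as an equivalent right-to-left per-run script (insertions before
deletions within a run) followed by the substitutions in post-indel
coordinates. Replaying the log on the source reproduces the output exactly,
which the test suite exploits as an aligner-free ground truth.

Degenerate inputs: a profile demanding `k_del ≥ L` (read would vanish) or
`k_sub` above the post-indel length is an error, not a silent clamp.

### Length shaping

Each read draws one of six categories from the integer-percentage vector
`(gauss, longDel, longRead, short, veryShort, secondGauss)`; the annotated
category is the drawn one, so category bookkeeping is exact even when a
drawn Gaussian length falls outside its nominal range. Laws:

| category    | law                                   | default share |
|-------------|---------------------------------------|---------------|
| gauss       | length ~ round(N(1500, 30))           | 67 |
| longDel     | one internal block of `round(50 + Exp(150))` bases removed at a uniform start, resampled (≤100 tries) until the final length is in (1000, 1450) | 21 |
| longRead    | 1601 + round(Exp(200))                | 1 |
| short       | Uniform{200..999}                     | 9 |
| veryShort   | Uniform{20..199}                      | 2 |
| secondGauss | length ~ round(N(1100, 30))           | 0 (user-declared) |

Gaussian draws are *not* truncated to the descriptive [1450, 1600] range:
truncation would shrink the realized SD (~24 instead of 30 at ±1.67σ) and
the printed moments (1500/30, 1100/30) are the contract. For categories
other than longDel, a shorter target truncates the 3' end (early pore
exit); a longer target appends bases, by default i.i.d. uniform ACGT
(`pad-random`; `duplicate-tail` is available). The longDel exponential
scale (150, offset 50) is a package choice — no canonical value exists —
placing typical final lengths mid-range (~1300 bp). The veryShort floor of
20 bp avoids zero-length reads that break SAM conventions. A read too short
to host a long deletion (≤1000 bp) keeps its sequence and is re-annotated
by its length with a logged warning.

Random reads (`-r`, percent of n; count `⌈r·n⌉`) are uniform ACGT with
lengths drawn through the same mixture and `cat=random`, zero error counts.

### Training

From the mapped primary records of a SAM file (secondary/supplementary
skipped, clipped bases excluded): insertions/deletions from CIGAR I/D,
mismatches from `NM − I − D`, cross-checked against MD when present (MD
wins, with a warning count). The split is pooled over reads, not averaged
per read, so long reads weigh more. Identities
`100·match/(match+mismatch+ins+del)` are binned into 1000 bins over
[0, 100]; the error-rate sample is reconstructed as `100 − bin center`
repeated per count (bias ≤ half a bin width, 0.05 at 1000 bins) and fitted
by `scipy.stats.exponweib.fit` (MLE). The fit must return parameters with
`loc ∈ [0, min(sample)]` and reproduce the sample mean within 5%;
otherwise it is retried with `loc` fixed at 0 and at just below the sample
minimum, and finally fails loudly with diagnostics. A single-bin
(degenerate) histogram returns a near-degenerate law preserving the mean.
Length percentages come from the boundary classification (<200, <1000,
<1450, ≤1600, >1600) with largest-remainder rounding to a sum of exactly
100; the secondGauss share cannot be distinguished from the longDel range
by boundaries, so it is user-declared and subtracted from longDel.

Training does not require an aligner for simulated data: the injector's
edit logs yield exact per-read counts (`alignments_from_logs`), defining
the alignment as match = L − del − sub, mismatch = sub. Note that the
alignment-derived error rate `(i+d+s)/(L+i)` is deterministically slightly
below the injected percentage of L (the denominator includes insertions):
about 0.3 points at a 10% mean rate. Retrained error-rate means are
therefore expected to sit marginally below the generating mean.

### Evaluation

Pooled error rate `100·Σ(mm+i+d)/Σ(match+mm+i+d)` over mapped primary
records; % unmapped over primary records; identity mean and population SD
(per-read identity is the complement of the per-read error rate by
construction); species-level precision TP/assigned and recall TP/total with
TP = reads assigned to a community species (assignment = label of the best
primary alignment target, ties by first occurrence). Precision ≥ recall
always, since assigned ⊆ total.

## Synthetic data

The fixture generator emulates a community amplicon simulator run with
length-bias, copy-bias and truncation disabled: references are one ancestor
(uniform random, 1500 bp) independently mutated per taxon at 5% per site
(pairwise identity kept below 97% so taxa are distinguishable), and each
error-free read is the *full, unmutated* reference of a taxon drawn i.i.d.
from the abundance profile. The default profile is an eight-species mock
community with abundances between 0.02 and 0.18. What this does not
emulate: real 16S conserved/variable-region structure, primer and PCR
artifacts, chimeras, copy-number variation, or basecaller-specific error
context. Tests passing on these fixtures demonstrate the simulator's
internal contracts (counts, laws, round-trips), not that real 16S data are
perfectly described by the model.

## Verification sizes and known limitations

The acceptance checks run at the sizes the constants are stated for: 10^5
reads for the error-type shares and the default category mixture, 5·10^4
for the Gaussian length moments and the training round trip. The round-trip
check uses a generating mixture (40, 25, 5, 10, 5, 15) that exercises all
six categories. A known estimator bias constrains such checks at high Gauss
shares: since the Gauss law is untruncated, ~4.8% of its mass falls below
the 1450 bp boundary and is classified as longDel on retraining — ~3.2
points of apparent transfer at the default 67% share, under 2 points at
shares ≤40%. This is a property of boundary classification against
overlapping laws, not an implementation defect; training on real data
carries the same ambiguity.

Other limitations: no context-dependent (k-mer) error model; a single fixed
FASTQ quality value (default phred 8) rather than per-base qualities; no
strand asymmetry; the profile-to-count realization drops sub-0.5
remainders, so very low rates on short reads under-realize slightly.
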