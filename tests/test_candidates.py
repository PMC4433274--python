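import numpy as np
import pytest

from mirpipe.candidates import (
    PAIR_WEIGHTS,
    assess_hairpin,
    discover_candidates,
    fold_nussinov,
)
from mirpipe.errors import ValidationError
from mirpipe.io_core import GenomicInterval, PipelineConfig, ReadRecord, \
    reverse_complement
from mirpipe.preprocess import ClassifiedRead

from .oracles import brute_force_best_fold

rng = np.random.default_rng(42)
BASES = list("ACGU")


def random_rna(n, r=rng):
    return "".join(r.choice(BASES, n))


class TestFold:
    def test_perfect_gc_stem(self):
        fold = fold_nussinov("GGGAAACCC", min_loop=3)
        assert fold.pairing == [(0, 8), (1, 7), (2, 6)]
        assert fold.n_pairs == 3
        assert fold.energy_score == -9

    def test_unpairable_sequence(self):
        fold = fold_nussinov("AAAAAA")
        assert fold.n_pairs == 0 and fold.energy_score == 0

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            fold_nussinov("ACGU")

    def test_matches_exhaustive_oracle_on_short_sequences(self):
        r = np.random.default_rng(0)
        for _ in range(200):
            seq = random_rna(int(r.integers(5, 15)), r)
            fold = fold_nussinov(seq)
            assert -fold.energy_score == brute_force_best_fold(seq)

    def test_structures_are_valid(self):
        r = np.random.default_rng(1)
        for _ in range(50):
            seq = random_rna(int(r.integers(10, 40)), r)
            fold = fold_nussinov(seq)
            used = set()
            for i, j in fold.pairing:
                assert (seq[i], seq[j]) in PAIR_WEIGHTS
                assert j - i > 3  # loop constraint
                assert i not in used and j not in used
                used |= {i, j}
            for (i1, j1), (i2, j2) in zip(fold.pairing, fold.pairing[1:]):
                assert not (i1 < i2 < j1 < j2)  # no crossings

    def test_deterministic_traceback(self):
        seq = random_rna(30, np.random.default_rng(5))
        assert fold_nussinov(seq).pairing == fold_nussinov(seq).pairing


def perfect_hairpin(arm_len=22, loop_len=8, seed=8):
    r = np.random.default_rng(seed)
    arm = random_rna(arm_len, r)
    loop = random_rna(loop_len, r)
    return arm, arm + loop + reverse_complement(arm)


class TestHairpinAssessment:
    def test_constructed_stem_loop_passes_on_5p_arm(self):
        arm, precursor = perfect_hairpin()
        fold = assess_hairpin(precursor, arm)
        assert fold.is_hairpin and fold.mature_arm == "5p"
        assert fold.mature_paired_fraction >= 0.6

    def test_mature_on_3p_arm(self):
        arm, precursor = perfect_hairpin()
        fold = assess_hairpin(precursor, reverse_complement(arm))
        assert fold.is_hairpin and fold.mature_arm == "3p"

    def test_mature_spanning_the_loop_fails(self):
        arm, precursor = perfect_hairpin()
        spanning = precursor[14:40]  # crosses the terminal loop
        fold = assess_hairpin(precursor, spanning)
        assert not fold.is_hairpin

    def test_mature_absent_rejected(self):
        _, precursor = perfect_hairpin()
        with pytest.raises(ValidationError):
            assess_hairpin(precursor, "UUUUUUUUUU")

    def test_shuffled_precursors_mostly_fail(self):
        arm, precursor = perfect_hairpin()
        r = np.random.default_rng(10)
        fails = 0
        n = 100
        for _ in range(n):
            letters = list(precursor)
            r.shuffle(letters)
            shuffled = "".join(letters)
            mature = shuffled[15:37]
            if shuffled.count(mature) != 1:
                fails += 1
                continue
            if not assess_hairpin(shuffled, mature).is_hairpin:
                fails += 1
        assert fails >= 90


def make_locus_reads(genome_seq, chrom, start, counts, length=22):
    """Classified unannotated reads stacked on one genomic window."""
    reads = []
    for k, count in enumerate(counts):
        s = start + k * 2
        seq = genome_seq[s:s + length]
        reads.append(ClassifiedRead(
            ReadRecord(f"r{start}-{k}", seq, count), "unannotated",
            genome_hits=[GenomicInterval(chrom, s, s + length)],
        ))
    return reads


class TestDiscovery:
    @pytest.fixture()
    def hairpin_genome(self):
        # construct until the excision window (flanks included) passes the
        # hairpin check, as the synthetic generator guarantees
        r = np.random.default_rng(21)
        for _ in range(50):
            arm = random_rna(22, r)
            precursor = arm + random_rna(8, r) + reverse_complement(arm)
            left = random_rna(300, r)
            right = random_rna(300, r)
            genome = {"chr1": left + precursor + right}
            window = genome["chr1"][len(left) - 20:len(left) + 22 + 50]
            if assess_hairpin(window, arm).is_hairpin:
                return genome, arm, len(left)
        raise AssertionError("could not construct a recoverable hairpin")

    def test_planted_hairpin_with_enough_reads_is_retained(self, hairpin_genome):
        genome, arm, start = hairpin_genome
        reads = [ClassifiedRead(
            ReadRecord("r1", arm, 12), "unannotated",
            genome_hits=[GenomicInterval("chr1", start, start + 22)])]
        cands = discover_candidates(reads, genome)
        assert len(cands) == 1
        assert cands[0].mature_sequence == arm
        assert cands[0].candidate_id == "seq-1_x12"
        assert cands[0].hairpin.is_hairpin

    def test_count_filter_boundary(self, hairpin_genome):
        genome, arm, start = hairpin_genome
        for count, kept in ((9, 0), (10, 1)):
            reads = [ClassifiedRead(
                ReadRecord("r1", arm, count), "unannotated",
                genome_hits=[GenomicInterval("chr1", start, start + 22)])]
            assert len(discover_candidates(reads, genome)) == kept

    def test_non_folding_locus_rejected_despite_high_count(self):
        r = np.random.default_rng(33)
        # shuffled composition, no designed stem
        seq = random_rna(660, r)
        genome = {"chr1": seq}
        read_seq = seq[310:332]
        reads = [ClassifiedRead(
            ReadRecord("r1", read_seq, 50), "unannotated",
            genome_hits=[GenomicInterval("chr1", 310, 332)])]
        assert discover_candidates(reads, genome) == []

    def test_retention_monotone_in_count(self, hairpin_genome):
        genome, arm, start = hairpin_genome
        base = [ClassifiedRead(
            ReadRecord("r1", arm, 15), "unannotated",
            genome_hits=[GenomicInterval("chr1", start, start + 22)])]
        extra = base + [ClassifiedRead(
            ReadRecord("r2", genome["chr1"][start + 4:start + 24], 3),
            "unannotated",
            genome_hits=[GenomicInterval("chr1", start + 4, start + 24)])]
        kept_base = discover_candidates(base, genome)
        kept_extra = discover_candidates(extra, genome)
        assert len(kept_base) == 1 and len(kept_extra) == 1
        assert kept_extra[0].total_count > kept_base[0].total_count
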