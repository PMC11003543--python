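import numpy as np
import pytest

from _oracles import confusion_oracle, mcc_oracle
from conftest import dna, mutate
from tecurator.benchmark import (
    classification_agreement,
    confusion,
    consensus_length_band,
    fragmentation_ratio,
    mcc,
    random_annotations,
)
from tecurator.seqio import Annotation, ConsensusRecord


def ann(start, end, family="f", classification="LINE/L1", contig="ctg_0", strand="+"):
    return Annotation(contig, start, end, strand, family, classification)


class TestConfusion:
    def test_worked_example(self):
        counts = confusion([ann(10, 30)], [ann(20, 40)], 100)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (10, 10, 10, 70)

    def test_identical_sets(self):
        counts = confusion([ann(10, 30)], [ann(10, 30)], 100)
        assert counts.fp == counts.fn == 0

    def test_empty_test(self):
        counts = confusion([ann(10, 30)], [], 100)
        assert (counts.tp, counts.fp, counts.fn) == (0, 0, 20)

    def test_counts_conserve_genome_length(self):
        rng = np.random.default_rng(1)
        ref = [ann(int(s), int(s) + 50) for s in rng.integers(0, 9_000, 20)]
        test = [ann(int(s), int(s) + 70) for s in rng.integers(0, 9_000, 15)]
        counts = confusion(ref, test, 10_000)
        assert counts.total == 10_000

    def test_against_per_base_oracle(self):
        rng = np.random.default_rng(2)
        ref = [ann(int(s), int(s) + int(l)) for s, l in zip(rng.integers(0, 900, 12), rng.integers(1, 80, 12))]
        test = [ann(int(s), int(s) + int(l)) for s, l in zip(rng.integers(0, 900, 9), rng.integers(1, 80, 9))]
        counts = confusion(ref, test, 1000)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == confusion_oracle(ref, test, 1000)


class TestMcc:
    def test_known_value(self):
        from tecurator.benchmark import ConfusionCounts

        assert mcc(ConfusionCounts(90, 10, 10, 900)) == pytest.approx(0.8890, abs=1e-4)
        assert mcc(ConfusionCounts(90, 10, 10, 900)) == pytest.approx(
            mcc_oracle(90, 10, 10, 900)
        )

    def test_perfect_is_plus_one(self):
        counts = confusion([ann(10, 40)], [ann(10, 40)], 100)
        assert mcc(counts) == pytest.approx(1.0)

    def test_complement_is_minus_one(self):
        counts = confusion([ann(10, 40)], [ann(0, 10), ann(40, 100)], 100)
        assert mcc(counts) == pytest.approx(-1.0)

    def test_zero_denominator_convention(self):
        from tecurator.benchmark import ConfusionCounts

        assert mcc(ConfusionCounts(0, 0, 0, 100)) == 0.0

    def test_random_null_near_zero(self):
        # coverage-matched random annotations over 50 replicates
        rng = np.random.default_rng(7)
        starts = np.sort(rng.choice(np.arange(0, 99_000, 600), 30, replace=False))
        ref = [ann(int(s), int(s) + 500) for s in starts]
        values = []
        for seed in range(1, 51):
            test = random_annotations(ref, 100_000, seed=seed)
            values.append(mcc(confusion(ref, test, 100_000)))
        assert abs(float(np.mean(values))) < 0.05


class TestClassificationAgreement:
    def test_identical_copy_correct(self):
        counts = classification_agreement([ann(0, 100)], [ann(0, 100)])
        assert (counts.correct, counts.misclassified, counts.missing) == (1, 0, 0)

    def test_wrong_class_misclassified(self):
        counts = classification_agreement(
            [ann(0, 100, classification="DNA/Tc1")],
            [ann(0, 100, classification="LINE/L1")],
        )
        assert counts.misclassified == 1

    def test_subfamily_difference_still_correct(self):
        counts = classification_agreement(
            [ann(0, 100, classification="LINE/L1")],
            [ann(0, 100, classification="LINE/R2")],
        )
        assert counts.correct == 1

    def test_no_overlap_missing(self):
        counts = classification_agreement([ann(0, 100)], [ann(5000, 5100)])
        assert counts.missing == 1

    def test_below_half_coverage_missing(self):
        counts = classification_agreement([ann(0, 100)], [ann(0, 40)])
        assert counts.missing == 1

    def test_totals_conserved(self):
        ref = [ann(i * 1000, i * 1000 + 200) for i in range(10)]
        test = [ann(0, 150), ann(1000, 1200, classification="DNA/Tc1")]
        counts = classification_agreement(ref, test)
        assert counts.total == 10


class TestFragmentationRatio:
    def test_identical_sets_ratio_one(self):
        base = [ann(i * 1000, i * 1000 + 300) for i in range(5)]
        ratios = fragmentation_ratio(base, base)
        assert ratios["all"] == pytest.approx(1.0)
        assert ratios["LINE"] == pytest.approx(1.0)

    def test_three_way_split_ratio_three(self):
        base = [ann(0, 300), ann(1000, 1300)]
        split = [
            ann(0, 100), ann(100, 200), ann(200, 300),
            ann(1000, 1100), ann(1100, 1200), ann(1200, 1300),
        ]
        assert fragmentation_ratio(base, split)["all"] == pytest.approx(3.0)

    def test_unoverlapped_baseline_excluded(self):
        base = [ann(0, 300), ann(10_000, 10_300)]
        other = [ann(0, 300)]
        assert fragmentation_ratio(base, other)["all"] == pytest.approx(1.0)


class TestConsensusLengthBand:
    def test_percent_arithmetic(self):
        seq = dna(1000, seed=1)
        real = [ConsensusRecord("real1", "x", seq)]
        test = [ConsensusRecord("test1", "x", seq[:950])]
        summary = consensus_length_band(test, real)
        assert summary.entries[0].percent_of_real == pytest.approx(95.0)
        assert summary.in_band_fraction == 1.0

    def test_identical_libraries_fully_in_band(self):
        lib = [ConsensusRecord(f"r{i}", "x", dna(500, seed=i)) for i in range(3)]
        summary = consensus_length_band(lib, lib)
        assert summary.in_band_fraction == 1.0

    def test_half_length_out_of_band(self):
        seq = dna(1000, seed=2)
        summary = consensus_length_band(
            [ConsensusRecord("t", "x", seq[:500])], [ConsensusRecord("r", "x", seq)]
        )
        assert summary.entries[0].percent_of_real == pytest.approx(50.0)
        assert summary.in_band_fraction == 0.0

    def test_best_scoring_pairing(self):
        real_a, real_b = dna(800, seed=3), dna(800, seed=4)
        test = [ConsensusRecord("t", "x", mutate(real_b, 0.05, seed=5))]
        real = [ConsensusRecord("a", "x", real_a), ConsensusRecord("b", "x", real_b)]
        summary = consensus_length_band(test, real)
        assert summary.entries[0].real_id == "b"

    def test_unpaired_reported(self):
        summary = consensus_length_band(
            [ConsensusRecord("t", "x", dna(300, seed=6))],
            [ConsensusRecord("r", "x", dna(300, seed=7))],
        )
        assert summary.entries[0].real_id is None
        assert summary.entries[0].percent_of_real is None
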