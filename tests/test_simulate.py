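import numpy as np
import pytest

from conftest import dna
from tecurator.search import pairwise_align, revcomp
from tecurator.simulate import (
    COPY_NUMBER_MAX,
    COPY_NUMBER_MIN,
    FamilyConfig,
    SimConfig,
    mutate_copy,
    sample_copy_numbers,
    simulate_genome,
    write_reference_gff,
)
from tecurator.seqio import read_annotations


def _family(name="fam1", length=800, seed=1, **kwargs):
    defaults = dict(
        classification="LINE/L1",
        sequence=dna(length, seed=seed),
        copy_number=10,
        divergence_max=0.10,
        fragmented_fraction=0.0,
        nested_fraction=0.0,
    )
    defaults.update(kwargs)
    return FamilyConfig(name=name, **defaults)


class TestRandomGenome:
    def test_gc_content_within_one_percent_at_100kb(self):
        genome, insertions = simulate_genome(SimConfig(genome_length=100_000, gc=0.42, seed=3))
        assert insertions == []
        seq = genome.contigs["ctg_0"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.42) < 0.01

    def test_extreme_gc_targets(self):
        for gc in (0.21, 0.58):
            genome, _ = simulate_genome(SimConfig(genome_length=100_000, gc=gc, seed=5))
            seq = genome.contigs["ctg_0"]
            observed = (seq.count("G") + seq.count("C")) / len(seq)
            assert abs(observed - gc) < 0.01


class TestSampleCopyNumbers:
    def test_clamped_to_paper_range(self):
        draws = sample_copy_numbers(10_000, seed=1)
        assert min(draws) >= COPY_NUMBER_MIN
        assert max(draws) <= COPY_NUMBER_MAX

    def test_deterministic(self):
        assert sample_copy_numbers(50, seed=9) == sample_copy_numbers(50, seed=9)

    def test_distribution_tracks_normal_oracle(self):
        draws = np.array(sample_copy_numbers(10_000, seed=2))
        oracle = np.clip(
            np.rint(np.random.default_rng(123).normal(150, 120, 10_000)),
            COPY_NUMBER_MIN,
            COPY_NUMBER_MAX,
        )
        assert abs(draws.mean() - oracle.mean()) < 10
        # interior mass dominates the clamp points
        interior = ((draws > COPY_NUMBER_MIN) & (draws < COPY_NUMBER_MAX)).mean()
        assert interior > 0.75


class TestMutateCopy:
    def test_zero_divergence_identity(self):
        seq = dna(500, seed=7)
        out, realized = mutate_copy(seq, 0.0, seed=1)
        assert out == seq
        assert realized == 0.0

    def test_realized_divergence_concentrates(self):
        seq = dna(10_000, seed=8)
        out, realized = mutate_copy(seq, 0.10, seed=2)
        assert 0.08 <= realized <= 0.12
        observed = sum(1 for a, b in zip(seq, out) if a != b) / len(seq)
        assert observed == pytest.approx(realized)

    def test_transition_transversion_ratio_near_two(self):
        seq = dna(60_000, seed=9)
        out, _ = mutate_copy(seq, 0.2, seed=3)
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        ts = tv = 0
        for a, b in zip(seq, out):
            if a == b:
                continue
            if (a, b) in transitions:
                ts += 1
            else:
                tv += 1
        assert ts / tv == pytest.approx(2.0, rel=0.15)

    def test_excessive_divergence_rejected(self):
        with pytest.raises(ValueError):
            mutate_copy("ACGT", 0.6, seed=1)


class TestSimulateGenome:
    def test_copy_count_conservation(self):
        config = SimConfig(
            genome_length=200_000,
            gc=0.5,
            families=[_family("a", copy_number=5), _family("b", seed=2, copy_number=7)],
            seed=11,
        )
        _, insertions = simulate_genome(config)
        assert len(insertions) == 12

    def test_genome_length_is_base_plus_insertions(self):
        config = SimConfig(
            genome_length=150_000, gc=0.45, families=[_family(copy_number=20)], seed=13
        )
        genome, insertions = simulate_genome(config)
        inserted = sum(i.end - i.start for i in insertions)
        assert genome.total_length == 150_000 + inserted

    def test_recorded_spans_align_to_source(self):
        fam = _family(copy_number=15, divergence_max=0.20)
        config = SimConfig(genome_length=200_000, gc=0.5, families=[fam], seed=17)
        genome, insertions = simulate_genome(config)
        seq = genome.contigs["ctg_0"]
        for ins in insertions:
            copy = seq[ins.start : ins.end]
            if ins.strand == "-":
                copy = revcomp(copy)
            identity = sum(1 for a, b in zip(copy, fam.sequence) if a == b) / len(copy)
            assert identity == pytest.approx(1 - ins.divergence, abs=0.02)

    def test_mean_realized_divergence(self):
        fam = _family(copy_number=200, length=600, divergence_max=0.20)
        config = SimConfig(genome_length=2_000_000, gc=0.5, families=[fam], seed=1)
        _, insertions = simulate_genome(config)
        mean_div = np.mean([i.divergence for i in insertions])
        assert 0.08 <= mean_div <= 0.12  # uniform(0, 0.2) has mean 0.10

    def test_fragmentation_produces_truncated_copies(self):
        fam = _family(copy_number=40, fragmented_fraction=0.5)
        config = SimConfig(genome_length=400_000, gc=0.5, families=[fam], seed=19)
        _, insertions = simulate_genome(config)
        fragmented = [i for i in insertions if i.fragmented]
        intact = [i for i in insertions if not i.fragmented]
        assert fragmented and intact
        full = len(fam.sequence)
        assert all(i.end - i.start < full for i in fragmented)
        assert all(i.end - i.start == full for i in intact)

    def test_nested_insertions_inside_hosts(self):
        fam = _family(copy_number=20, nested_fraction=0.3, length=1000)
        config = SimConfig(genome_length=300_000, gc=0.5, families=[fam], seed=23)
        _, insertions = simulate_genome(config)
        nested = [i for i in insertions if i.nested]
        assert len(nested) == 6  # round(0.3 * 20)
        by_id = {i.insertion_id: i for i in insertions}
        for child in nested:
            assert child.parent_id in by_id
            host = by_id[child.parent_id]
            assert host.start <= child.start and child.end <= host.end

    def test_same_seed_byte_identical(self, tmp_path):
        config = SimConfig(
            genome_length=80_000,
            gc=0.42,
            families=[_family(copy_number=8, fragmented_fraction=0.3, nested_fraction=0.2)],
            seed=29,
        )
        g1, i1 = simulate_genome(config)
        g2, i2 = simulate_genome(config)
        assert g1.contigs == g2.contigs
        write_reference_gff(i1, tmp_path / "a.gff3")
        write_reference_gff(i2, tmp_path / "b.gff3")
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_reference_gff_readable(self, tmp_path):
        config = SimConfig(
            genome_length=50_000, gc=0.5, families=[_family(copy_number=5)], seed=31
        )
        _, insertions = simulate_genome(config)
        path = tmp_path / "ref.gff3"
        write_reference_gff(insertions, path)
        back = read_annotations(path, "gff3")
        assert len(back) == len(insertions)
        assert [(a.start, a.end) for a in back] == [(i.start, i.end) for i in insertions]

    def test_infeasible_packing_rejected(self):
        fam = _family(copy_number=732, length=5000)
        with pytest.raises(ValueError, match="genome_length"):
            simulate_genome(SimConfig(genome_length=1000, gc=0.5, families=[fam], seed=1))

    def test_bad_gc_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(genome_length=100, gc=1.5)
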