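import random

import pytest

from conftest import dna, mutate, plant_copies
from tecurator.beat import (
    BeatParams,
    Extract,
    Verdict,
    assess_iteration,
    beat_curate,
    build_consensus,
    extend_flanks,
    select_candidates,
    trim_to_mutual_support,
    validate_extended,
)
from tecurator.search import SearchHit, local_support_spans, pairwise_align
from tecurator.seqio import ConsensusRecord, ConsensusStatus, GenomeAssembly


def _hit(score, identity=0.9, coverage=0.8, start=0, end=500):
    return SearchHit(
        query_id="q",
        contig="ctg_0",
        q_start=0,
        q_end=end - start,
        s_start=start,
        s_end=end,
        strand="+",
        identity=identity,
        query_coverage=coverage,
        score=score,
    )


class TestSelectCandidates:
    def test_top_twenty_by_score(self):
        hits = [_hit(score=s) for s in range(25, 0, -1)]
        random.Random(0).shuffle(hits)
        out = select_candidates(hits, BeatParams())
        assert len(out) == 20
        assert [h.score for h in out] == sorted(range(6, 26), reverse=True)

    def test_low_identity_excluded_regardless_of_score(self):
        hits = [_hit(score=9999, identity=0.65)] + [_hit(score=s) for s in range(10)]
        out = select_candidates(hits, BeatParams())
        assert all(h.identity > 0.70 for h in out)

    def test_identity_exactly_seventy_percent_excluded(self):
        out = select_candidates([_hit(score=10, identity=0.70)], BeatParams())
        assert out == []

    def test_coverage_exactly_fifty_percent_excluded(self):
        out = select_candidates([_hit(score=10, coverage=0.50)], BeatParams())
        assert out == []

    def test_two_passing_hits_signals_low_copy(self):
        out = select_candidates([_hit(score=10), _hit(score=9)], BeatParams())
        assert len(out) < BeatParams().min_matches


class TestExtendFlanks:
    def test_flank_arithmetic(self):
        genome = GenomeAssembly(contigs={"ctg_0": dna(20_000, seed=1)})
        (ext,) = extend_flanks(genome, [_hit(10, start=5000, end=5500)], flank=1000)
        assert len(ext.sequence) == 2500
        assert ext.sequence == genome.contigs["ctg_0"][4000:6500]
        assert (ext.core_start, ext.core_end) == (1000, 1500)

    def test_left_clamp(self):
        genome = GenomeAssembly(contigs={"ctg_0": dna(20_000, seed=1)})
        (ext,) = extend_flanks(genome, [_hit(10, start=50, end=550)], flank=1000)
        assert ext.sequence == genome.contigs["ctg_0"][0:1550]
        assert (ext.core_start, ext.core_end) == (50, 550)

    def test_minus_strand_is_reverse_complement_of_plus_extract(self):
        from tecurator.search import revcomp

        genome = GenomeAssembly(contigs={"ctg_0": dna(20_000, seed=1)})
        plus_hit = _hit(10, start=5000, end=5500)
        minus_hit = _hit(10, start=5000, end=5500)
        minus_hit.strand = "-"
        (plus_ext,) = extend_flanks(genome, [plus_hit], flank=1000)
        (minus_ext,) = extend_flanks(genome, [minus_hit], flank=1000)
        assert minus_ext.sequence == revcomp(plus_ext.sequence)
        assert (minus_ext.core_start, minus_ext.core_end) == (1000, 1500)


class TestValidateExtended:
    def test_true_copy_retained_and_noise_discarded(self):
        consensus = dna(800, seed=30)
        true_extract = Extract(dna(300, seed=31) + mutate(consensus, 0.05, 32) + dna(300, seed=33), 300, 1100)
        noise = Extract(dna(1400, seed=34), 300, 1100)
        kept = validate_extended([true_extract, noise], consensus, BeatParams())
        assert kept == [true_extract]


class TestTrimToMutualSupport:
    def test_identical_extracts_untouched(self):
        seq = dna(1500, seed=40)
        extracts = [Extract(seq, 500, 1000) for _ in range(3)]
        out = trim_to_mutual_support(extracts, BeatParams())
        assert all(e.sequence == seq for e in out)

    def test_unique_host_flank_removed(self):
        te = dna(1000, seed=41)
        shared_left, shared_right = dna(200, seed=42), dna(200, seed=43)
        core = shared_left + te + shared_right
        unique = dna(1000, seed=44)
        extracts = [
            Extract(unique + core, len(unique) + 200, len(unique) + 200 + len(te)),
            Extract(core, 200, 200 + len(te)),
            Extract(core, 200, 200 + len(te)),
        ]
        out = trim_to_mutual_support(extracts, BeatParams())
        # the 1 kb unique host flank has no pairwise support anywhere
        assert len(out[0].sequence) <= len(core) + 50
        for a, b in [(0, 1), (0, 2)]:
            spans = local_support_spans(out[a].sequence, extracts[b].sequence)
            covered = set()
            for lo, hi in spans:
                covered.update(range(lo, hi))
            # trimmed sequence is (almost) fully supported
            assert len(covered) >= 0.9 * len(out[a].sequence)

    def test_single_sequence_returned_with_warning(self):
        extracts = [Extract(dna(100, seed=45), 0, 100)]
        assert trim_to_mutual_support(extracts, BeatParams()) == extracts


class TestBuildConsensus:
    def test_unanimous_rows(self):
        seqs = ["ACGTACGTACGTACGTACGT"] * 3
        assert build_consensus(seqs, seqs[0]) == seqs[0]

    def test_majority_vote_per_column(self):
        base = dna(60, seed=50)
        variant = base[:30] + ("A" if base[30] != "A" else "C") + base[31:]
        out = build_consensus([base, base, variant], base)
        assert out == base  # 2:1 majority at the variant column

    def test_private_insertion_columns_removed(self):
        base = dna(80, seed=51)
        with_ins = base[:40] + "AAAAA" + base[40:]
        out = build_consensus([with_ins, base, base], base)
        assert out == base

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            build_consensus(["ACGT" * 10], "ACGT" * 10)


class TestAssessIteration:
    def test_growth_below_half_flank_is_done(self):
        prev = dna(2000, seed=60)
        new = prev + dna(400, seed=61)
        decision = assess_iteration(new, prev, BeatParams(flank=1000))
        assert decision.verdict == Verdict.DONE

    def test_growth_above_half_flank_continues(self):
        prev = dna(2000, seed=62)
        new = prev + dna(600, seed=63)
        decision = assess_iteration(new, prev, BeatParams(flank=1000))
        assert decision.verdict == Verdict.CONTINUE

    def test_shorter_reverts(self):
        prev = dna(2000, seed=64)
        decision = assess_iteration(prev[:1500], prev, BeatParams())
        assert decision.verdict == Verdict.REVERT

    def test_low_coverage_of_previous_reverts(self):
        prev = dna(2000, seed=65)
        # same length but only ~half of prev present
        new = prev[:1000] + dna(1100, seed=66)
        decision = assess_iteration(new, prev, BeatParams())
        assert decision.verdict == Verdict.REVERT


class TestBeatCurate:
    def test_recovers_full_length_from_fragment(self):
        te = dna(2500, seed=70)
        base = dna(150_000, seed=71)
        genome, _ = plant_copies(base, te, 12, seed=72, max_divergence=0.08)
        record = ConsensusRecord("fam", "LINE/L1", te[800:1700])
        out = beat_curate(record, genome)
        assert out.status == ConsensusStatus.CURATED
        assert 0.95 * len(te) <= len(out.sequence) <= 1.05 * len(te)
        assert out.iterations_run <= BeatParams().max_iterations
        aln = pairwise_align(record.sequence, out.sequence)
        assert aln.identity > 0.70

    def test_two_copies_low_copy_unchanged(self):
        te = dna(1200, seed=73)
        base = dna(60_000, seed=74)
        genome, _ = plant_copies(base, te, 2, seed=75, max_divergence=0.02)
        record = ConsensusRecord("fam", "DNA/hAT", te)
        out = beat_curate(record, genome)
        assert out.status == ConsensusStatus.LOW_COPY
        assert out.sequence == te
        assert out.iterations_run == 0

    def test_tandem_input_untouched(self):
        record = ConsensusRecord("sat", "Satellite", "ACGTG" * 200)
        genome = GenomeAssembly(contigs={"ctg_0": dna(50_000, seed=76)})
        out = beat_curate(record, genome)
        assert out.status == ConsensusStatus.TANDEM
        assert out.sequence == record.sequence
        assert out.iterations_run == 0

    def test_deterministic(self):
        te = dna(1500, seed=77)
        base = dna(80_000, seed=78)
        genome, _ = plant_copies(base, te, 8, seed=79, max_divergence=0.05)
        record = ConsensusRecord("fam", "LTR/Copia", te[200:900])
        out1 = beat_curate(record, genome)
        out2 = beat_curate(record, genome)
        assert out1 == out2
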