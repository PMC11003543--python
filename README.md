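# tecurator

Transposable-element (TE) annotation toolkit: iterative consensus
curation, tandem-repeat triage, library-based genome annotation,
annotation refinement (defragmentation, overlap resolution, length
filtering), divergence landscapes, a synthetic-genome generator with
ground truth, and a nucleotide-level benchmarking harness (confusion
matrix / MCC).

Everything runs self-contained on a single CPU: homology search is an
internal seed-and-extend engine (k-mer seeding, diagonal clustering,
banded Smith-Waterman with dc-megablast-like scoring), multiple
alignment is an internal center-star aligner, and tandem detection is a
shifted-self-identity scanner. No external aligners are required.

## Library overview

| module | purpose |
| --- | --- |
| `tecurator.seqio` | FASTA/GFF3/BED/RepeatMasker-table I/O, genome preparation (`ctg_n` headers, IUPAC ambiguity masking) |
| `tecurator.search` | seed-and-extend local search (`find_hits`, `pairwise_align`), pluggable engine |
| `tecurator.tandem` | tandem-region detection, consensus triage, satellite/macrosatellite classification |
| `tecurator.beat` | iterative consensus extension: search, flank extraction, validation, mutual-support trimming, majority-rule consensus, iteration assessment |
| `tecurator.annotate` | library-vs-genome annotation with greedy per-locus resolution, soft/hard masking, optional 80/80 clustering |
| `tecurator.refine` | defragmentation (gap ≤ 150 bp), midpoint overlap resolution, optional <100 bp filter |
| `tecurator.landscape` | Kimura 2-parameter divergence, pie/family/landscape summary tables |
| `tecurator.simulate` | synthetic genomes: GC-controlled base sequence, mutated/fragmented/nested TE insertions, ground-truth GFF |
| `tecurator.benchmark` | confusion matrix, MCC, classification agreement, fragmentation ratio, consensus-length recovery |

Internal coordinates are 0-based half-open everywhere; conversion to
1-based inclusive conventions happens only at the GFF3/RepeatMasker I/O
boundary.

## CLI

```bash
tecurator simulate -c config.yml -o simdir --seed 1
tecurator triage   -l library.fa -o triaged.fa
tecurator curate   -g genome.fa -l library.fa -o curated.fa -i 10 -f 1000 -n 20
tecurator annotate -g genome.fa -l curated.fa -o outdir -c no -d yes
tecurator refine   -a outdir/annotations.gff3 -o refined.gff3 -m no
tecurator landscape -a refined.gff3 -g genome.fa -o summaries
tecurator benchmark -r reference.gff3 -t refined.gff3 -g genome.fa -o report.json
tecurator benchlib  -t curated.fa -r real.fa -o lengths.tsv
tecurator run-all  -g genome.fa -l seed_library.fa -o rundir -d yes
```

`run-all` writes a `summaryFiles/` directory containing the final GFF3 +
BED annotations, the curated library FASTA, the TSV summary tables and
(optionally) a softmasked genome. A simulator config looks like:

```yaml
genome_length: 1000000
gc: 0.42
seed: 1
families:
  - name: fam1
    classification: LINE/L1
    sequence: ACGT...        # the family consensus
    copy_number: 50
    divergence_max: 0.15
    fragmented_fraction: 0.1
    nested_fraction: 0.1
```

## Tests

```bash
python -m pytest tests/
```

The suite includes per-module unit tests, hypothesis property tests for
the interval and sequence invariants, and `tests/test_acceptance.py`
with the end-to-end criteria (consensus length recovery, end-to-end
annotation MCC, engine-vs-Smith-Waterman oracle agreement). The full run
takes a few minutes; the heavy acceptance tests dominate.

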