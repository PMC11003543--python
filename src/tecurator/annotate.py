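"""Library-vs-genome annotation, masking, and optional 80/80 clustering.

Annotation runs the internal search engine for every consensus and
resolves competing hits greedily by score, so a locus is attributed to a
single best family; lower-scoring overlapping hits are truncated to their
uncovered parts or dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from tecurator.landscape import kimura_from_alignment
from tecurator.search import EngineParams, SearchHit, Searcher, get_searcher, pairwise_align
from tecurator.seqio import Annotation, ConsensusRecord, GenomeAssembly

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 0.60
DEFAULT_MIN_SCORE = 60
MIN_FRAGMENT = 10  # truncated leftovers shorter than this are dropped


def _top_class(classification: str) -> str:
    return classification.split("/")[0]


def annotate_genome(
    genome: GenomeAssembly,
    library: list[ConsensusRecord],
    min_score: float = DEFAULT_MIN_SCORE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    engine: EngineParams | None = None,
) -> list[Annotation]:
    """Annotate a genome with a consensus library.

    Every library consensus is searched against the genome; hits compete
    per contig, best score first. Each annotation carries raw p-distance
    divergence (1 - identity) and the Kimura divergence computed from its
    alignment. Output is sorted by (contig, start).
    """
    if not library:
        raise ValueError("annotation requires a non-empty library")
    searcher = get_searcher(genome, engine) if engine else get_searcher(genome)
    all_hits: list[tuple[SearchHit, ConsensusRecord]] = []
    for record in library:
        hits = searcher.find_hits(
            record.sequence,
            min_identity=min_identity,
            query_id=record.id,
            keep_alignment=True,
            min_score=int(min_score),
        )
        logger.debug("%s: %d raw hits", record.id, len(hits))
        all_hits.extend((h, record) for h in hits)

    # greedy per-locus competition: best score first; ties to the longer
    # alignment, then lexicographic family id (determinism)
    all_hits.sort(key=lambda hr: (-hr[0].score, -(hr[0].s_end - hr[0].s_start), hr[1].id))
    claimed: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.contigs}
    annotations: list[Annotation] = []
    for hit, record in all_hits:
        free = _subtract(hit.s_start, hit.s_end, claimed[hit.contig])
        for start, end in free:
            if end - start < MIN_FRAGMENT:
                continue
            claimed[hit.contig].append((start, end))
            p_dist = 1.0 - hit.identity
            kim = kimura_from_alignment(hit.aligned_query, hit.aligned_subject)
            annotations.append(
                Annotation(
                    contig=hit.contig,
                    start=start,
                    end=end,
                    strand=hit.strand,
                    family=record.id,
                    classification=record.classification,
                    divergence=p_dist,
                    kimura=kim,
                    score=hit.score,
                )
            )
    annotations.sort(key=lambda a: (a.contig, a.start, a.end))
    return annotations


def _subtract(start: int, end: int, claimed: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Parts of [start, end) not covered by any claimed interval."""
    overlapping = sorted(
        (max(s, start), min(e, end)) for s, e in claimed if s < end and e > start
    )
    free = []
    cursor = start
    for s, e in overlapping:
        if s > cursor:
            free.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < end:
        free.append((cursor, end))
    return free


def mask_genome(
    genome: GenomeAssembly, annotations: list[Annotation], mode: str = "soft"
) -> GenomeAssembly:
    """Mask annotated spans: lowercase (``soft``) or ``N`` (``hard``)."""
    if mode not in ("soft", "hard"):
        raise ValueError(f"unknown mask mode {mode!r}")
    masked = {}
    per_contig: dict[str, list[Annotation]] = {}
    for ann in annotations:
        per_contig.setdefault(ann.contig, []).append(ann)
    for contig, seq in genome.contigs.items():
        chars = list(seq)
        for ann in per_contig.get(contig, []):
            if mode == "soft":
                chars[ann.start : ann.end] = seq[ann.start : ann.end].lower()
            else:
                chars[ann.start : ann.end] = "N" * (ann.end - ann.start)
        masked[contig] = "".join(chars)
    return GenomeAssembly(contigs=masked, header_map=dict(genome.header_map))


@dataclass(frozen=True)
class ClusterParams:
    min_identity: float = 0.80
    min_coverage_of_shorter: float = 0.80


def cluster_library(
    library: list[ConsensusRecord], params: ClusterParams = ClusterParams()
) -> list[ConsensusRecord]:
    """Greedy longest-first 80/80 clustering (both strands).

    A sequence joins an existing cluster when it aligns to the cluster
    representative with identity >= 0.80 over >= 0.80 of the shorter of
    the two sequences; representatives are returned. Ties in length are
    broken lexicographically by id so the result is order-stable.
    """
    if not library:
        raise ValueError("clustering requires a non-empty library")
    ordered = sorted(library, key=lambda r: (-len(r.sequence), r.id))
    representatives: list[ConsensusRecord] = []
    for record in ordered:
        joined = False
        for rep in representatives:
            shorter = min(len(record.sequence), len(rep.sequence))
            aln = pairwise_align(record.sequence, rep.sequence)
            aligned_shorter = min(aln.a_end - aln.a_start, aln.b_end - aln.b_start)
            if (
                aln.identity >= params.min_identity
                and shorter > 0
                and aligned_shorter / shorter >= params.min_coverage_of_shorter
            ):
                joined = True
                break
        if not joined:
            representatives.append(record)
    return representatives
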