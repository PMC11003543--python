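"""Iterative consensus improvement: search, extract, align, trim.

Each iteration finds genomic copies of the current consensus, extends
their flanks, discards extracts that no longer resemble the *initial*
consensus (guarding against locking onto an abundant neighbouring
repeat), trims flank sequence with no support from any other extract,
rebuilds a majority-rule consensus from a multiple alignment, and then
decides whether to continue, stop, or revert to the previous consensus.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np

from tecurator import _align
from tecurator.search import (
    EngineParams,
    ScoringParams,
    SearchHit,
    Searcher,
    encode,
    get_searcher,
    local_support_spans,
    pairwise_align,
    revcomp,
)
from tecurator.seqio import ConsensusRecord, ConsensusStatus, GenomeAssembly
from tecurator.tandem import classify_satellites, triage_consensus

logger = logging.getLogger(__name__)


class Verdict(enum.Enum):
    CONTINUE = "CONTINUE"
    DONE = "DONE"
    REVERT = "REVERT"
    LOW_COPY = "LOW_COPY"


@dataclass(frozen=True)
class IterationDecision:
    verdict: Verdict
    reason: str


@dataclass(frozen=True)
class BeatParams:
    """Tunable knobs of the iterative curation loop."""

    flank: int = 1000
    max_iterations: int = 10
    max_candidates: int = 20
    candidate_min_identity: float = 0.70
    candidate_min_coverage: float = 0.50
    min_matches: int = 3
    accept_min_coverage_of_prev: float = 0.80
    done_fraction_of_flank: float = 0.50
    seed: int = 0
    engine: EngineParams = field(default_factory=EngineParams)

    def __post_init__(self) -> None:
        if self.flank <= 0 or self.max_iterations < 1 or self.min_matches < 1:
            raise ValueError("invalid BeatParams")


@dataclass
class Extract:
    """One flank-extended genomic copy, in query orientation."""

    sequence: str
    core_start: int  # span of the original hit within `sequence`
    core_end: int


def select_candidates(hits: list[SearchHit], params: BeatParams) -> list[SearchHit]:
    """Filter hits to candidates for consensus construction.

    Keeps hits with identity strictly above ``candidate_min_identity`` and
    query coverage strictly above ``candidate_min_coverage``, then the top
    ``max_candidates`` by score. Returns an empty list only when no hit
    passes; callers compare the result length against ``min_matches`` to
    detect the low-copy condition.
    """
    passing = [
        h
        for h in hits
        if h.identity > params.candidate_min_identity
        and h.query_coverage > params.candidate_min_coverage
    ]
    passing.sort(key=lambda h: -h.score)
    return passing[: params.max_candidates]


def extend_flanks(genome: GenomeAssembly, hits: list[SearchHit], flank: int) -> list[Extract]:
    """Extract each hit with ``flank`` bp added on both sides, clamped to the
    contig, reverse-complemented for minus-strand hits so that every extract
    is in query orientation."""
    extracts = []
    for hit in hits:
        contig_seq = genome.contigs[hit.contig]
        lo = max(0, hit.s_start - flank)
        hi = min(len(contig_seq), hit.s_end + flank)
        seq = contig_seq[lo:hi]
        core_start = hit.s_start - lo
        core_end = hit.s_end - lo
        if hit.strand == "-":
            seq = revcomp(seq)
            core_start, core_end = len(seq) - core_end, len(seq) - core_start
        extracts.append(Extract(sequence=seq, core_start=core_start, core_end=core_end))
    return extracts


def validate_extended(
    extracts: list[Extract], initial_consensus: str, params: BeatParams
) -> list[Extract]:
    """Keep only extracts that still align to the round-0 consensus with
    identity > 0.70 and consensus coverage > 0.50."""
    kept = []
    for extract in extracts:
        aln = pairwise_align(
            initial_consensus, extract.sequence, params.engine.scoring, both_strands=False
        )
        if (
            aln.identity > params.candidate_min_identity
            and aln.coverage_of_a > params.candidate_min_coverage
        ):
            kept.append(extract)
    return kept


def trim_to_mutual_support(extracts: list[Extract], params: BeatParams) -> list[Extract]:
    """Trim flank positions with no alignment support from any other extract.

    The core (pre-extension) span is never trimmed; only unsupported flank
    tails outside the supported envelope are removed.
    """
    if len(extracts) < 2:
        logger.warning("trim_to_mutual_support called with fewer than 2 sequences")
        return extracts
    trimmed = []
    for i, extract in enumerate(extracts):
        n = len(extract.sequence)
        supported = np.zeros(n, dtype=bool)
        supported[extract.core_start : extract.core_end] = True
        # partners can only widen the supported envelope; stop once several
        # consecutive partners add nothing (keeps this O(n) in practice)
        stale = 0
        for j, other in enumerate(extracts):
            if i == j:
                continue
            before = int(supported.sum())
            for a, b in local_support_spans(extract.sequence, other.sequence, params.engine):
                supported[a:b] = True
            if int(supported.sum()) == before:
                stale += 1
                if stale >= 3:
                    break
            else:
                stale = 0
        idx = np.nonzero(supported)[0]
        lo, hi = int(idx[0]), int(idx[-1]) + 1
        trimmed.append(
            Extract(
                sequence=extract.sequence[lo:hi],
                core_start=extract.core_start - lo,
                core_end=extract.core_end - lo,
            )
        )
    return trimmed


# ---------------------------------------------------------------------------
# Multiple alignment (center-star) and majority consensus

_BASE_ORDER = "ACGT"


def _star_msa(sequences: list[str], scoring: ScoringParams) -> list[str]:
    """Center-star multiple alignment: global-align every sequence to the
    longest one and merge the pairwise gap structures."""
    center_idx = max(range(len(sequences)), key=lambda i: (len(sequences[i]), -i))
    center = sequences[center_idx]
    others = [s for i, s in enumerate(sequences) if i != center_idx]
    # per-pair gap runs inserted *within* the center, keyed by center position
    pair_rows = []
    max_ins = np.zeros(len(center) + 1, dtype=np.int64)
    for seq in others:
        _, ops = _align.nw_global(
            encode(seq),
            encode(center),
            np.int32(scoring.match),
            np.int32(scoring.mismatch),
            np.int32(scoring.gap_open),
            np.int32(scoring.gap_extend),
        )
        ins = np.zeros(len(center) + 1, dtype=np.int64)
        row_ops = []
        ci = 0
        for op in ops:
            if op == 0:  # consume both
                row_ops.append((0, ci))
                ci += 1
            elif op == 1:  # gap in center: insertion of seq relative to center
                ins[ci] += 1
                row_ops.append((1, ci))
            else:  # gap in seq
                row_ops.append((2, ci))
                ci += 1
        np.maximum(max_ins, ins, out=max_ins)
        pair_rows.append((seq, row_ops, ins))
    # column layout: for center position c: max_ins[c] insertion columns, then c
    col_of_center = np.zeros(len(center), dtype=np.int64)
    ins_col_start = np.zeros(len(center) + 1, dtype=np.int64)
    col = 0
    for c in range(len(center) + 1):
        ins_col_start[c] = col
        col += int(max_ins[c])
        if c < len(center):
            col_of_center[c] = col
            col += 1
    width = col
    rows = []
    center_row = ["-"] * width
    for c, ch in enumerate(center):
        center_row[col_of_center[c]] = ch
    for seq, row_ops, ins in pair_rows:
        row = ["-"] * width
        si = 0
        used_ins = np.zeros(len(center) + 1, dtype=np.int64)
        for op, ci in row_ops:
            if op == 0:
                row[col_of_center[ci]] = seq[si]
                si += 1
            elif op == 1:
                row[ins_col_start[ci] + used_ins[ci]] = seq[si]
                used_ins[ci] += 1
                si += 1
            # op == 2: center consumed, seq gapped -> nothing to place
        rows.append("".join(row))
    rows.insert(center_idx, "".join(center_row))
    return rows


def _drop_single_occupancy_columns(rows: list[str]) -> list[str]:
    arr = np.array([list(r) for r in rows])
    occupancy = (arr != "-").sum(axis=0)
    keep = occupancy != 1
    return ["".join(r) for r in arr[:, keep]]


def _majority_consensus(rows: list[str]) -> str:
    """Per-column strict plurality of non-gap symbols; ties broken A<C<G<T;
    columns with fewer than 2 non-gap symbols emit nothing. N never wins
    unless it is the only symbol class present (then the column is skipped)."""
    arr = np.array([list(r) for r in rows])
    out = []
    for col in arr.T:
        symbols = col[col != "-"]
        if len(symbols) < 2:
            continue
        counts: dict[str, int] = {}
        for s in symbols:
            counts[s] = counts.get(s, 0) + 1
        best_base = None
        best_count = -1
        for base in _BASE_ORDER:
            c = counts.get(base, 0)
            if c > best_count:
                best_base, best_count = base, c
        if best_count <= 0:
            continue  # only N/others in this column
        out.append(best_base)
    return "".join(out)


def build_consensus(
    sequences: list[str], starting_consensus: str, scoring: ScoringParams = ScoringParams()
) -> str:
    """Majority-rule consensus of the trimmed extracts.

    An MSA of the extracts plus the starting consensus is built; columns
    occupied by exactly one sequence are removed; the starting-consensus row
    is dropped; the remaining rows are realigned and the per-column majority
    base emitted (columns with fewer than two non-gap symbols emit nothing).
    """
    if len(sequences) < 2:
        raise ValueError("consensus construction needs at least 2 sequences")
    rows = _star_msa(sequences + [starting_consensus], scoring)
    rows = _drop_single_occupancy_columns(rows)
    rows = rows[:-1]  # remove starting consensus (appended last -> last row
    # unless it was the center; handle that case below)
    degapped = [r.replace("-", "") for r in rows]
    degapped = [r for r in degapped if r]
    if len(degapped) < 2:
        raise ValueError("degenerate family: fewer than 2 informative sequences")
    realigned = _star_msa(degapped, scoring)
    return _majority_consensus(realigned)


def assess_iteration(
    new_consensus: str, prev_consensus: str, params: BeatParams
) -> IterationDecision:
    """Decide the fate of one iteration's consensus.

    REVERT when the new consensus is shorter than the previous one or
    covers less than 80% of it; DONE when growth is below half the flank
    size; CONTINUE otherwise.
    """
    if not new_consensus or not prev_consensus:
        raise ValueError("assess_iteration requires non-empty sequences")
    if len(new_consensus) < len(prev_consensus):
        return IterationDecision(Verdict.REVERT, "new consensus shorter than previous")
    aln = pairwise_align(new_consensus, prev_consensus, params.engine.scoring)
    coverage_of_prev = (aln.b_end - aln.b_start) / len(prev_consensus) if aln.score > 0 else 0.0
    if coverage_of_prev < params.accept_min_coverage_of_prev:
        return IterationDecision(
            Verdict.REVERT,
            f"coverage of previous consensus {coverage_of_prev:.2f} < "
            f"{params.accept_min_coverage_of_prev:.2f}",
        )
    growth = len(new_consensus) - len(prev_consensus)
    if growth < params.done_fraction_of_flank * params.flank:
        return IterationDecision(Verdict.DONE, f"growth {growth} bp below threshold")
    return IterationDecision(Verdict.CONTINUE, f"growth {growth} bp; continuing")


def beat_curate(
    record: ConsensusRecord,
    genome: GenomeAssembly,
    params: BeatParams = BeatParams(),
    searcher: Searcher | None = None,
) -> ConsensusRecord:
    """Run the full iterative curation loop on one raw consensus.

    Deterministic given identical inputs. The returned record carries the
    final sequence, a status, and the number of iterations executed.
    """
    status, record = triage_consensus(record)
    if status != ConsensusStatus.RAW:
        return record
    if searcher is None:
        searcher = get_searcher(genome, params.engine)

    initial = record.sequence
    current = initial
    iterations = 0
    final_status = ConsensusStatus.CURATED
    while iterations < params.max_iterations:
        hits = searcher.find_hits(
            current,
            min_identity=params.candidate_min_identity,
            min_coverage=params.candidate_min_coverage,
            query_id=record.id,
        )
        candidates = select_candidates(hits, params)
        if len(candidates) < params.min_matches:
            final_status = ConsensusStatus.LOW_COPY
            break
        extracts = extend_flanks(genome, candidates, params.flank)
        extracts = validate_extended(extracts, initial, params)
        if len(extracts) < params.min_matches:
            final_status = ConsensusStatus.LOW_COPY
            break
        extracts = trim_to_mutual_support(extracts, params)
        try:
            new_consensus = build_consensus(
                [e.sequence for e in extracts], current, params.engine.scoring
            )
        except ValueError:
            final_status = ConsensusStatus.LOW_COPY
            break
        if not new_consensus:
            final_status = ConsensusStatus.LOW_COPY
            break
        iterations += 1
        decision = assess_iteration(new_consensus, current, params)
        logger.debug(
            "%s iteration %d: %s (%s)", record.id, iterations, decision.verdict.value,
            decision.reason,
        )
        if decision.verdict == Verdict.REVERT:
            break
        current = new_consensus
        if decision.verdict == Verdict.DONE:
            break

    out = record.with_(sequence=current, status=final_status, iterations_run=iterations)
    if final_status == ConsensusStatus.CURATED:
        sat_status, out = classify_satellites(out)
    return out


def curate_library(
    library: list[ConsensusRecord],
    genome: GenomeAssembly,
    params: BeatParams = BeatParams(),
) -> list[ConsensusRecord]:
    """Curate every raw consensus in a library against one genome."""
    searcher = get_searcher(genome, params.engine)
    out = []
    for record in library:
        logger.info("curating %s (%d bp)", record.id, len(record.sequence))
        out.append(beat_curate(record, genome, params, searcher=searcher))
    return out
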