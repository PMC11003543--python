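"""Seed-and-extend local homology search.

This is the internal engine used for consensus curation and library-based
annotation: exact k-mer seeding on both strands, diagonal clustering of
seeds into candidate loci, and windowed Smith-Waterman extension of each
locus. The engine is pluggable — anything producing :class:`SearchHit`
objects under the same contract can be substituted.

Default scoring is dc-megablast-like: match +2, mismatch -3, gap open -5,
gap extend -2 (first gap column pays the opening penalty only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tecurator import _align
from tecurator.seqio import GenomeAssembly

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(sequence: str) -> str:
    """Reverse complement of a nucleotide string."""
    return sequence.translate(_COMPLEMENT)[::-1]


def encode(sequence: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0..T=3, other=4)."""
    return _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringParams:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


@dataclass(frozen=True)
class EngineParams:
    scoring: ScoringParams = field(default_factory=ScoringParams)
    seed_size: int = 11
    diag_tolerance: int = 50
    join_gap: int = 300
    min_seeds: int = 2
    max_kmer_occupancy: int = 10_000
    window_margin: int = 100
    min_score: int = 40


DEFAULT_ENGINE = EngineParams()


@dataclass
class SearchHit:
    """One local alignment of a query consensus against a contig.

    Subject coordinates always satisfy ``s_start < s_end`` regardless of
    strand; query coordinates are on the forward query. ``identity`` is
    matches / alignment columns and ``query_coverage`` is aligned query
    bases / query length.
    """

    query_id: str
    contig: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    identity: float
    query_coverage: float
    score: float
    aligned_query: str | None = None
    aligned_subject: str | None = None


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    identity: float
    coverage_of_a: float
    score: float
    strand: str
    a_start: int = 0
    a_end: int = 0
    b_start: int = 0
    b_end: int = 0


def _kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Rolling k-mer integer codes; windows containing non-ACGT get -1."""
    n = len(enc)
    if n < k:
        return np.empty(0, dtype=np.int64)
    m = n - k + 1
    codes = np.zeros(m, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + enc[j : j + m]
    bad = (enc > 3).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(bad)))
    invalid = (cum[k:] - cum[:-k]) > 0
    codes[invalid] = -1
    return codes


class _ContigIndex:
    """Sorted k-mer code index over one contig."""

    def __init__(self, enc: np.ndarray, k: int):
        self.enc = enc
        codes = _kmer_codes(enc, k)
        order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[order]
        self.positions = order.astype(np.int64)

    def lookup(self, query_codes: np.ndarray, max_occ: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (query_pos, subject_pos) seed pairs."""
        valid = query_codes >= 0
        qpos_all = np.nonzero(valid)[0]
        qc = query_codes[qpos_all]
        lo = np.searchsorted(self.sorted_codes, qc, side="left")
        hi = np.searchsorted(self.sorted_codes, qc, side="right")
        counts = hi - lo
        keep = (counts > 0) & (counts <= max_occ)
        lo, hi, qpos_all = lo[keep], hi[keep], qpos_all[keep]
        counts = hi - lo
        if len(counts) == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qpos = np.repeat(qpos_all, counts)
        idx = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)])
        spos = self.positions[idx]
        return qpos, spos


class Searcher:
    """Reusable search engine bound to one genome assembly."""

    def __init__(self, genome: GenomeAssembly, params: EngineParams = DEFAULT_ENGINE):
        self.genome = genome
        self.params = params
        self._indexes: dict[str, _ContigIndex] = {}

    def _index(self, contig: str) -> _ContigIndex:
        if contig not in self._indexes:
            self._indexes[contig] = _ContigIndex(
                encode(self.genome.contigs[contig]), self.params.seed_size
            )
        return self._indexes[contig]

    # -- seed clustering -----------------------------------------------------

    def _clusters(
        self, qpos: np.ndarray, spos: np.ndarray, q_len: int
    ) -> list[tuple[int, int, int, int, int]]:
        """Group seeds into candidate loci.

        Returns (s_lo, s_hi, n_seeds, d_min, d_max) subject windows with
        their seed-diagonal range. Seeds are bucketed by diagonal, then
        chained along the subject with a gap limit.
        """
        p = self.params
        if len(qpos) == 0:
            return []
        diag = spos - qpos
        order = np.lexsort((spos, diag))
        diag, spos_s, qpos_s = diag[order], spos[order], qpos[order]
        clusters: list[tuple[int, int, int]] = []
        start = 0
        for i in range(1, len(diag) + 1):
            if i == len(diag) or diag[i] - diag[start] > p.diag_tolerance:
                self._split_band(
                    qpos_s[start:i], spos_s[start:i], q_len, clusters
                )
                start = i
        # drop sub-threshold (usually spurious single-seed) clusters before
        # merging so they cannot widen a real locus's diagonal band
        clusters = [c for c in clusters if c[2] >= p.min_seeds]
        return self._merge_windows(clusters)

    def _split_band(
        self,
        qpos: np.ndarray,
        spos: np.ndarray,
        q_len: int,
        out: list[tuple[int, int, int, int, int]],
    ) -> None:
        """Split one diagonal band into loci on large subject gaps."""
        order = np.argsort(spos, kind="stable")
        qpos, spos = qpos[order], spos[order]
        gap_limit = self.params.join_gap + q_len
        start = 0
        for i in range(1, len(spos) + 1):
            if i == len(spos) or spos[i] - spos[i - 1] > gap_limit:
                out.append(self._window(qpos[start:i], spos[start:i], q_len))
                start = i

    def _window(
        self, qpos: np.ndarray, spos: np.ndarray, q_len: int
    ) -> tuple[int, int, int, int, int]:
        p = self.params
        margin = p.window_margin + q_len // 10
        s_lo = int(spos.min() - qpos.max()) - margin
        s_hi = int(spos.max() + (q_len - qpos.min())) + margin
        diag = spos - qpos
        return s_lo, s_hi, len(qpos), int(diag.min()), int(diag.max())

    @staticmethod
    def _merge_windows(
        windows: list[tuple[int, int, int, int, int]]
    ) -> list[tuple[int, int, int, int, int]]:
        if not windows:
            return []
        windows.sort()
        merged = [windows[0]]
        for lo, hi, n, dmin, dmax in windows[1:]:
            mlo, mhi, mn, mdmin, mdmax = merged[-1]
            # merge only same-locus windows: overlapping subject spans AND
            # compatible diagonals, otherwise the band would blow up
            if lo <= mhi and dmin - mdmax <= 100 and mdmin - dmax <= 100:
                merged[-1] = (mlo, max(mhi, hi), mn + n, min(mdmin, dmin), max(mdmax, dmax))
            else:
                merged.append((lo, hi, n, dmin, dmax))
        return merged

    # -- alignment -----------------------------------------------------------

    def _align_window(
        self, q_enc: np.ndarray, s_enc: np.ndarray, d_lo: int | None = None,
        d_hi: int | None = None,
    ) -> tuple[int, int, int, int, int, np.ndarray]:
        sc = self.params.scoring
        args = (
            q_enc,
            s_enc,
            np.int32(sc.match),
            np.int32(sc.mismatch),
            np.int32(sc.gap_open),
            np.int32(sc.gap_extend),
        )
        if d_lo is None or d_hi is None:
            return _align.sw_local(*args)
        return _align.sw_local_banded(*args, np.int64(d_lo), np.int64(d_hi))

    def find_hits(
        self,
        query: str,
        min_identity: float = 0.0,
        min_coverage: float = 0.0,
        query_id: str = "query",
        keep_alignment: bool = False,
        min_score: int | None = None,
    ) -> list[SearchHit]:
        """All local alignments of ``query`` against the genome, both strands.

        Hits are filtered by identity/coverage/score, overlapping hits on the
        same locus are collapsed to the best-scoring one, and the result is
        sorted by descending score.
        """
        p = self.params
        if len(query) < p.seed_size:
            import warnings

            warnings.warn(f"query {query_id!r} shorter than seed size; no search performed")
            return []
        min_score = p.min_score if min_score is None else min_score
        hits: list[SearchHit] = []
        for contig in self.genome.contigs:
            index = self._index(contig)
            contig_len = len(index.enc)
            for strand in ("+", "-"):
                q_seq = query if strand == "+" else revcomp(query)
                q_enc = encode(q_seq)
                q_codes = _kmer_codes(q_enc, p.seed_size)
                qpos, spos = index.lookup(q_codes, p.max_kmer_occupancy)
                for s_lo, s_hi, n_seeds, d_min, d_max in self._clusters(
                    qpos, spos, len(q_seq)
                ):
                    if n_seeds < p.min_seeds:
                        continue
                    s_lo = max(0, s_lo)
                    s_hi = min(contig_len, s_hi)
                    if s_hi - s_lo < p.seed_size:
                        continue
                    pad = p.window_margin + len(q_seq) // 50
                    score, qa, qb, sa, sb, ops = self._align_window(
                        q_enc,
                        index.enc[s_lo:s_hi],
                        d_lo=d_min - s_lo - pad,
                        d_hi=d_max - s_lo + pad,
                    )
                    if score < min_score or qb <= qa:
                        continue
                    window_seq = self.genome.contigs[contig][s_lo:s_hi]
                    hit = self._make_hit(
                        query, q_seq, window_seq, strand, contig, s_lo, score,
                        qa, qb, sa, sb, ops, query_id, keep_alignment,
                    )
                    if hit.identity >= min_identity and hit.query_coverage >= min_coverage:
                        hits.append(hit)
        return _collapse_hits(hits)

    def _make_hit(
        self,
        query: str,
        q_oriented: str,
        window_seq: str,
        strand: str,
        contig: str,
        s_offset: int,
        score: int,
        qa: int,
        qb: int,
        sa: int,
        sb: int,
        ops: np.ndarray,
        query_id: str,
        keep_alignment: bool,
    ) -> SearchHit:
        matches, columns, al_q, al_s = _expand_alignment(
            q_oriented, window_seq, qa, sa, ops, build_strings=keep_alignment,
        )
        identity = matches / columns if columns else 0.0
        coverage = (qb - qa) / len(query)
        if strand == "+":
            q_start, q_end = qa, qb
        else:
            q_start, q_end = len(query) - qb, len(query) - qa
            if al_q is not None:
                al_q, al_s = revcomp(al_q), revcomp(al_s)
        return SearchHit(
            query_id=query_id,
            contig=contig,
            q_start=q_start,
            q_end=q_end,
            s_start=s_offset + sa,
            s_end=s_offset + sb,
            strand=strand,
            identity=identity,
            query_coverage=coverage,
            score=float(score),
            aligned_query=al_q,
            aligned_subject=al_s,
        )


def _expand_alignment(
    q_seq: str, s_seq: str, qa: int, sa: int, ops: np.ndarray, build_strings: bool
) -> tuple[int, int, str | None, str | None]:
    """Count matches/columns along an ops path; optionally build gapped strings."""
    qi, si = qa, sa
    matches = 0
    a_parts: list[str] = []
    b_parts: list[str] = []
    for op in ops:
        if op == 0:
            qc, sc = q_seq[qi], s_seq[si]
            if qc == sc and qc != "N":
                matches += 1
            if build_strings:
                a_parts.append(qc)
                b_parts.append(sc)
            qi += 1
            si += 1
        elif op == 1:
            if build_strings:
                a_parts.append(q_seq[qi])
                b_parts.append("-")
            qi += 1
        else:
            if build_strings:
                a_parts.append("-")
                b_parts.append(s_seq[si])
            si += 1
    columns = len(ops)
    if build_strings:
        return matches, columns, "".join(a_parts), "".join(b_parts)
    return matches, columns, None, None


def _collapse_hits(hits: list[SearchHit]) -> list[SearchHit]:
    """Keep the best-scoring hit per locus; drop hits mostly covered by a better one."""
    hits.sort(key=lambda h: (-h.score, h.contig, h.s_start))
    kept: list[SearchHit] = []
    for hit in hits:
        redundant = False
        for other in kept:
            if other.contig != hit.contig:
                continue
            overlap = min(hit.s_end, other.s_end) - max(hit.s_start, other.s_start)
            shorter = min(hit.s_end - hit.s_start, other.s_end - other.s_start)
            if shorter > 0 and overlap / shorter > 0.5:
                redundant = True
                break
        if not redundant:
            kept.append(hit)
    return kept


# -- module-level convenience ------------------------------------------------

_searcher_cache: dict[int, tuple[object, Searcher]] = {}


def get_searcher(genome: GenomeAssembly, params: EngineParams = DEFAULT_ENGINE) -> Searcher:
    """Memoized :class:`Searcher` per genome object (index reuse)."""
    key = id(genome)
    cached = _searcher_cache.get(key)
    if cached is not None and cached[0] is genome and cached[1].params == params:
        return cached[1]
    searcher = Searcher(genome, params)
    if len(_searcher_cache) > 8:
        _searcher_cache.clear()
    _searcher_cache[key] = (genome, searcher)
    return searcher


def find_hits(
    query: str,
    genome: GenomeAssembly,
    min_identity: float = 0.0,
    min_coverage: float = 0.0,
    **kwargs,
) -> list[SearchHit]:
    """See :meth:`Searcher.find_hits`."""
    return get_searcher(genome).find_hits(query, min_identity, min_coverage, **kwargs)


def _align_pair(a: str, b: str, scoring: ScoringParams) -> tuple[int, int, int, int, int, np.ndarray]:
    return _align.sw_local(
        encode(a),
        encode(b),
        np.int32(scoring.match),
        np.int32(scoring.mismatch),
        np.int32(scoring.gap_open),
        np.int32(scoring.gap_extend),
    )


def pairwise_align(
    a: str, b: str, scoring: ScoringParams = ScoringParams(), both_strands: bool = True
) -> PairwiseAlignment:
    """Best local alignment of ``a`` against ``b``, trying both orientations.

    ``coverage_of_a`` is aligned bases of ``a`` / len(a); identity is
    matches / alignment columns. An empty alignment yields zeros.
    """
    if not a or not b:
        raise ValueError("pairwise_align requires non-empty sequences")
    best = None
    for strand in ("+", "-") if both_strands else ("+",):
        a_or = a if strand == "+" else revcomp(a)
        score, qa, qb, sa, sb, ops = _align_pair(a_or, b, scoring)
        if best is None or score > best[0]:
            best = (score, qa, qb, sa, sb, ops, strand, a_or)
    score, qa, qb, sa, sb, ops, strand, a_or = best
    if score <= 0 or qb <= qa:
        return PairwiseAlignment("", "", 0.0, 0.0, 0.0, "+")
    matches, columns, al_a, al_b = _expand_alignment(a_or, b, qa, sa, ops, build_strings=True)
    a_start, a_end = (qa, qb) if strand == "+" else (len(a) - qb, len(a) - qa)
    return PairwiseAlignment(
        aligned_a=al_a,
        aligned_b=al_b,
        identity=matches / columns if columns else 0.0,
        coverage_of_a=(qb - qa) / len(a),
        score=float(score),
        strand=strand,
        a_start=a_start,
        a_end=a_end,
        b_start=sa,
        b_end=sb,
    )


def local_support_spans(a: str, b: str, params: EngineParams = DEFAULT_ENGINE,
                        min_score: int = 40) -> list[tuple[int, int]]:
    """Spans of ``a`` covered by seeded local alignments to ``b`` (either strand).

    Used for mutual-support flank trimming; cheaper than full pairwise DP
    because only seeded windows are aligned.
    """
    genome = GenomeAssembly(contigs={"b": b})
    searcher = Searcher(genome, params)
    spans = [
        (h.q_start, h.q_end)
        for h in searcher.find_hits(a, min_score=min_score)
    ]
    return spans
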