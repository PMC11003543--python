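"""Post-annotation polish: defragmentation, overlap resolution, length filter.

Defragmentation merges chains of same-family, same-strand fragments lying
within a gap threshold of each other (and, when full-length-LTR intervals
are supplied, LTR fragments inside one interval). Overlap resolution then
splits any remaining overlap at its midpoint so every base is attributed
to exactly one annotation.
"""

from __future__ import annotations

import itertools
import logging
from typing import Sequence

from tecurator.seqio import Annotation

logger = logging.getLogger(__name__)

DEFAULT_MAX_GAP = 150
DEFAULT_MIN_LENGTH = 100


def _sorted(annotations: Sequence[Annotation]) -> list[Annotation]:
    return sorted(annotations, key=lambda a: (a.contig, a.start, a.end))


def _weighted_divergence(members: list[Annotation]) -> float | None:
    pairs = [(a.length, a.divergence) for a in members if a.divergence is not None]
    if not pairs:
        return None
    total = sum(w for w, _ in pairs)
    return sum(w * d for w, d in pairs) / total


def _weighted_kimura(members: list[Annotation]) -> float | None:
    pairs = [(a.length, a.kimura) for a in members if a.kimura is not None]
    if not pairs:
        return None
    total = sum(w for w, _ in pairs)
    return sum(w * k for w, k in pairs) / total


def _merge_chain(members: list[Annotation], group_id: str) -> Annotation:
    first = members[0]
    return Annotation(
        contig=first.contig,
        start=min(a.start for a in members),
        end=max(a.end for a in members),
        strand=first.strand,
        family=first.family,
        classification=first.classification,
        divergence=_weighted_divergence(members),
        kimura=_weighted_kimura(members),
        score=max((a.score for a in members if a.score is not None), default=None),
        group_id=group_id,
    )


def defragment(
    annotations: Sequence[Annotation],
    max_gap: int = DEFAULT_MAX_GAP,
    ltr_intervals: Sequence[Annotation] | None = None,
) -> list[Annotation]:
    """Merge same-family, same-strand fragment chains with gaps <= ``max_gap``.

    Merged divergence is the length-weighted mean of member divergences.
    When ``ltr_intervals`` is given, LTR-classified annotations fully inside
    one interval are merged into a single locus regardless of gap.
    """
    anns = _sorted(annotations)
    groups = itertools.count()
    merged: list[Annotation] = []
    # chain per (contig, family, strand)
    open_chains: dict[tuple[str, str, str], list[Annotation]] = {}
    for ann in anns:
        key = (ann.contig, ann.family, ann.strand)
        chain = open_chains.get(key)
        if chain is not None and ann.start - chain[-1].end <= max_gap:
            chain.append(ann)
        else:
            if chain is not None:
                merged.append(_merge_chain(chain, f"group_{next(groups)}"))
            open_chains[key] = [ann]
    for chain in open_chains.values():
        merged.append(_merge_chain(chain, f"group_{next(groups)}"))

    if ltr_intervals:
        merged = _merge_ltr(merged, ltr_intervals, groups)
    return _sorted(merged)


def _merge_ltr(
    annotations: list[Annotation],
    ltr_intervals: Sequence[Annotation],
    groups: "itertools.count",
) -> list[Annotation]:
    out: list[Annotation] = []
    buckets: dict[int, list[Annotation]] = {}
    intervals = list(ltr_intervals)
    for ann in annotations:
        placed = False
        if ann.classification.split("/")[0] == "LTR":
            for i, iv in enumerate(intervals):
                if iv.contig == ann.contig and iv.start <= ann.start and ann.end <= iv.end:
                    buckets.setdefault(i, []).append(ann)
                    placed = True
                    break
        if not placed:
            out.append(ann)
    for i, members in sorted(buckets.items()):
        by_strand: dict[str, list[Annotation]] = {}
        for m in _sorted(members):
            by_strand.setdefault(m.strand, []).append(m)
        for strand_members in by_strand.values():
            out.append(_merge_chain(strand_members, f"ltr_group_{next(groups)}"))
    return out


def resolve_overlaps(annotations: Sequence[Annotation]) -> list[Annotation]:
    """Split pairwise overlaps at the midpoint; drop fully nested annotations.

    The leftmost-starting annotation keeps the left half of an overlap (the
    extra base when the overlap length is odd); an annotation wholly
    contained in another is removed. The union of covered bases is
    preserved and the output is overlap-free.
    """
    out: list[Annotation] = []
    for ann in _sorted(annotations):
        dropped = False
        if out:
            prev = out[-1]
            if prev.contig == ann.contig and prev.end > ann.start:
                if ann.end <= prev.end:
                    dropped = True  # fully contained in the previous annotation
                else:
                    overlap = prev.end - ann.start
                    left_share = (overlap + 1) // 2  # odd overlap: extra base left
                    boundary = ann.start + left_share
                    out[-1] = prev.with_(end=boundary)
                    ann = ann.with_(start=boundary)
        if not dropped:
            out.append(ann)
    return out


def length_filter(
    annotations: Sequence[Annotation],
    min_length: int = DEFAULT_MIN_LENGTH,
    enabled: bool = False,
) -> list[Annotation]:
    """Optionally drop annotations shorter than ``min_length`` (off by default)."""
    if not enabled:
        return list(annotations)
    return [a for a in annotations if a.length >= min_length]


def refine(
    annotations: Sequence[Annotation],
    max_gap: int = DEFAULT_MAX_GAP,
    ltr_intervals: Sequence[Annotation] | None = None,
    min_length: int = DEFAULT_MIN_LENGTH,
    length_filter_enabled: bool = False,
) -> list[Annotation]:
    """Defragment, resolve overlaps, then (optionally) length-filter."""
    out = defragment(annotations, max_gap=max_gap, ltr_intervals=ltr_intervals)
    out = resolve_overlaps(out)
    return length_filter(out, min_length=min_length, enabled=length_filter_enabled)
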