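"""Annotation scoring: confusion matrix, MCC, classification agreement,
fragmentation ratio and consensus-length recovery."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from tecurator.search import pairwise_align
from tecurator.seqio import Annotation, ConsensusRecord


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class AgreementCounts:
    correct: int
    misclassified: int
    missing: int

    @property
    def total(self) -> int:
        return self.correct + self.misclassified + self.missing


def _coverage_mask(annotations: Sequence[Annotation], contig_lengths: dict[str, int]):
    masks = {c: np.zeros(n, dtype=bool) for c, n in contig_lengths.items()}
    for ann in annotations:
        if ann.contig in masks:
            masks[ann.contig][ann.start : ann.end] = True
    return masks


def confusion(
    reference: Sequence[Annotation],
    test: Sequence[Annotation],
    genome_length: int | dict[str, int],
) -> ConfusionCounts:
    """Nucleotide-level TP/FP/FN/TN of a test annotation vs a reference.

    Presence/absence only; family identity is ignored. ``genome_length``
    may be a single length (single-contig case: every annotation must be
    on one contig) or a contig -> length map.
    """
    if isinstance(genome_length, int):
        contigs = {a.contig for a in reference} | {a.contig for a in test}
        if len(contigs) > 1:
            raise ValueError("scalar genome_length with multi-contig annotations")
        name = contigs.pop() if contigs else "ctg_0"
        lengths = {name: genome_length}
    else:
        lengths = dict(genome_length)
    ref_masks = _coverage_mask(reference, lengths)
    test_masks = _coverage_mask(test, lengths)
    tp = fp = fn = tn = 0
    for contig in lengths:
        r, t = ref_masks[contig], test_masks[contig]
        tp += int((r & t).sum())
        fp += int((~r & t).sum())
        fn += int((r & ~t).sum())
        tn += int((~r & ~t).sum())
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; zero-denominator convention -> 0."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _top_class(classification: str) -> str:
    return classification.split("/")[0] if classification else "Unknown"


def classification_agreement(
    reference: Sequence[Annotation],
    test: Sequence[Annotation],
    min_overlap_fraction: float = 0.5,
) -> AgreementCounts:
    """Per-reference-copy agreement with a test annotation set.

    A reference copy covered over less than ``min_overlap_fraction`` of its
    length is *missing*; otherwise it is *correct* when the top-level class
    covering most of it matches its own top-level class, else
    *misclassified*.
    """
    per_contig: dict[str, list[Annotation]] = {}
    for t in test:
        per_contig.setdefault(t.contig, []).append(t)
    for anns in per_contig.values():
        anns.sort(key=lambda a: a.start)

    correct = misclassified = missing = 0
    for ref in reference:
        cover_by_class: dict[str, int] = {}
        covered = 0
        for t in per_contig.get(ref.contig, []):
            if t.start >= ref.end:
                break
            overlap = min(ref.end, t.end) - max(ref.start, t.start)
            if overlap > 0:
                cls = _top_class(t.classification)
                cover_by_class[cls] = cover_by_class.get(cls, 0) + overlap
                covered += overlap
        # overlapping test annotations never double-cover a base after
        # overlap resolution, so summed overlap is a faithful coverage
        if covered < min_overlap_fraction * ref.length:
            missing += 1
        elif max(cover_by_class, key=cover_by_class.get) == _top_class(ref.classification):
            correct += 1
        else:
            misclassified += 1
    return AgreementCounts(correct=correct, misclassified=misclassified, missing=missing)


def fragmentation_ratio(
    baseline: Sequence[Annotation], other: Sequence[Annotation]
) -> dict[str, float]:
    """Mean number of ``other`` annotations per overlapped baseline annotation.

    Baseline annotations with no overlap in ``other`` are excluded. Keys are
    top-level classifications plus ``"all"``.
    """
    per_contig: dict[str, list[Annotation]] = {}
    for t in other:
        per_contig.setdefault(t.contig, []).append(t)
    for anns in per_contig.values():
        anns.sort(key=lambda a: a.start)

    counts_by_class: dict[str, list[int]] = {}
    for base in baseline:
        n = 0
        for t in per_contig.get(base.contig, []):
            if t.start >= base.end:
                break
            if min(base.end, t.end) - max(base.start, t.start) > 0:
                n += 1
        if n == 0:
            continue
        counts_by_class.setdefault(_top_class(base.classification), []).append(n)
        counts_by_class.setdefault("all", []).append(n)
    return {cls: float(np.mean(v)) for cls, v in counts_by_class.items()}


@dataclass
class LengthBandEntry:
    test_id: str
    real_id: str | None
    percent_of_real: float | None


@dataclass
class LengthBandSummary:
    entries: list[LengthBandEntry]
    in_band_fraction: float
    band: tuple[float, float] = (95.0, 105.0)


def consensus_length_band(
    test_library: Sequence[ConsensusRecord],
    real_library: Sequence[ConsensusRecord],
    band: tuple[float, float] = (95.0, 105.0),
    min_pair_score: float = 50.0,
) -> LengthBandSummary:
    """Pair each test consensus with its best-scoring real sequence and
    report test length as a percent of real length, plus the fraction of
    paired entries inside the band.

    Pairs scoring below ``min_pair_score`` are treated as no hit and
    reported unpaired.
    """
    if not test_library or not real_library:
        raise ValueError("both libraries must be non-empty")
    entries = []
    n_paired = 0
    n_in_band = 0
    for test in test_library:
        best_score = min_pair_score
        best_real = None
        for real in real_library:
            aln = pairwise_align(test.sequence, real.sequence)
            if aln.score > best_score:
                best_score = aln.score
                best_real = real
        if best_real is None:
            entries.append(LengthBandEntry(test.id, None, None))
            continue
        percent = 100.0 * len(test.sequence) / len(best_real.sequence)
        entries.append(LengthBandEntry(test.id, best_real.id, percent))
        n_paired += 1
        if band[0] <= percent <= band[1]:
            n_in_band += 1
    fraction = n_in_band / n_paired if n_paired else 0.0
    return LengthBandSummary(entries=entries, in_band_fraction=fraction, band=band)


def random_annotations(
    reference: Sequence[Annotation],
    genome_length: int,
    seed: int,
    contig: str = "ctg_0",
) -> list[Annotation]:
    """Coverage-matched random annotation set (null model for MCC ~ 0).

    Intervals are placed uniformly, independent of the reference, with the
    same count and lengths as the reference set; overlaps between placed
    intervals are allowed (coverage then differs slightly, which the null
    tolerates).
    """
    rng = np.random.default_rng(seed)
    out = []
    for ann in reference:
        length = ann.length
        start = int(rng.integers(0, max(1, genome_length - length)))
        out.append(
            Annotation(
                contig=contig,
                start=start,
                end=start + length,
                strand=ann.strand,
                family=ann.family,
                classification=ann.classification,
            )
        )
    return out
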