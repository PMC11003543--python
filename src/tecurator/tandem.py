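"""Tandem-repeat detection and consensus triage.

A single internal detector (shifted-self-identity over candidate periods)
stands in for external tandem finders. Triage thresholds are strict as
written: a consensus is a tandem repeat only when *more* than 90% of it is
tandem-covered, and curation proceeds when the covered fraction is at most
50%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tecurator.search import encode
from tecurator.seqio import ConsensusRecord, ConsensusStatus

MATCH_THRESHOLD = 0.75
MAX_PERIOD = 2000
MIN_REGION = 12

TANDEM_FRACTION = 0.90      # strictly above -> tandem repeat
TRIM_FRACTION = 0.50        # strictly above -> trim to longest non-tandem run
SATELLITE_FRACTION = 0.50   # strictly above -> likely simple/satellite
MACROSAT_FRACTION = 0.90    # one contiguous region strictly above this
MACROSAT_MIN_PERIOD = 200


@dataclass(frozen=True)
class TandemRegion:
    """One tandem stretch on a consensus (half-open span)."""

    start: int
    end: int
    period: int
    identity: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TandemProfile:
    regions: list[TandemRegion]
    tandem_fraction: float
    longest_contiguous: TandemRegion | None

    def covered_mask(self, length: int) -> np.ndarray:
        mask = np.zeros(length, dtype=bool)
        for region in self.regions:
            mask[region.start : region.end] = True
        return mask


def _regions_for_period(match: np.ndarray, period: int, n: int) -> list[TandemRegion]:
    """Maximal stretches where shifted-self identity stays >= threshold.

    ``match[i]`` is True when ``seq[i] == seq[i + period]``. A rolling
    window flags candidate anchors; runs of flagged anchors are extended
    to full regions and trimmed to matching boundaries.
    """
    m = len(match)
    window = min(m, max(period, MIN_REGION))
    cums = np.concatenate(([0], np.cumsum(match)))
    win_frac = (cums[window:] - cums[:-window]) / window
    anchors = win_frac >= MATCH_THRESHOLD
    if not anchors.any():
        return []
    regions = []
    idx = np.nonzero(anchors)[0]
    splits = np.nonzero(np.diff(idx) > 1)[0]
    run_starts = np.concatenate(([0], splits + 1))
    run_ends = np.concatenate((splits, [len(idx) - 1]))
    edge = min(MIN_REGION, window)
    for rs, re in zip(run_starts, run_ends):
        lo, hi = int(idx[rs]), int(idx[re]) + window  # span in match coords
        # shrink edges while the local edge window falls below threshold, so
        # harmonic periods do not drag flanking sequence into the region
        while hi - lo >= edge and (cums[lo + edge] - cums[lo]) / edge < MATCH_THRESHOLD:
            lo += 1
        while hi - lo >= edge and (cums[hi] - cums[hi - edge]) / edge < MATCH_THRESHOLD:
            hi -= 1
        # trim to matching boundary positions
        while lo < hi and not match[lo]:
            lo += 1
        while hi > lo and not match[hi - 1]:
            hi -= 1
        if hi <= lo:
            continue
        identity = float(match[lo:hi].mean())
        if identity < MATCH_THRESHOLD:
            continue
        start, end = lo, min(hi + period, n)
        if end - start < max(2 * period, MIN_REGION):
            continue
        regions.append(TandemRegion(start=start, end=end, period=period, identity=identity))
    return regions


def detect_tandem(sequence: str) -> TandemProfile:
    """Detect tandem-repeat regions by shifted-self comparison.

    Deterministic; every reported region satisfies: shifting it by its
    period matches at least 75% of comparable positions.
    """
    n = len(sequence)
    if n < 2:
        raise ValueError("sequence too short for tandem detection")
    enc = encode(sequence)
    regions: list[TandemRegion] = []
    for period in range(1, min(MAX_PERIOD, n // 2) + 1):
        match = enc[:-period] == enc[period:]
        regions.extend(_regions_for_period(match, period, n))
    # prefer long regions with short periods; drop regions adding little new
    # coverage so the profile stays readable
    regions.sort(key=lambda r: (-r.length, r.period, r.start))
    kept: list[TandemRegion] = []
    mask = np.zeros(n, dtype=bool)
    for region in regions:
        new = int((~mask[region.start : region.end]).sum())
        if new >= max(region.period, MIN_REGION) or (
            kept and new > 0 and region.period == kept[0].period
        ):
            kept.append(region)
            mask[region.start : region.end] = True
    kept.sort(key=lambda r: (r.start, r.period))
    fraction = float(mask.mean()) if n else 0.0
    longest = max(kept, key=lambda r: (r.length, -r.period), default=None)
    return TandemProfile(regions=kept, tandem_fraction=fraction, longest_contiguous=longest)


def _longest_uncovered_run(mask: np.ndarray) -> tuple[int, int]:
    """Leftmost longest run of False in ``mask`` (half-open)."""
    best = (0, 0)
    start = None
    for i, covered in enumerate(mask):
        if not covered and start is None:
            start = i
        elif covered and start is not None:
            if i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    if start is not None and len(mask) - start > best[1] - best[0]:
        best = (start, len(mask))
    return best


def triage_consensus(record: ConsensusRecord) -> tuple[ConsensusStatus, ConsensusRecord]:
    """Apply the entry triage rules to a raw consensus.

    tandem fraction > 0.90 -> TANDEM, untouched, excluded from curation;
    0.50 < fraction <= 0.90 -> longest non-tandem section extracted, final
    (CURATED, no iterative curation); fraction <= 0.50 -> stays RAW and
    proceeds to curation.
    """
    profile = detect_tandem(record.sequence)
    fraction = profile.tandem_fraction
    if fraction > TANDEM_FRACTION:
        out = record.with_(status=ConsensusStatus.TANDEM)
        return ConsensusStatus.TANDEM, out
    if fraction > TRIM_FRACTION:
        mask = profile.covered_mask(len(record.sequence))
        start, end = _longest_uncovered_run(mask)
        if end <= start:
            out = record.with_(status=ConsensusStatus.TANDEM)
            return ConsensusStatus.TANDEM, out
        out = record.with_(
            sequence=record.sequence[start:end], status=ConsensusStatus.CURATED
        )
        return ConsensusStatus.CURATED, out
    return ConsensusStatus.RAW, record


def classify_satellites(record: ConsensusRecord) -> tuple[ConsensusStatus, ConsensusRecord]:
    """Post-curation satellite triage.

    tandem fraction > 0.50 flags the consensus as likely simple/satellite;
    if additionally one contiguous region covers > 0.90 of the length with
    a period of at least 200 bp, the record becomes a MACROSATELLITE and is
    trimmed to the first full period of that region.
    """
    profile = detect_tandem(record.sequence)
    n = len(record.sequence)
    if profile.tandem_fraction <= SATELLITE_FRACTION:
        return record.status, record
    flagged = record.with_(satellite=True)
    macro = None
    for region in profile.regions:
        if region.length / n > MACROSAT_FRACTION and region.period >= MACROSAT_MIN_PERIOD:
            if macro is None or region.length > macro.length or (
                region.length == macro.length and region.period < macro.period
            ):
                macro = region
    if macro is not None:
        unit = record.sequence[macro.start : macro.start + macro.period]
        out = flagged.with_(sequence=unit, status=ConsensusStatus.MACROSATELLITE)
        return ConsensusStatus.MACROSATELLITE, out
    return flagged.status, flagged
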