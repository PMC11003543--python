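"""Independent reference implementations used to verify the package.

These deliberately avoid the package's own alignment/detection code paths:
full Smith-Waterman comes from biotite, tandem coverage from a brute-force
period scan, and interval arithmetic from per-base boolean arrays.
"""

from __future__ import annotations

import numpy as np


def sw_oracle(a: str, b: str):
    """Optimal local alignment of a vs b via biotite (full DP, no heuristics).

    Returns (score, identity, a_start, a_end, b_start, b_end) with identity
    = matches / alignment columns.
    """
    import biotite.sequence as bs
    import biotite.sequence.align as ba

    matrix = np.full((4, 4), -3, dtype=np.int32)
    np.fill_diagonal(matrix, 2)
    mat = ba.SubstitutionMatrix(
        bs.NucleotideSequence.alphabet_unamb,
        bs.NucleotideSequence.alphabet_unamb,
        matrix,
    )
    s1, s2 = bs.NucleotideSequence(a), bs.NucleotideSequence(b)
    aln = ba.align_optimal(s1, s2, mat, gap_penalty=(-5, -2), local=True, max_number=1)[0]
    trace = aln.trace
    matches = 0
    for i, j in trace:
        if i >= 0 and j >= 0 and a[i] == b[j]:
            matches += 1
    columns = len(trace)
    identity = matches / columns if columns else 0.0
    a_idx = trace[:, 0][trace[:, 0] >= 0]
    b_idx = trace[:, 1][trace[:, 1] >= 0]
    return (
        int(aln.score),
        identity,
        int(a_idx.min()),
        int(a_idx.max()) + 1,
        int(b_idx.min()),
        int(b_idx.max()) + 1,
    )


def tandem_fraction_oracle(seq: str, max_period: int = 50, threshold: float = 0.75,
                           min_len: int = 16) -> float:
    """Brute-force tandem coverage by exhaustive period scan.

    For every period p, every window of length max(2p, min_len) on the
    shifted-self match profile whose mean match rate reaches the threshold
    marks its span (window plus one period) as tandem-covered.
    """
    n = len(seq)
    covered = np.zeros(n, dtype=bool)
    enc = np.frombuffer(seq.encode(), dtype=np.uint8)
    for p in range(1, min(max_period, n // 2) + 1):
        m = (enc[:-p] == enc[p:]).astype(np.int64)
        w = max(2 * p, min_len)
        if len(m) < w:
            continue
        cums = np.concatenate(([0], np.cumsum(m)))
        means = (cums[w:] - cums[:-w]) / w
        for i in np.nonzero(means >= threshold)[0]:
            covered[i : i + w + p] = True
    return float(covered.mean())


def confusion_oracle(reference, test, genome_length):
    """Per-base labelling loop (slow, obviously correct)."""
    labels_ref = np.zeros(genome_length, dtype=bool)
    labels_test = np.zeros(genome_length, dtype=bool)
    for ann in reference:
        for i in range(ann.start, ann.end):
            labels_ref[i] = True
    for ann in test:
        for i in range(ann.start, ann.end):
            labels_test[i] = True
    tp = int((labels_ref & labels_test).sum())
    fp = int((~labels_ref & labels_test).sum())
    fn = int((labels_ref & ~labels_test).sum())
    tn = int((~labels_ref & ~labels_test).sum())
    return tp, fp, fn, tn


def mcc_oracle(tp: int, fp: int, fn: int, tn: int) -> float:
    import math

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def kimura_oracle(p: float, q: float) -> float:
    import math

    return -0.5 * math.log((1 - 2 * p - q) * math.sqrt(1 - 2 * q))
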