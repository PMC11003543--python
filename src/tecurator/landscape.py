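"""Divergence computation and annotation summaries.

Provides the closed-form Kimura two-parameter distance, per-annotation
divergence from alignments, and the three machine-readable summary tables:
classification pie data, family table, and the divergence landscape
(1-Kimura-% bins from 0 to 50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from tecurator.seqio import Annotation, GenomeAssembly

N_BINS = 50

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def kimura_distance(p: float, q: float) -> float | None:
    """Kimura two-parameter distance from transition fraction ``p`` and
    transversion fraction ``q``.

    K = -1/2 * ln((1 - 2p - q) * sqrt(1 - 2q)). Returns ``None`` when the
    arguments fall outside the domain (saturated divergence).
    """
    if p < 0 or q < 0:
        raise ValueError("substitution fractions must be non-negative")
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        return None
    return -0.5 * math.log(w1 * math.sqrt(w2))


def substitution_fractions(aligned_a: str, aligned_b: str) -> tuple[float, float]:
    """Transition and transversion fractions over aligned non-gap columns."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings must have equal length")
    sites = transitions = transversions = 0
    for ca, cb in zip(aligned_a.upper(), aligned_b.upper()):
        if ca in "-N" or cb in "-N":
            continue
        sites += 1
        if ca == cb:
            continue
        if (ca, cb) in _TRANSITIONS:
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        return 0.0, 0.0
    return transitions / sites, transversions / sites


def kimura_from_alignment(aligned_a: str | None, aligned_b: str | None) -> float | None:
    """Kimura distance of one alignment; ``None`` if absent or saturated."""
    if aligned_a is None or aligned_b is None:
        return None
    p, q = substitution_fractions(aligned_a, aligned_b)
    return kimura_distance(p, q)


def annotation_divergences(
    annotations: list[Annotation],
    alignments: dict[int, tuple[str, str]] | None = None,
) -> list[Annotation]:
    """Fill per-annotation Kimura divergence from aligned sequence pairs.

    ``alignments`` maps annotation list index -> (aligned consensus,
    aligned genomic copy); annotations whose Kimura value is already set
    are passed through. Annotations without any alignment keep
    ``kimura=None`` and are excluded from the landscape.
    """
    out = []
    for i, ann in enumerate(annotations):
        if ann.kimura is None and alignments and i in alignments:
            a, b = alignments[i]
            ann = ann.with_(kimura=kimura_from_alignment(a, b))
        out.append(ann)
    return out


@dataclass
class SummaryTables:
    pie: pd.DataFrame
    families: pd.DataFrame
    landscape: pd.DataFrame


def _top_class(classification: str) -> str:
    return classification.split("/")[0] if classification else "Unknown"


def summarize(annotations: list[Annotation], genome: GenomeAssembly) -> SummaryTables:
    """Build the pie, family and landscape tables.

    Pie percentages (including the Non-Repeat remainder) sum to 100. The
    landscape is binned by floor(Kimura * 100) into 1%-wide bins 0..50,
    values above 50 clamped into the last bin; plotting convention reverses
    the x-axis so ancient activity sits on the left.
    """
    total = genome.total_length
    if total == 0:
        raise ValueError("empty genome")

    by_class: dict[str, int] = {}
    fam_rows: dict[tuple[str, str], dict] = {}
    land: dict[tuple[int, str], int] = {}
    annotated = 0
    for ann in annotations:
        cls = _top_class(ann.classification)
        by_class[cls] = by_class.get(cls, 0) + ann.length
        annotated += ann.length
        key = (ann.family, ann.classification)
        row = fam_rows.setdefault(key, {"count": 0, "bp": 0})
        row["count"] += 1
        row["bp"] += ann.length
        if ann.kimura is not None:
            b = min(int(ann.kimura * 100), N_BINS)
            land[(b, cls)] = land.get((b, cls), 0) + ann.length

    pie = pd.DataFrame(
        [
            {"classification": cls, "bp": bp, "percent": 100.0 * bp / total}
            for cls, bp in sorted(by_class.items())
        ]
        + [
            {
                "classification": "Non-Repeat",
                "bp": total - annotated,
                "percent": 100.0 * (total - annotated) / total,
            }
        ]
    )

    families = pd.DataFrame(
        [
            {
                "family": fam,
                "classification": cls,
                "count": row["count"],
                "bp": row["bp"],
                "percent": 100.0 * row["bp"] / total,
            }
            for (fam, cls), row in fam_rows.items()
        ]
    )
    if not families.empty:
        families = families.sort_values(
            ["bp", "family"], ascending=[False, True]
        ).reset_index(drop=True)

    classes = sorted({cls for _, cls in land})
    records = []
    for b in range(N_BINS + 1):
        rec = {"kimura_bin": b}
        for cls in classes:
            rec[cls] = 100.0 * land.get((b, cls), 0) / total
        records.append(rec)
    landscape = pd.DataFrame(records)
    return SummaryTables(pie=pie, families=families, landscape=landscape)


def write_summary_tables(tables: SummaryTables, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables.pie.to_csv(outdir / "summary_pie.tsv", sep="\t", index=False)
    tables.families.to_csv(outdir / "family_summary.tsv", sep="\t", index=False)
    tables.landscape.to_csv(outdir / "landscape.tsv", sep="\t", index=False)


def plot_landscape(tables: SummaryTables, path) -> None:
    """Optional stacked-bar landscape rendering (reversed x-axis)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = tables.landscape.set_index("kimura_bin")
    fig, ax = plt.subplots(figsize=(8, 4))
    bottom = None
    for cls in df.columns:
        ax.bar(df.index, df[cls], bottom=bottom, label=cls, width=1.0)
        bottom = df[cls] if bottom is None else bottom + df[cls]
    ax.set_xlim(N_BINS + 0.5, -0.5)  # ancient activity on the left
    ax.set_xlabel("Kimura distance to consensus (%)")
    ax.set_ylabel("Percent of genome")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
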