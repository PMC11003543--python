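"""Sequence and annotation I/O.

Reads and writes FASTA, GFF3, BED6 and RepeatMasker ``.out`` tables, and
prepares genome assemblies for analysis (header sanitisation, ambiguity
masking).

Internal coordinates are 0-based half-open everywhere; GFF3 and
RepeatMasker coordinates (1-based inclusive) are converted on read/write.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_AMBIGUOUS = "RYSWKMBDHV"
_AMBIG_TABLE = str.maketrans(_AMBIGUOUS + _AMBIGUOUS.lower(), "N" * 2 * len(_AMBIGUOUS))
_VALID_RE = re.compile(r"^[ACGTN]*$")

GFF_SOURCE = "te-curator"
GFF_TYPE = "dispersed_repeat"


class ConsensusStatus(enum.Enum):
    """Curation status of a consensus model."""

    RAW = "RAW"
    CURATED = "CURATED"
    TANDEM = "TANDEM"
    MACROSATELLITE = "MACROSATELLITE"
    LOW_COPY = "LOW_COPY"


@dataclass
class ConsensusRecord:
    """One TE family model: sequence plus classification and provenance."""

    id: str
    classification: str
    sequence: str
    status: ConsensusStatus = ConsensusStatus.RAW
    iterations_run: int = 0
    satellite: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"consensus {self.id!r} has an empty sequence")

    def with_(self, **kwargs) -> "ConsensusRecord":
        return replace(self, **kwargs)


@dataclass
class Annotation:
    """One genomic TE interval (0-based half-open)."""

    contig: str
    start: int
    end: int
    strand: str
    family: str
    classification: str = "Unknown"
    divergence: float | None = None
    kimura: float | None = None
    score: float | None = None
    group_id: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"annotation on {self.contig}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def with_(self, **kwargs) -> "Annotation":
        return replace(self, **kwargs)


@dataclass
class GenomeAssembly:
    """Named contigs plus the sanitized↔original header map."""

    contigs: dict[str, str]
    header_map: dict[str, str] = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs


def prepare_genome(raw_records: Sequence[tuple[str, str]]) -> GenomeAssembly:
    """Sanitize raw FASTA records into a :class:`GenomeAssembly`.

    Headers are replaced by ``ctg_<n>`` (0-based, input order), sequences
    are upper-folded and ambiguous IUPAC codes replaced by ``N``. The
    original headers are retained in ``header_map``.
    """
    if not raw_records:
        raise ValueError("no input records")
    contigs: dict[str, str] = {}
    header_map: dict[str, str] = {}
    seen: set[str] = set()
    for n, (header, sequence) in enumerate(raw_records):
        original = header.lstrip(">").strip()
        if original in seen:
            raise ValueError(f"duplicate FASTA header: {original!r}")
        seen.add(original)
        if not sequence:
            raise ValueError(f"record {original!r} has an empty sequence")
        cleaned = sequence.translate(_AMBIG_TABLE).upper()
        if not _VALID_RE.match(cleaned):
            bad = sorted(set(cleaned) - set("ACGTN"))
            raise ValueError(f"record {original!r} contains invalid symbols: {bad}")
        name = f"ctg_{n}"
        contigs[name] = cleaned
        header_map[name] = original
    return GenomeAssembly(contigs=contigs, header_map=header_map)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (full-header, sequence) pairs."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.description, str(rec.seq)))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (header, sequence) pairs as 60-column-wrapped FASTA."""
    seq_records = [
        SeqRecord(Seq(seq), id=header.split()[0], description=header)
        for header, seq in records
    ]
    # Biopython prefixes id + description; keep the full header verbatim.
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def split_family_classification(header: str) -> tuple[str, str]:
    """Split a ``name#Class/Family`` FASTA header token."""
    token = header.split()[0]
    if "#" in token:
        family, classification = token.split("#", 1)
        return family, classification or "Unknown"
    return token, "Unknown"


def read_library(path: str | Path) -> list[ConsensusRecord]:
    """Read a consensus library FASTA (``name#Class/Family`` headers)."""
    records = []
    for header, seq in read_fasta(path):
        family, classification = split_family_classification(header)
        records.append(
            ConsensusRecord(id=family, classification=classification, sequence=seq.upper())
        )
    return records


def write_library(library: Iterable[ConsensusRecord], path: str | Path) -> None:
    """Write a consensus library, carrying status in the header."""
    write_fasta(
        [
            (f"{rec.id}#{rec.classification} status={rec.status.value}", rec.sequence)
            for rec in library
        ],
        path,
    )


# ---------------------------------------------------------------------------
# Annotation tables

def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" in part:
            key, value = part.split("=", 1)
            attrs[key.strip()] = value.strip()
    return attrs


def read_annotations(path: str | Path, format: str) -> list[Annotation]:
    """Read annotations from GFF3, BED6 or RepeatMasker ``.out``."""
    if format == "gff3":
        return _read_gff3(path)
    if format == "bed":
        return _read_bed(path)
    if format == "rmout":
        return _read_rmout(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_gff3(path: str | Path) -> list[Annotation]:
    annotations = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            try:
                start = int(fields[3]) - 1  # 1-based inclusive -> 0-based half-open
                end = int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end < start after conversion")
            attrs = _parse_gff_attributes(fields[8])
            divergence = attrs.get("divergence")
            kimura = attrs.get("kimura")
            annotations.append(
                Annotation(
                    contig=fields[0],
                    start=start,
                    end=end,
                    strand=fields[6] if fields[6] in "+-" else "+",
                    family=attrs.get("family", attrs.get("ID", "Unknown")),
                    classification=attrs.get("classification", "Unknown"),
                    divergence=float(divergence) if divergence is not None else None,
                    kimura=float(kimura) if kimura is not None else None,
                    score=float(fields[5]) if fields[5] not in (".", "") else None,
                    group_id=attrs.get("group_id"),
                )
            )
    return annotations


def _read_bed(path: str | Path) -> list[Annotation]:
    annotations = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 BED columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            family, classification = split_family_classification(fields[3])
            annotations.append(
                Annotation(
                    contig=fields[0],
                    start=start,
                    end=end,
                    strand=fields[5] if fields[5] in "+-" else "+",
                    family=family,
                    classification=classification,
                    score=float(fields[4]) if fields[4] not in (".", "") else None,
                )
            )
    return annotations


def _read_rmout(path: str | Path) -> list[Annotation]:
    """Read a RepeatMasker .out table (3-line header, whitespace-delimited)."""
    annotations = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if lineno <= 3 or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: expected >=11 RepeatMasker columns")
            try:
                score = float(fields[0])
                div = float(fields[1])
                start = int(fields[5]) - 1  # 1-based inclusive -> 0-based half-open
                end = int(fields[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end < start after conversion")
            strand = "+" if fields[8] == "+" else "-"
            annotations.append(
                Annotation(
                    contig=fields[4],
                    start=start,
                    end=end,
                    strand=strand,
                    family=fields[9],
                    classification=fields[10],
                    divergence=div / 100.0,
                    score=score,
                )
            )
    return annotations


def write_annotations(annotations: Sequence[Annotation], path: str | Path, format: str) -> None:
    """Write annotations as GFF3 (1-based inclusive) or BED6."""
    if format == "gff3":
        _write_gff3(annotations, path)
    elif format == "bed":
        _write_bed(annotations, path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")


def _write_gff3(annotations: Sequence[Annotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, ann in enumerate(annotations):
            attrs = [
                f"ID=te_{i}",
                f"family={ann.family}",
                f"classification={ann.classification}",
            ]
            if ann.divergence is not None:
                attrs.append(f"divergence={ann.divergence:.6g}")
            if ann.kimura is not None:
                attrs.append(f"kimura={ann.kimura:.6g}")
            if ann.group_id is not None:
                attrs.append(f"group_id={ann.group_id}")
            score = f"{ann.score:.6g}" if ann.score is not None else "."
            fh.write(
                "\t".join(
                    [
                        ann.contig,
                        GFF_SOURCE,
                        GFF_TYPE,
                        str(ann.start + 1),
                        str(ann.end),
                        score,
                        ann.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def _write_bed(annotations: Sequence[Annotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            score = f"{ann.score:.6g}" if ann.score is not None else "0"
            fh.write(
                "\t".join(
                    [
                        ann.contig,
                        str(ann.start),
                        str(ann.end),
                        f"{ann.family}#{ann.classification}",
                        score,
                        ann.strand,
                    ]
                )
                + "\n"
            )
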