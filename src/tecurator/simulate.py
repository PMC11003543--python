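"""Synthetic genome generator with ground-truth TE insertions.

Builds a random base sequence at a target GC content, inserts mutated
TE copies at random positions (insertions expand the sequence, so
non-TE bases stay uncontaminated for true-negative counting), truncates
a configurable fraction of copies, and runs a second pass that nests
additional copies inside first-pass insertions. Ground truth is returned
as a sorted list of reference insertions and can be written as GFF3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from tecurator.search import revcomp
from tecurator.seqio import Annotation, GenomeAssembly

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}

COPY_NUMBER_MEAN = 150.0
COPY_NUMBER_SD = 120.0
COPY_NUMBER_MIN = 5
COPY_NUMBER_MAX = 732


@dataclass(frozen=True)
class FamilyConfig:
    name: str
    classification: str
    sequence: str
    copy_number: int
    divergence_max: float = 0.30
    fragmented_fraction: float = 0.0
    nested_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"family {self.name}: empty sequence")
        if self.copy_number < 0:
            raise ValueError(f"family {self.name}: negative copy number")


@dataclass(frozen=True)
class SimConfig:
    genome_length: int
    gc: float
    families: Sequence[FamilyConfig] = ()
    seed: int = 0
    indel_fraction: float = 0.0  # fraction of mutation events that are 1-3 bp indels

    def __post_init__(self) -> None:
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must lie strictly between 0 and 1")
        for fam in self.families:
            for frac in (fam.divergence_max, fam.fragmented_fraction, fam.nested_fraction):
                if not (0.0 <= frac <= 1.0):
                    raise ValueError(f"family {fam.name}: fraction out of [0, 1]")


@dataclass
class ReferenceInsertion:
    contig: str
    start: int
    end: int
    strand: str
    family: str
    classification: str
    divergence: float
    fragmented: bool = False
    nested: bool = False
    insertion_id: str = ""
    parent_id: str | None = None

    def to_annotation(self) -> Annotation:
        return Annotation(
            contig=self.contig,
            start=self.start,
            end=self.end,
            strand=self.strand,
            family=self.family,
            classification=self.classification,
            divergence=self.divergence,
        )


def load_config(path: str | Path) -> SimConfig:
    """Load a simulator config from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    families = [FamilyConfig(**fam) for fam in raw.get("families", [])]
    return SimConfig(
        genome_length=int(raw["genome_length"]),
        gc=float(raw["gc"]),
        families=families,
        seed=int(raw.get("seed", 0)),
        indel_fraction=float(raw.get("indel_fraction", 0.0)),
    )


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """i.i.d. bases with P(G) = P(C) = gc/2."""
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=probs))


def sample_copy_numbers(
    n_families: int,
    seed: int,
    mean: float = COPY_NUMBER_MEAN,
    sd: float = COPY_NUMBER_SD,
) -> list[int]:
    """Normal copy-number draws, rounded and clamped to [5, 732]."""
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    draws = np.rint(rng.normal(mean, sd, size=n_families))
    return [int(min(max(d, COPY_NUMBER_MIN), COPY_NUMBER_MAX)) for d in draws]


def mutate_copy(
    sequence: str,
    divergence: float,
    seed: int | np.random.Generator,
    indel_fraction: float = 0.0,
) -> tuple[str, float]:
    """Mutate a copy by per-site substitution with the given probability.

    Substitutions are transition-biased 2:1 (P(transition) = 2/3). When
    ``indel_fraction`` > 0, that fraction of mutation events becomes a
    1-3 bp insertion or deletion instead. Returns the mutated sequence
    and its realized substitution p-distance (substitutions / sites).
    """
    if divergence > 0.45:
        raise ValueError("divergence above 0.45 is not meaningful under this model")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[str] = []
    n_sites = len(sequence)
    substitutions = 0
    for base in sequence:
        if rng.random() >= divergence:
            out.append(base)
            continue
        if indel_fraction > 0 and rng.random() < indel_fraction:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(base)
            out.append("".join(rng.choice(_BASES, size=int(rng.integers(1, 4)))))
            continue
        substitutions += 1
        if rng.random() < 2.0 / 3.0:
            out.append(_TRANSITION[base] if base in _TRANSITION else base)
        else:
            choices = _TRANSVERSIONS.get(base)
            out.append(choices[int(rng.integers(0, 2))] if choices else base)
    realized = substitutions / n_sites if n_sites else 0.0
    return "".join(out), realized


def _prepare_copy(
    fam: FamilyConfig, rng: np.random.Generator, indel_fraction: float, force_intact: bool
) -> tuple[str, float, str, bool]:
    """Mutate, optionally fragment, and orient one copy."""
    divergence = float(rng.uniform(0.0, fam.divergence_max))
    seq, realized = mutate_copy(fam.sequence, divergence, rng, indel_fraction)
    fragmented = (not force_intact) and rng.random() < fam.fragmented_fraction
    if fragmented:
        cut = float(rng.uniform(0.10, 0.90))
        keep = max(1, int(round(len(seq) * (1.0 - cut))))
        seq = seq[:keep] if rng.random() < 0.5 else seq[len(seq) - keep :]
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        seq = revcomp(seq)
    return seq, realized, strand, fragmented


def simulate_genome(config: SimConfig) -> tuple[GenomeAssembly, list[ReferenceInsertion]]:
    """Simulate one contig with TE insertions and return ground truth.

    Pass 1 inserts every family's ``copy_number`` copies at uniform-random
    positions of the base sequence. Pass 2 inserts an additional
    ``round(nested_fraction * copy_number)`` copies per family *inside*
    randomly chosen pass-1 insertions; the host record keeps one entry
    whose span covers both of its segments, linked via ``parent_id``.
    Fully reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    base = random_sequence(config.genome_length, config.gc, rng)

    total_insert = sum(
        len(f.sequence) * (f.copy_number + int(round(f.nested_fraction * f.copy_number)))
        for f in config.families
    )
    if config.families and total_insert > 50 * config.genome_length:
        raise ValueError(
            "total insertion length vastly exceeds the base genome; "
            "increase genome_length"
        )

    # pass 1: placement in base coordinates, then assembly with offsets
    placements = []  # (base_pos, seq, fam, divergence, strand, fragmented)
    for fam in config.families:
        for _ in range(fam.copy_number):
            seq, realized, strand, fragmented = _prepare_copy(
                fam, rng, config.indel_fraction, force_intact=False
            )
            pos = int(rng.integers(0, config.genome_length + 1))
            placements.append((pos, seq, fam, realized, strand, fragmented))
    placements.sort(key=lambda t: t[0])

    parts: list[str] = []
    insertions: list[ReferenceInsertion] = []
    cursor = 0
    out_pos = 0
    counter = 0
    for pos, seq, fam, divergence, strand, fragmented in placements:
        parts.append(base[cursor:pos])
        out_pos += pos - cursor
        insertions.append(
            ReferenceInsertion(
                contig="ctg_0",
                start=out_pos,
                end=out_pos + len(seq),
                strand=strand,
                family=fam.name,
                classification=fam.classification,
                divergence=divergence,
                fragmented=fragmented,
                insertion_id=f"ins_{counter}",
            )
        )
        counter += 1
        parts.append(seq)
        out_pos += len(seq)
        cursor = pos
    parts.append(base[cursor:])
    genome_seq = "".join(parts)

    # pass 2: nested insertions inside pass-1 copies
    host_pool = list(range(len(insertions)))
    for fam in config.families:
        n_nested = int(round(fam.nested_fraction * fam.copy_number))
        for _ in range(n_nested):
            if not host_pool:
                break
            seq, realized, strand, fragmented = _prepare_copy(
                fam, rng, config.indel_fraction, force_intact=True
            )
            host_idx = int(host_pool[int(rng.integers(0, len(host_pool)))])
            host = insertions[host_idx]
            if host.end - host.start < 2:
                continue
            site = int(rng.integers(host.start + 1, host.end))
            genome_seq = genome_seq[:site] + seq + genome_seq[site:]
            child = ReferenceInsertion(
                contig="ctg_0",
                start=site,
                end=site + len(seq),
                strand=strand,
                family=fam.name,
                classification=fam.classification,
                divergence=realized,
                fragmented=fragmented,
                nested=True,
                insertion_id=f"ins_{counter}",
                parent_id=host.insertion_id,
            )
            counter += 1
            # shift everything downstream of the nesting site
            for ins in insertions:
                if ins.start >= site:
                    ins.start += len(seq)
                    ins.end += len(seq)
                elif ins.end > site:
                    ins.end += len(seq)  # host (and any enclosing span) widens
            insertions.append(child)

    insertions.sort(key=lambda i: (i.start, i.end))
    genome = GenomeAssembly(contigs={"ctg_0": genome_seq}, header_map={"ctg_0": "simulated"})
    return genome, insertions


def write_reference_gff(insertions: list[ReferenceInsertion], path: str | Path) -> None:
    """Ground-truth GFF3 with divergence/fragmented/nested/parent attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ins in insertions:
            attrs = [
                f"ID={ins.insertion_id}",
                f"family={ins.family}",
                f"classification={ins.classification}",
                f"divergence={ins.divergence:.6g}",
                f"fragmented={'yes' if ins.fragmented else 'no'}",
                f"nested={'yes' if ins.nested else 'no'}",
            ]
            if ins.parent_id:
                attrs.append(f"parent_id={ins.parent_id}")
            fh.write(
                "\t".join(
                    [
                        ins.contig,
                        "te-curator-sim",
                        "dispersed_repeat",
                        str(ins.start + 1),
                        str(ins.end),
                        ".",
                        ins.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
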