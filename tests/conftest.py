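from __future__ import annotations

import random

import numpy as np
import pytest

from tecurator.search import revcomp
from tecurator.seqio import GenomeAssembly


def dna(length: int, seed: int) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(length))


def mutate(seq: str, rate: float, seed: int) -> str:
    """Uniform random substitutions at the given per-site rate."""
    rng = random.Random(seed)
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([c for c in "ACGT" if c != out[i]])
    return "".join(out)


def plant_copies(
    base: str,
    te: str,
    n_copies: int,
    seed: int,
    max_divergence: float = 0.10,
    revcomp_some: bool = True,
) -> tuple[GenomeAssembly, list[tuple[int, int, str]]]:
    """Insert mutated copies of ``te`` into ``base`` (expansion model).

    Returns the genome and the planted (start, end, strand) spans.
    """
    rng = random.Random(seed)
    positions = sorted(rng.sample(range(len(base)), n_copies))
    parts = []
    spans = []
    prev = 0
    offset = 0
    for pos in positions:
        parts.append(base[prev:pos])
        copy = mutate(te, rng.uniform(0, max_divergence), rng.randrange(1 << 30))
        strand = "+"
        if revcomp_some and rng.random() < 0.5:
            copy = revcomp(copy)
            strand = "-"
        start = pos + offset
        spans.append((start, start + len(copy), strand))
        parts.append(copy)
        offset += len(copy)
        prev = pos
    parts.append(base[prev:])
    genome = GenomeAssembly(contigs={"ctg_0": "".join(parts)})
    return genome, spans


@pytest.fixture(scope="session")
def small_genome() -> GenomeAssembly:
    return GenomeAssembly(contigs={"ctg_0": dna(20_000, seed=1)})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
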