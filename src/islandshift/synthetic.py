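"""Synthetic genomes for end-to-end testing without downloads.

The predictor consumes only mononucleotide counts per window, so an
i.i.d. base model is the right level of realism for its test surface:
a compositionally homogeneous backbone at a chosen G+C fraction, with
optional implanted segments of divergent G+C at known coordinates, and a
donor pool of genomes spanning a wide G+C gradient standing in for the
bundled collection of real bacterial donor genomes.  A and T (and G and C)
are drawn with equal probability within their pools.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bandwidth import DonorPool
from .genome_windows import GenomeSequence

_NUC_CODES = np.frombuffer(b"ATCG", dtype=np.uint8)

#: Default donor pool: five synthetic genomes spanning the bacterial G+C
#: range at 0.10 spacing — wider than the 7.5% mutual-dissimilarity floor,
#: so the default five artificial fragments are always drawable (for
#: even-split compositions the dissimilarity metric equals |ΔGC|).
DEFAULT_DONOR_GCS = (0.25, 0.35, 0.45, 0.65, 0.75)
DEFAULT_DONOR_LENGTH = 500_000


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic host genome with known implants."""

    genome_length: int
    background_gc: float
    implants: tuple[tuple[int, int, float], ...] = ()  # (start, length, gc)
    donor_gcs: tuple[float, ...] = DEFAULT_DONOR_GCS
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        if not 0.0 < self.background_gc < 1.0:
            raise ValueError("background_gc must lie in (0,1)")
        spans = []
        for start, length, gc in self.implants:
            if not 0.0 < gc < 1.0:
                raise ValueError(f"implant gc {gc} outside (0,1)")
            if start < 0 or length < 1 or start + length > self.genome_length:
                raise ValueError(
                    f"implant ({start}, {length}) outside genome bounds"
                )
            spans.append((start, start + length))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("implants overlap")
        for gc in self.donor_gcs:
            if not 0.0 < gc < 1.0:
                raise ValueError(f"donor gc {gc} outside (0,1)")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    p = np.array([at, at, gc / 2.0, gc / 2.0])  # A, T, C, G
    return rng.choice(_NUC_CODES, size=n, p=p)


def generate_host(
    spec: SyntheticSpec,
) -> tuple[GenomeSequence, list[tuple[int, int]]]:
    """Host genome plus the ground-truth implant intervals [start, end)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    arr = _random_bases(rng, spec.genome_length, spec.background_gc)
    truth = []
    for start, length, gc in spec.implants:
        arr[start:start + length] = _random_bases(rng, length, gc)
        truth.append((start, start + length))
    genome = GenomeSequence(
        id=f"synthetic_host_gc{spec.background_gc:.2f}_seed{spec.seed}",
        sequence=arr.tobytes().decode("ascii"),
    )
    return genome, sorted(truth)


def synthetic_pool(
    gcs=DEFAULT_DONOR_GCS,
    length: int = DEFAULT_DONOR_LENGTH,
    seed: int = 0,
) -> DonorPool:
    """In-memory donor pool: one i.i.d. genome per G+C value."""
    if not gcs:
        raise ValueError("gcs must be non-empty")
    rng = np.random.default_rng(seed)
    genomes, provenance = [], []
    for gc in gcs:
        arr = _random_bases(rng, length, gc)
        name = f"synthetic_donor_gc{gc:.2f}"
        genomes.append(
            GenomeSequence(id=name, sequence=arr.tobytes().decode("ascii"))
        )
        provenance.append(f"{name}.fna")
    return DonorPool(genomes=genomes, provenance=provenance)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> Path:
    """Write one genome as FASTA, sequence wrapped at *width* columns."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        seq = genome.sequence
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")
    return path


def generate_donor_pool(
    gcs,
    length: int,
    seed: int,
    directory: str | Path,
) -> DonorPool:
    """Write a synthetic donor pool as a FASTA directory and return it."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pool = synthetic_pool(gcs=gcs, length=length, seed=seed)
    for genome, fname in zip(pool.genomes, pool.provenance):
        write_fasta(genome, directory / fname)
    return pool


def truth_to_bed(
    truth: list[tuple[int, int]],
    chrom: str,
    prefix: str = "implant",
) -> str:
    """Ground-truth implant intervals as BED lines."""
    lines = [
        f"{chrom}\t{s}\t{e}\t{prefix}{i + 1:02d}"
        for i, (s, e) in enumerate(truth)
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def island_benchmark_spec(seed: int = 0) -> SyntheticSpec:
    """Canonical recovery benchmark: 2 Mb host at GC 0.55 with one 150 kb
    implant at GC 0.30 starting at 0.8 Mb."""
    return SyntheticSpec(
        genome_length=2_000_000,
        background_gc=0.55,
        implants=((800_000, 150_000, 0.30),),
        seed=seed,
    )


def negative_control_spec(seed: int = 0) -> SyntheticSpec:
    """Homogeneous 2 Mb host at GC 0.55, no implants."""
    return SyntheticSpec(
        genome_length=2_000_000,
        background_gc=0.55,
        implants=(),
        seed=seed,
    )
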