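import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from islandshift.genome_windows import GenomeSequence, Window


@pytest.fixture
def rng():
    return np.random.default_rng(20160105)


def make_windows(n: int, length: int = 50_000, counts=None):
    """Consecutive full windows with supplied or zero count vectors."""
    out = []
    for i in range(n):
        c = np.zeros(4, dtype=np.int64) if counts is None else np.asarray(
            counts[i], dtype=np.int64)
        out.append(Window(index=i, start=i * length, end=(i + 1) * length,
                          counts=c, is_partial=False))
    return out


@pytest.fixture
def windows_factory():
    return make_windows


def write_fasta_text(path, header, seq, width=60):
    with open(path, "w") as fh:
        fh.write(f">{header}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")
    return path


@pytest.fixture
def fasta_writer():
    return write_fasta_text
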