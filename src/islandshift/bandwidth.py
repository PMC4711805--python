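"""Automatic bandwidth selection by artificial-fragment insertion.

The bandwidth h controls how many clusters mean shift produces, and no
universally good value exists across genomes.  The heuristic implemented
here calibrates h per genome: a fixed number of window-sized fragments is
drawn from donor genomes of *different* bacteria, each fragment required to
deviate from the host genome's per-nucleotide window-sum statistics,

    sum_i Y_i < mean - c*sd   or   sum_i Y_i > mean + c*sd

for at least one nucleotide (c >= 1), and required to differ from every
other selected fragment by more than 7.5% in the sum of the four
nucleotides.  Mean shift is run on host windows plus fragments, starting
from a generous bandwidth; h is decreased geometrically until the clustering
places every artificial fragment in its own cluster.  At that bandwidth,
genuinely alien host windows (candidate genomic islands) separate from the
genome backbone as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome_windows import (
    GenomeSequence,
    WindowStats,
    partition_windows,
    read_fasta,
)
from .mean_shift import (
    Clustering,
    KernelSpec,
    MeanShiftConfig,
    max_pairwise_distance,
    run_mean_shift,
)

logger = logging.getLogger(__name__)

#: Minimum pairwise compositional dissimilarity between selected fragments.
MIN_DISSIMILARITY = 0.075

_FASTA_SUFFIXES = (".fna", ".fa", ".fasta")


class InsufficientDonorDiversityError(RuntimeError):
    """Donor pool exhausted before the requested fragment count was reached."""

    def __init__(self, found: int, requested: int):
        self.found = found
        self.requested = requested
        super().__init__(
            f"only {found} of {requested} artificial fragments could be "
            f"selected: donor pool lacks enough deviating, mutually "
            f"dissimilar windows"
        )


class BandwidthSearchError(RuntimeError):
    """The bandwidth floor was reached without separating the fragments."""

    def __init__(self, history: list["SearchStep"]):
        self.history = history
        super().__init__(
            f"bandwidth search failed: no h in {len(history)} steps "
            f"separated all artificial fragments"
        )


@dataclass(frozen=True)
class DonorPool:
    """Donor genomes from which artificial fragments are drawn."""

    genomes: list[GenomeSequence]
    provenance: list[str]


@dataclass(frozen=True)
class ArtificialFragment:
    """A donor window accepted by the deviation + dissimilarity criteria."""

    counts: np.ndarray
    donor_id: str
    donor_offset: int
    length: int


@dataclass(frozen=True)
class SearchStep:
    h: float
    separated: bool
    n_clusters: int


@dataclass
class BandwidthSearch:
    """Geometric bandwidth schedule h_init, h_init*decay, ... down to h_min."""

    h_init: float
    decay: float = 0.9
    h_min: float | None = None  # default: h_init / 1000
    history: list[SearchStep] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.h_init <= 0:
            raise ValueError("h_init must be positive")
        if not 0.0 < self.decay < 1.0:
            raise ValueError("decay must lie in (0, 1)")
        if self.h_min is None:
            self.h_min = self.h_init / 1000.0
        if self.h_min <= 0 or self.h_min > self.h_init:
            raise ValueError("h_min must lie in (0, h_init]")

    def grid(self) -> list[float]:
        """The full h schedule the search would visit."""
        out, h = [], self.h_init
        while h >= self.h_min:
            out.append(h)
            h *= self.decay
        return out

    def history_tsv(self) -> str:
        lines = ["h\tseparated\tn_clusters"]
        lines += [f"{s.h:.6g}\t{int(s.separated)}\t{s.n_clusters}"
                  for s in self.history]
        return "\n".join(lines) + "\n"


def load_donor_pool(
    directory: str | Path,
    host: GenomeSequence | None = None,
) -> DonorPool:
    """Read every FASTA file in *directory* as one donor genome.

    A donor identical to the host (same record id and length) is skipped
    with a warning — fragments must come from different bacteria.
    """
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in _FASTA_SUFFIXES
    )
    genomes, provenance = [], []
    for p in paths:
        g = read_fasta(p)
        if host is not None and g.id == host.id and g.length == host.length:
            logger.warning("donor %s matches the host genome; skipped", p.name)
            continue
        genomes.append(g)
        provenance.append(p.name)
    if not genomes:
        raise FileNotFoundError(f"no donor FASTA files found in {directory}")
    return DonorPool(genomes=genomes, provenance=provenance)


def deviates(
    counts: np.ndarray,
    stats: WindowStats,
    c: float,
    quantifier: str = "any",
) -> bool:
    """Deviation criterion: window sum outside mean +/- c*sd.

    ``quantifier='any'`` (default): at least one of the four nucleotide sums
    deviates.  ``'all'``: every one must (near-degenerate since the four
    sums are constrained to total ~j; exposed for completeness).
    """
    if c < 1:
        raise ValueError("standard-deviation coefficient c must be >= 1")
    counts = np.asarray(counts, dtype=float)
    lo = stats.mean - c * stats.sd
    hi = stats.mean + c * stats.sd
    outside = (counts < lo) | (counts > hi)
    if quantifier == "any":
        return bool(outside.any())
    if quantifier == "all":
        return bool(outside.all())
    raise ValueError(f"quantifier must be 'any' or 'all', got {quantifier!r}")


def dissimilarity(a: np.ndarray, b: np.ndarray, j: int) -> float:
    """Compositional dissimilarity of two windows of nominal length *j*.

    L1 distance of the count 4-vectors divided by 2j — the fraction of the
    window mass that differs in composition.  Symmetric; 0 iff the
    compositions are identical; 1 when the windows share no composition
    (e.g. all-A vs all-T).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.abs(a - b).sum() / (2.0 * j))


def select_artificial_fragments(
    pool: DonorPool,
    stats: WindowStats,
    j: int,
    c: float,
    n_frag: int,
    seed: int,
    min_dissimilarity: float = MIN_DISSIMILARITY,
    quantifier: str = "any",
) -> list[ArtificialFragment]:
    """Draw *n_frag* deviating, mutually dissimilar windows from the pool.

    Full windows of every donor genome are enumerated, the candidate order
    is shuffled by *seed*, and the first candidates passing (a) the
    deviation criterion against the host statistics and (b) the pairwise
    dissimilarity floor against all already-accepted fragments are kept.
    """
    if n_frag < 1:
        raise ValueError("n_frag must be >= 1")
    if not pool.genomes:
        raise ValueError("donor pool is empty")
    candidates: list[tuple[str, "np.ndarray", int]] = []
    for g in pool.genomes:
        if g.length < j:
            continue
        for w in partition_windows(g, j):
            if not w.is_partial:
                candidates.append((g.id, w.counts, w.start))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(candidates))
    selected: list[ArtificialFragment] = []
    for idx in order:
        donor_id, counts, offset = candidates[int(idx)]
        if not deviates(counts, stats, c, quantifier):
            continue
        if any(dissimilarity(counts, f.counts, j) <= min_dissimilarity
               for f in selected):
            continue
        selected.append(
            ArtificialFragment(counts=counts, donor_id=donor_id,
                               donor_offset=offset, length=j)
        )
        if len(selected) == n_frag:
            return selected
    raise InsufficientDonorDiversityError(len(selected), n_frag)


def is_separated(
    clustering: Clustering,
    artificial_ids: Iterable[int],
    strict: bool = True,
) -> bool:
    """Do the artificial fragments sit in clusters of their own?

    Strict (default): every fragment is a singleton cluster — no host
    window and no other fragment shares it.  Relaxed: fragments may share
    clusters with each other but not with host windows.
    """
    art = set(int(i) for i in artificial_ids)
    labels = clustering.labels
    for a in art:
        members = np.nonzero(labels == labels[a])[0]
        if any(int(m) not in art for m in members):
            return False
        if strict and len(members) > 1:
            return False
    return True


def default_h_init(host_vectors: Sequence[np.ndarray] | np.ndarray) -> float:
    """Starting bandwidth: the host feature-space diameter.

    With a flat kernel this guarantees a single initial cluster; for the
    gaussian kernel it is a generous ceiling.
    """
    d = max_pairwise_distance(host_vectors)
    if d <= 0:
        raise ValueError("host windows are all identical; no usable diameter")
    return d


def find_bandwidth(
    host_vectors: Sequence[np.ndarray] | np.ndarray,
    fragments: Sequence[ArtificialFragment],
    kernel: KernelSpec,
    search: BandwidthSearch,
    epsilon: float = 1e-3,
    max_iterations: int = 500,
    strict: bool = True,
) -> float:
    """Largest bandwidth on the search grid separating all fragments.

    Runs mean shift on host windows plus fragments at decreasing h and
    returns the first (largest) h at which :func:`is_separated` holds.
    Every step is recorded in ``search.history``.

    Raises :class:`BandwidthSearchError` when the floor ``h_min`` is
    reached without separation.
    """
    host = np.asarray(host_vectors, dtype=float)
    frag = np.array([f.counts for f in fragments], dtype=float)
    data = np.vstack([host, frag])
    artificial_ids = range(host.shape[0], data.shape[0])
    for h in search.grid():
        cfg = MeanShiftConfig(bandwidth=h, epsilon=epsilon,
                              max_iterations=max_iterations)
        clustering = run_mean_shift(data, kernel, cfg)
        sep = is_separated(clustering, artificial_ids, strict=strict)
        search.history.append(
            SearchStep(h=h, separated=sep, n_clusters=clustering.n_clusters)
        )
        logger.debug("bandwidth search: h=%.4g separated=%s clusters=%d",
                     h, sep, clustering.n_clusters)
        if sep:
            return h
    raise BandwidthSearchError(search.history)
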