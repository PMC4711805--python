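"""Genomic island calls from the final host-window clustering.

Genomic islands typically span 10–200 kb, and one donor can leave several
islands in one recipient genome, so the decision rule is applied at the
cluster level: any cluster whose total window mass does not surpass the cap
(default 200 kb) is called, regardless of whether its windows are
consecutive.  For reporting, each called cluster is split into maximal runs
of consecutive windows, one coordinate interval per run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .genome_windows import GenomeSequence, Window
from .mean_shift import Clustering

#: Default cluster-mass cap, bp.
DEFAULT_MAX_ISLAND_MASS = 200_000


@dataclass(frozen=True)
class GenomicIsland:
    """A predicted island interval [start, end) on the host genome."""

    identifier: str
    start: int
    end: int
    member_windows: tuple[int, ...]
    mass: int
    cluster_id: int

    def to_mb(self) -> str:
        """Coordinate range in Mb, 3 decimals, e.g. '1.800–2.000'."""
        return f"{self.start / 1e6:.3f}–{self.end / 1e6:.3f}"


@dataclass
class GIReport:
    """The full prediction output for one genome."""

    genome_id: str
    genome_length: int
    params: dict
    islands: list[GenomicIsland]
    warnings: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [
            f"# islandshift genomic island report",
            f"# genome: {self.genome_id} ({self.genome_length / 1e6:.3f} Mb)",
        ]
        for k, v in self.params.items():
            lines.append(f"# {k}: {v}")
        for w in self.warnings:
            lines.append(f"# WARNING: {w}")
        if not self.islands:
            lines.append("no genomic islands detected")
        else:
            lines.append("identifier\tinterval_mb\tstart_bp\tend_bp\tmass_bp")
            for isl in self.islands:
                lines.append(
                    f"{isl.identifier}\t{isl.to_mb()}\t{isl.start}\t"
                    f"{isl.end}\t{isl.mass}"
                )
        return "\n".join(lines) + "\n"

    def to_bed(self) -> str:
        """BED (0-based, half-open): chrom, start, end, name."""
        lines = [
            f"{self.genome_id}\t{isl.start}\t{isl.end}\t{isl.identifier}"
            for isl in self.islands
        ]
        return "\n".join(lines) + ("\n" if lines else "")

    def params_json(self) -> str:
        return json.dumps(self.params, indent=2, sort_keys=True) + "\n"


def _consecutive_runs(indices: np.ndarray) -> list[list[int]]:
    runs: list[list[int]] = []
    for i in sorted(int(v) for v in indices):
        if runs and i == runs[-1][-1] + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    return runs


def call_islands(
    clustering: Clustering,
    windows: list[Window],
    max_mass: int = DEFAULT_MAX_ISLAND_MASS,
) -> list[GenomicIsland]:
    """Low-mass clusters become islands; runs of consecutive windows
    become the reported intervals.

    The mass test applies to the whole cluster (sum over all its windows,
    contiguous or not); a cluster over the cap contributes nothing even if
    one of its runs is small.  Partial trailing windows count their true
    length.  The clustering must cover host windows only.
    """
    if len(windows) != len(clustering.labels):
        raise ValueError(
            "clustering must label exactly the host windows "
            f"({len(clustering.labels)} labels vs {len(windows)} windows)"
        )
    lengths = np.array([w.length for w in windows], dtype=np.int64)
    islands: list[GenomicIsland] = []
    for cid in range(clustering.n_clusters):
        members = clustering.members(cid)
        cluster_mass = int(lengths[members].sum())
        if cluster_mass > max_mass:
            continue
        for run in _consecutive_runs(members):
            islands.append(
                GenomicIsland(
                    identifier="",  # assigned after sorting
                    start=windows[run[0]].start,
                    end=windows[run[-1]].end,
                    member_windows=tuple(run),
                    mass=int(lengths[run].sum()),
                    cluster_id=cid,
                )
            )
    islands.sort(key=lambda isl: isl.start)
    return [
        GenomicIsland(
            identifier=f"GI{i + 1:02d}",
            start=isl.start,
            end=isl.end,
            member_windows=isl.member_windows,
            mass=isl.mass,
            cluster_id=isl.cluster_id,
        )
        for i, isl in enumerate(islands)
    ]


def format_report(
    islands: list[GenomicIsland],
    genome: GenomeSequence,
    params: dict,
    warnings: list[str] | None = None,
) -> GIReport:
    """Bundle islands, genome identity and run parameters into a report."""
    return GIReport(
        genome_id=genome.id,
        genome_length=genome.length,
        params=dict(params),
        islands=list(islands),
        warnings=list(warnings or []),
    )
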