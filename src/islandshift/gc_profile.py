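"""Cumulative G+C profile for visualising predicted islands.

The curve accumulates +1 per A/T and -1 per G/C along the genome and then
removes the least-squares linear trend, so a genome of uniform composition
maps to a flat line.  A region of composition different from the genome
average shows up as a segment of non-zero slope bounded by slope breaks:
a jump marks an abrupt G+C decrease, a fall an increase.  Inside a real
island the composition is typically homogeneous, so the segment is close
to straight.

Visualisation only — island calls never depend on this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_windows import GenomeSequence


@dataclass
class GCProfile:
    """Sampled, detrended cumulative AT-minus-GC curve."""

    positions: np.ndarray   # bp grid, strictly increasing
    cumulative: np.ndarray  # detrended running sum, one value per position
    highlighted: list[tuple[int, int]] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["position\tvalue"]
        lines += [f"{int(p)}\t{v:.6g}"
                  for p, v in zip(self.positions, self.cumulative)]
        return "\n".join(lines) + "\n"


def gc_cumulative(genome: GenomeSequence, step: int = 1000) -> GCProfile:
    """Running AT-minus-GC sum sampled every *step* bp, linearly detrended.

    N bases contribute 0.  The least-squares line through the sampled
    points is subtracted, so the genome-average composition maps to a flat
    trend and compositional anomalies appear as sloped segments.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    arr = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8)
    u = np.zeros(arr.shape[0], dtype=np.int8)
    u[(arr == ord("A")) | (arr == ord("T"))] = 1
    u[(arr == ord("G")) | (arr == ord("C"))] = -1
    S = np.cumsum(u, dtype=np.int64)
    L = genome.length
    positions = np.arange(step, L + 1, step, dtype=np.int64)
    if positions.size == 0 or positions[-1] != L:
        positions = np.append(positions, L)
    samples = S[positions - 1].astype(float)
    if positions.size >= 2:
        slope, intercept = np.polyfit(positions.astype(float), samples, 1)
        detrended = samples - (slope * positions + intercept)
    else:
        detrended = samples - samples
    return GCProfile(positions=positions, cumulative=detrended)


def plot_profile(
    profile: GCProfile,
    islands,
    path: str | Path,
) -> Path:
    """Line plot of the profile with island intervals highlighted.

    *islands* is a list of objects with ``start``/``end`` attributes (or
    (start, end) tuples).  Written to *path* (format from the suffix).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.plot(profile.positions / 1e6, profile.cumulative,
            color="0.35", lw=0.8, label="cumulative AT−GC (detrended)")
    for isl in islands:
        s, e = (isl.start, isl.end) if hasattr(isl, "start") else isl
        ax.axvspan(s / 1e6, e / 1e6, color="black", alpha=0.25)
        sel = (profile.positions >= s) & (profile.positions <= e)
        ax.plot(profile.positions[sel] / 1e6, profile.cumulative[sel],
                color="black", lw=1.6)
    ax.set_xlabel("genome position (Mb)")
    ax.set_ylabel("cumulative AT−GC (detrended)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
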