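"""Per-sample chromosome dot plots of windowed breadth of coverage.

One dot per window (x = chromosomal position, y = percent of bases covered),
colored black where coverage is as expected (NONE), red where unexpectedly
low (LOW) and blue where unexpectedly high (HIGH).  Homoeologous
chromosomes (same leading group number) share a panel row so substitutions
stand out as a paired deficit/excess.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .caller import HIGH, LOW, CallTrack
from .genome_windows import homoeologous_group

LABEL_COLORS = {0: "black", LOW: "red", HIGH: "blue"}

__all__ = ["plot_sample", "LABEL_COLORS"]


def plot_sample(
    track: CallTrack,
    chromosomes: list[str] | None = None,
    path=None,
    dot_size: float = 4.0,
):
    """Dot plot of a call track; returns the matplotlib Figure.

    ``chromosomes`` restricts the plot; unknown names are rejected.  When
    ``path`` is given the figure is also written there (PNG/SVG by suffix)
    with deterministic metadata.
    """
    grid = track.grid
    known = [c.name for c in grid.chromosomes]
    if chromosomes is None:
        chromosomes = known
    else:
        unknown = [c for c in chromosomes if c not in known]
        if unknown:
            raise ValueError(f"unknown chromosomes: {unknown}")

    groups: dict[object, list[str]] = {}
    for name in chromosomes:
        groups.setdefault(homoeologous_group(name), []).append(name)
    group_keys = sorted(groups, key=lambda g: (g is None, g))

    n_rows = len(group_keys)
    fig, axes = plt.subplots(
        n_rows, 1, figsize=(10, 1.8 * n_rows), squeeze=False, constrained_layout=True
    )
    for row, gk in enumerate(group_keys):
        ax = axes[row][0]
        offset = 0
        ticks, tick_labels = [], []
        for name in groups[gk]:
            sl = grid.chrom_slice(name)
            x = offset + (grid.starts[sl] + grid.ends[sl]) / 2
            y = track.values[sl] * 100.0
            colors = [LABEL_COLORS[int(l)] for l in track.labels[sl]]
            ax.scatter(x / 1e6, y, s=dot_size, c=colors, linewidths=0)
            length = grid.chrom(name).length
            ticks.append((offset + length / 2) / 1e6)
            tick_labels.append(name)
            offset += length
            ax.axvline(offset / 1e6, color="0.8", lw=0.8)
        ax.set_xticks(ticks)
        ax.set_xticklabels(tick_labels)
        ax.set_ylabel("% bases covered")
        ax.set_xlim(0, offset / 1e6)
    axes[-1][0].set_xlabel("position (Mb)")
    fig.suptitle(track.sample)
    if path is not None:
        fig.savefig(path, dpi=150, metadata=_deterministic_metadata(str(path)))
    return fig


def _deterministic_metadata(path: str) -> dict:
    if path.endswith(".png"):
        return {"Software": "introscan"}
    if path.endswith(".svg"):
        return {"Date": None}
    return {}
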