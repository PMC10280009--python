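"""Genome window grids and the tabular/interval formats the pipeline touches.

The whole pipeline indexes into a :class:`WindowGrid`: a partition of every
chromosome into fixed-size windows (default 1 Mb), 0-based half-open, with the
trailing partial window retained so telomeric ends are not blind spots.
Chromosomes carry a subgenome tag (e.g. ``A``/``B``/``D`` for hexaploid wheat)
and a donor flag marking chromosomes appended from a donor assembly
(e.g. rye ``1R``..``7R`` in a concatenated host+donor reference).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

DEFAULT_WINDOW_SIZE = 1_000_000

__all__ = [
    "GenomeSpec",
    "WindowGrid",
    "build_grid",
    "homoeologous_group",
    "read_genome_table",
    "write_genome_table",
    "read_profile_table",
    "write_profile_table",
    "write_calls_bed",
    "read_calls_bed",
]


@dataclass(frozen=True)
class GenomeSpec:
    """One chromosome of the (possibly concatenated host+donor) assembly."""

    name: str
    length: int
    subgenome: str = ""
    is_donor: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r}: length must be positive, got {self.length}")


def homoeologous_group(chromosome: str) -> int | None:
    """Homoeologous group number parsed as the first digit run in the name.

    ``chr1B`` -> 1, ``1R`` -> 1, ``scaffold_12`` -> 12; None when no digits.
    """
    m = re.search(r"\d+", chromosome)
    return int(m.group()) if m else None


class WindowGrid:
    """Fixed-size tiling of a genome; the coordinate system for all profiles.

    Windows are 0-based half-open, contiguous and non-overlapping within each
    chromosome, with global indices running consecutively in chromosome order.
    """

    def __init__(self, chromosomes: Sequence[GenomeSpec], window_size: int = DEFAULT_WINDOW_SIZE):
        if window_size <= 0:
            raise ValueError(f"window_size must be positive, got {window_size}")
        if not chromosomes:
            raise ValueError("genome is empty: at least one chromosome required")
        names = [c.name for c in chromosomes]
        for name in names:
            if names.count(name) > 1:
                raise ValueError(f"duplicate chromosome name {name!r}")
        self.chromosomes: tuple[GenomeSpec, ...] = tuple(chromosomes)
        self.window_size = int(window_size)

        chrom_idx, starts, ends = [], [], []
        self._slices: dict[str, slice] = {}
        pos = 0
        for ci, chrom in enumerate(self.chromosomes):
            n_win = -(-chrom.length // window_size)  # ceil
            s = np.arange(n_win, dtype=np.int64) * window_size
            e = np.minimum(s + window_size, chrom.length)
            chrom_idx.append(np.full(n_win, ci, dtype=np.int32))
            starts.append(s)
            ends.append(e)
            self._slices[chrom.name] = slice(pos, pos + n_win)
            pos += n_win
        self.chrom_index = np.concatenate(chrom_idx)
        self.starts = np.concatenate(starts)
        self.ends = np.concatenate(ends)

    # -- basic geometry -------------------------------------------------

    @property
    def n_windows(self) -> int:
        return self.starts.size

    @property
    def window_lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def chrom_names(self) -> np.ndarray:
        names = np.array([c.name for c in self.chromosomes], dtype=object)
        return names[self.chrom_index]

    @property
    def subgenomes(self) -> np.ndarray:
        tags = np.array([c.subgenome for c in self.chromosomes], dtype=object)
        return tags[self.chrom_index]

    @property
    def donor_mask(self) -> np.ndarray:
        flags = np.array([c.is_donor for c in self.chromosomes], dtype=bool)
        return flags[self.chrom_index]

    def chrom_slice(self, name: str) -> slice:
        try:
            return self._slices[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} not in grid") from None

    def chrom(self, name: str) -> GenomeSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"chromosome {name!r} not in grid")

    def windows(self) -> Iterator[tuple[str, int, int, int]]:
        """Yield (chromosome, start, end, global index) in grid order."""
        names = self.chrom_names
        for i in range(self.n_windows):
            yield names[i], int(self.starts[i]), int(self.ends[i]), i

    def window_index(self, chromosome: str, start: int) -> int:
        sl = self.chrom_slice(chromosome)
        off = start // self.window_size
        idx = sl.start + off
        if idx >= sl.stop or int(self.starts[idx]) != start:
            raise KeyError(f"no window at {chromosome}:{start}")
        return idx

    def overlapping_windows(self, chromosome: str, start: int, end: int) -> slice:
        """Global-index slice of windows intersecting [start, end)."""
        sl = self.chrom_slice(chromosome)
        if end <= start:
            return slice(sl.start, sl.start)
        first = sl.start + start // self.window_size
        last = sl.start + (end - 1) // self.window_size
        return slice(max(first, sl.start), min(last + 1, sl.stop))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, WindowGrid)
            and self.window_size == other.window_size
            and self.chromosomes == other.chromosomes
        )

    def __repr__(self) -> str:
        return (
            f"WindowGrid({len(self.chromosomes)} chromosomes, "
            f"{self.n_windows} windows of {self.window_size} bp)"
        )


def build_grid(genome: Iterable[GenomeSpec], window_size: int = DEFAULT_WINDOW_SIZE) -> WindowGrid:
    """Tile every chromosome completely; trailing partial windows are kept."""
    return WindowGrid(list(genome), window_size)


# -- genome spec tables -------------------------------------------------


def read_genome_table(path) -> list[GenomeSpec]:
    """Read a genome spec TSV: columns name, length[, subgenome[, donor]]."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "name" not in cols or "length" not in cols:
        raise ValueError(f"genome table {path} must have columns 'name' and 'length'")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            GenomeSpec(
                name=str(row.name),
                length=int(row.length),
                subgenome=str(getattr(row, "subgenome", "") or ""),
                is_donor=bool(getattr(row, "donor", False)),
            )
        )
    return out


def write_genome_table(chromosomes: Sequence[GenomeSpec], path) -> None:
    pd.DataFrame(
        {
            "name": [c.name for c in chromosomes],
            "length": [c.length for c in chromosomes],
            "subgenome": [c.subgenome for c in chromosomes],
            "donor": [c.is_donor for c in chromosomes],
        }
    ).to_csv(path, sep="\t", index=False)


# -- coverage profile tables --------------------------------------------

PROFILE_COLUMNS = ["sample", "chromosome", "start", "end", "fraction_covered"]


def write_profile_table(profile, path) -> None:
    """Write a per-window breadth profile as TSV (full float precision)."""
    grid = profile.grid
    df = pd.DataFrame(
        {
            "sample": profile.sample,
            "chromosome": grid.chrom_names,
            "start": grid.starts,
            "end": grid.ends,
            "fraction_covered": profile.values,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_profile_table(path, grid: WindowGrid):
    """Read one sample's breadth profile; rows must match the grid exactly."""
    from .coverage import CoverageProfile  # cycle-free at call time

    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str}, float_precision="round_trip")
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile table {path} lacks columns {missing}")
    samples = df["sample"].unique()
    if len(samples) != 1:
        raise ValueError(f"profile table {path} holds {len(samples)} samples; expected exactly one")
    values = np.full(grid.n_windows, np.nan)
    for row in df.itertuples(index=False):
        try:
            idx = grid.window_index(row.chromosome, int(row.start))
        except KeyError:
            raise ValueError(
                f"window {row.chromosome}:{row.start} in {path} does not match the grid"
            ) from None
        if int(row.end) != int(grid.ends[idx]):
            raise ValueError(
                f"window {row.chromosome}:{row.start}-{row.end} in {path} does not match the grid"
            )
        values[idx] = row.fraction_covered
    if np.isnan(values).any():
        i = int(np.flatnonzero(np.isnan(values))[0])
        raise ValueError(
            f"profile table {path} misses grid window {grid.chrom_names[i]}:{grid.starts[i]}"
        )
    return CoverageProfile(sample=str(samples[0]), grid=grid, values=values)


def grid_from_profile_table(path) -> WindowGrid:
    """Reconstruct the window grid implied by a complete profile table."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    window_size = int((df["end"] - df["start"]).max())
    chroms = []
    for name, sub in df.groupby("chromosome", sort=False):
        chroms.append(GenomeSpec(name=str(name), length=int(sub["end"].max())))
    return build_grid(chroms, window_size)


# -- call interval output ------------------------------------------------

BED_HEADER = "#chrom\tstart\tend\tname\tscore\tstrand"


def write_calls_bed(calls, path) -> None:
    """Write introgression calls as BED (0-based half-open).

    The name field encodes ``sample|label``; score is the window count.
    Lines are sorted by chromosome then start.
    """
    lines = [BED_HEADER]
    for call in sorted(calls, key=lambda c: (c.chromosome, c.start)):
        lines.append(
            f"{call.chromosome}\t{call.start}\t{call.end}\t"
            f"{call.sample}|{call.label}\t{call.n_windows}\t."
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_calls_bed(path) -> pd.DataFrame:
    """Parse a calls BED back into a DataFrame (chromosome/start/end/sample/label)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end, name = line.split("\t")[:4]
            sample, _, label = name.rpartition("|")
            rows.append((chrom, int(start), int(end), sample, label))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "sample", "label"])
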