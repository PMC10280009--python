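"""Per-window breadth of coverage from filtered alignments.

Breadth ("percentage of bases covered") of a window is the fraction of its
reference positions overlapped by at least one retained aligned base.  Reads
failing the FLAG filter (default 2308 = unmapped + secondary + supplementary,
the samtools ``-F 2308`` convention) contribute nothing.  Only CIGAR
operations that align read bases to the reference (M, =, X) cover positions;
deletions and skips (D, N) consume reference without covering it.

Also provides per-subgenome summaries used to tag samples that lack coverage
across a whole subgenome (non-hexaploid material in a wheat collection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pysam

from .genome_windows import WindowGrid

DEFAULT_EXCLUDE_FLAGS = 2308  # unmapped (4) | secondary (256) | supplementary (2048)

# CIGAR ops covering reference positions: M=0, EQUAL=7, DIFF=8
_COVERING_OPS = {0, 7, 8}
# ops consuming reference: M, D, N, =, X
_REF_CONSUMING = {0, 2, 3, 7, 8}

__all__ = [
    "CoverageProfile",
    "SubgenomeSummary",
    "compute_window_breadth",
    "chromosome_medians",
    "chromosome_median_ratio",
    "subgenome_medians",
    "flag_missing_genome",
]


@dataclass
class CoverageProfile:
    """Per-sample vector of fraction-of-bases-covered, one value per window."""

    sample: str
    grid: WindowGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_windows,):
            raise ValueError(
                f"profile has {self.values.size} values for {self.grid.n_windows} grid windows"
            )
        if np.any((self.values < 0) | (self.values > 1)):
            bad = self.values[(self.values < 0) | (self.values > 1)][0]
            raise ValueError(f"fraction covered outside [0,1]: {bad}")

    def scaled(self, factor: float) -> "CoverageProfile":
        """Profile multiplied by a positive constant, clipped to [0,1]."""
        return CoverageProfile(self.sample, self.grid, np.clip(self.values * factor, 0.0, 1.0))


@dataclass
class SubgenomeSummary:
    """Median breadth per subgenome and the tags flagged as missing."""

    sample: str
    medians: dict[str, float]
    missing_tags: list[str] = field(default_factory=list)


def compute_window_breadth(
    alignments,
    grid: WindowGrid,
    flag_exclude: int = DEFAULT_EXCLUDE_FLAGS,
    sample: str | None = None,
) -> CoverageProfile:
    """Breadth per grid window from a coordinate-sorted SAM/BAM.

    Parameters
    ----------
    alignments
        Path to a SAM/BAM file or an open :class:`pysam.AlignmentFile`,
        coordinate-sorted against the same reference the grid describes.
    grid
        Window grid whose chromosome names must cover the alignment header.
    flag_exclude
        FLAG bitmask; any record with an overlapping bit is discarded
        (default 2308).
    """
    own = isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__")
    af = pysam.AlignmentFile(str(alignments)) if own else alignments
    try:
        header_names = list(af.references)
        unknown = [n for n in header_names if n not in {c.name for c in grid.chromosomes}]
        if unknown:
            raise ValueError(f"alignment reference names absent from the grid: {unknown}")

        covered: dict[str, np.ndarray] = {}
        last = (-1, -1)
        for read in af:
            if read.flag & flag_exclude:
                continue
            if read.reference_id < 0 or read.cigartuples is None:
                continue
            key = (read.reference_id, read.reference_start)
            if key < last:
                raise ValueError("alignments are not coordinate-sorted")
            last = key
            rname = header_names[read.reference_id]
            if rname not in covered:
                covered[rname] = np.zeros(grid.chrom(rname).length, dtype=bool)
            mask = covered[rname]
            pos = read.reference_start
            for op, length in read.cigartuples:
                if op in _COVERING_OPS:
                    mask[pos : pos + length] = True
                if op in _REF_CONSUMING:
                    pos += length
    finally:
        if own:
            af.close()

    values = np.zeros(grid.n_windows)
    for name, mask in covered.items():
        sl = grid.chrom_slice(name)
        counts = np.add.reduceat(mask.astype(np.int64), grid.starts[sl])
        values[sl] = counts / grid.window_lengths[sl]
    sid = sample if sample is not None else "sample"
    return CoverageProfile(sample=sid, grid=grid, values=values)


def chromosome_medians(profile: CoverageProfile) -> dict[str, float]:
    """Median window breadth per chromosome."""
    out = {}
    for chrom in profile.grid.chromosomes:
        out[chrom.name] = float(np.median(profile.values[profile.grid.chrom_slice(chrom.name)]))
    return out


def chromosome_median_ratio(profile: CoverageProfile, chrom_a: str, chrom_b: str) -> float:
    """Ratio of median breadth of ``chrom_a`` to ``chrom_b``.

    The diagnostic used to gauge how similar an introgressed chromosome is to
    the segment it replaced: a depleted chromosome's median breadth divided by
    an unaffected homoeologue's.  Smaller ratios indicate a more distant donor.
    """
    med = chromosome_medians(profile)
    if med[chrom_b] == 0:
        raise ValueError(f"median breadth of {chrom_b} is zero; ratio undefined")
    return med[chrom_a] / med[chrom_b]


def subgenome_medians(profile: CoverageProfile) -> SubgenomeSummary:
    """Median breadth per subgenome over non-donor chromosomes."""
    grid = profile.grid
    tags = grid.subgenomes
    donor = grid.donor_mask
    medians: dict[str, float] = {}
    seen = []
    for t in tags:
        if t not in seen:
            seen.append(t)
    for tag in seen:
        sel = (tags == tag) & ~donor
        if not sel.any():
            warnings.warn(f"subgenome {tag!r} has no non-donor windows; excluded")
            continue
        medians[tag] = float(np.median(profile.values[sel]))
    return SubgenomeSummary(sample=profile.sample, medians=medians)


def flag_missing_genome(summary: SubgenomeSummary, ratio_threshold: float = 0.25) -> list[str]:
    """Tag subgenomes whose median breadth collapses relative to the best one.

    A subgenome is flagged when its median is below ``ratio_threshold`` times
    the maximum subgenome median.  Samples with a flagged subgenome are not
    hexaploid wheat (e.g. tetraploid material lacking the D genome).
    """
    if len(summary.medians) < 2:
        raise ValueError("missing-genome flagging needs at least two summarized subgenomes")
    best = max(summary.medians.values())
    if best == 0:
        warnings.warn(f"sample {summary.sample}: all subgenome medians are zero; nothing flagged")
        summary.missing_tags = []
        return []
    tags = [t for t, m in summary.medians.items() if m < ratio_threshold * best]
    summary.missing_tags = tags
    return tags
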