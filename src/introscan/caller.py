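"""The four-step introgression caller.

An introgression shows up as a run of genomic windows whose breadth of
coverage deviates from the sample's expectation: a deficit (LOW) where reads
from the donor segment fail to map to the host reference, an excess (HIGH)
where reads from a substituted chromosome pile onto its homoeologue.  Calling
proceeds in four steps:

1. *Initial calling.*  WGS mode: a window is seeded when its breadth deviates
   from the genome-wide median by more than ``mad_multiplier`` times the
   median absolute deviation (MAD, scaled by 1.4826 by default).  GBS mode:
   sample and an external reference-genotype profile are each normalised by
   their own median, and a window is seeded when the relative deviation
   ``(s - r)/r`` exceeds ``relative_deviation_threshold`` in magnitude.
   GBS is reference-normalised because methylation-sensitive restriction
   enzymes make capture efficiency strongly position-dependent.
2. *Seed denoising.*  Same-label runs shorter than ``min_seed_run`` (5) are
   erased.
3. *Gap filling.*  A gap between two surviving runs of the same label is
   filled iff every gap window's step-1 deviation already has the matching
   sign (sub-threshold but consistent evidence).
4. *Size pruning.*  Runs shorter than ``min_call_windows`` (25, i.e. 25 Mb at
   1-Mb windows) are erased; only large introgressions survive.

Runs never cross chromosome boundaries at any step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coverage import CoverageProfile
from .genome_windows import WindowGrid

LOW = -1
NONE = 0
HIGH = 1
LABEL_NAMES = {LOW: "LOW", NONE: "NONE", HIGH: "HIGH"}
LABEL_CODES = {v: k for k, v in LABEL_NAMES.items()}

__all__ = [
    "LOW",
    "NONE",
    "HIGH",
    "LABEL_NAMES",
    "CallerParams",
    "CallTrack",
    "IntrogressionCall",
    "initial_call_wgs",
    "initial_call_gbs",
    "denoise_seeds",
    "fill_gaps",
    "prune_short",
    "extract_calls",
    "compute_call_track",
    "call_introgressions",
    "label_runs",
    "write_track_table",
    "read_track_table",
]


@dataclass(frozen=True)
class CallerParams:
    """Tunable thresholds of the four calling steps."""

    mad_multiplier: float = 1.5
    mad_scale_constant: float = 1.4826
    relative_deviation_threshold: float = 0.20
    min_seed_run: int = 5
    min_call_windows: int = 25

    def __post_init__(self) -> None:
        for name in (
            "mad_multiplier",
            "mad_scale_constant",
            "relative_deviation_threshold",
            "min_seed_run",
            "min_call_windows",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_call_windows < self.min_seed_run:
            raise ValueError("min_call_windows must be >= min_seed_run")


@dataclass
class CallTrack:
    """Per-window state: raw signed deviation, label, mask, and pipeline stage.

    ``deviation`` is the step-1 statistic (WGS: value minus overall median;
    GBS: relative deviation); NaN on masked windows.  ``masked`` windows are
    never labeled and block gap filling: donor chromosomes in WGS mode,
    reference-zero windows in GBS mode.
    """

    sample: str
    grid: WindowGrid
    values: np.ndarray
    deviation: np.ndarray
    labels: np.ndarray
    masked: np.ndarray
    stage: int = 1

    def copy(self) -> "CallTrack":
        return replace(
            self,
            values=self.values.copy(),
            deviation=self.deviation.copy(),
            labels=self.labels.copy(),
            masked=self.masked.copy(),
        )


@dataclass(frozen=True)
class IntrogressionCall:
    """A maximal labeled run surviving all four steps."""

    sample: str
    chromosome: str
    start: int
    end: int
    label: str  # "LOW" or "HIGH"
    n_windows: int
    size: int  # bases, = end - start
    mean_deviation: float


def label_runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs of a label vector as (start, stop, label)."""
    n = labels.size
    if n == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    bounds = np.concatenate(([0], change, [n]))
    return [
        (int(bounds[i]), int(bounds[i + 1]), int(labels[bounds[i]]))
        for i in range(bounds.size - 1)
    ]


def _per_chrom(grid: WindowGrid):
    for chrom in grid.chromosomes:
        yield chrom, grid.chrom_slice(chrom.name)


def initial_call_wgs(profile: CoverageProfile, params: CallerParams = CallerParams()) -> CallTrack:
    """Step 1, WGS mode: genome-wide median/MAD thresholding.

    The median and MAD are computed over non-donor windows only; donor
    chromosomes (present when mapping against a concatenated host+donor
    reference) are masked and never labeled.
    """
    grid = profile.grid
    if grid.n_windows < 2:
        raise ValueError("initial calling needs at least 2 windows")
    host = ~grid.donor_mask
    if not host.any():
        raise ValueError("grid has no non-donor windows")
    v = profile.values
    m = float(np.median(v[host]))
    mad = float(np.median(np.abs(v[host] - m))) * params.mad_scale_constant
    dev = v - m
    labels = np.zeros(grid.n_windows, dtype=np.int8)
    called = np.abs(dev) > params.mad_multiplier * mad  # strict: "larger than"
    labels[called & (dev < 0)] = LOW
    labels[called & (dev > 0)] = HIGH
    labels[~host] = NONE
    deviation = dev.astype(float)
    deviation[~host] = np.nan
    return CallTrack(
        sample=profile.sample,
        grid=grid,
        values=v.copy(),
        deviation=deviation,
        labels=labels,
        masked=~host,
        stage=1,
    )


def initial_call_gbs(
    profile: CoverageProfile,
    reference: CoverageProfile,
    params: CallerParams = CallerParams(),
) -> CallTrack:
    """Step 1, GBS mode: relative deviation against a reference-genotype profile.

    Both profiles are normalised by their own median breadth, which cancels
    library-size differences; the per-window capture-efficiency pattern of the
    restriction enzyme cancels in the ratio.  Windows where the reference has
    zero breadth are uncallable and masked.
    """
    grid = profile.grid
    if reference.grid != grid:
        raise ValueError("sample and reference profiles are on different grids")
    if grid.n_windows < 2:
        raise ValueError("initial calling needs at least 2 windows")
    med_v = float(np.median(profile.values))
    med_u = float(np.median(reference.values))
    if med_v == 0:
        raise ValueError(f"sample {profile.sample}: median breadth is zero; profile unusable")
    if med_u == 0:
        raise ValueError(f"reference {reference.sample}: median breadth is zero; profile unusable")
    s = profile.values / med_v
    r = reference.values / med_u
    masked = (r == 0) | grid.donor_mask
    dev = np.full(grid.n_windows, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev[~masked] = (s[~masked] - r[~masked]) / r[~masked]
    labels = np.zeros(grid.n_windows, dtype=np.int8)
    called = np.abs(dev) > params.relative_deviation_threshold  # strict; NaN -> False
    labels[called & (dev < 0)] = LOW
    labels[called & (dev > 0)] = HIGH
    return CallTrack(
        sample=profile.sample,
        grid=grid,
        values=profile.values.copy(),
        deviation=dev,
        labels=labels,
        masked=masked,
        stage=1,
    )


def denoise_seeds(track: CallTrack, params: CallerParams = CallerParams()) -> CallTrack:
    """Step 2: erase same-label runs shorter than ``min_seed_run``."""
    out = track.copy()
    for _, sl in _per_chrom(track.grid):
        lab = out.labels[sl]
        for start, stop, value in label_runs(lab):
            if value != NONE and stop - start < params.min_seed_run:
                lab[start:stop] = NONE
    out.stage = max(track.stage, 2)
    return out


def fill_gaps(track: CallTrack, params: CallerParams = CallerParams()) -> CallTrack:
    """Step 3: fill gaps between same-label runs when sub-threshold evidence agrees.

    The gap between two neighbouring surviving runs with the same label is
    relabeled iff *every* gap window's step-1 deviation has the sign the label
    implies (negative for LOW, positive for HIGH).  Zero or undefined
    (masked) deviations block filling.
    """
    out = track.copy()
    for _, sl in _per_chrom(track.grid):
        lab = out.labels[sl]
        dev = out.deviation[sl]
        runs = [r for r in label_runs(lab) if r[2] != NONE]
        for (s1, e1, v1), (s2, e2, v2) in zip(runs, runs[1:]):
            if v1 != v2 or e1 == s2:
                continue
            gap = dev[e1:s2]
            if np.isnan(gap).any():
                continue
            if v1 == LOW and np.all(gap < 0):
                lab[e1:s2] = LOW
            elif v1 == HIGH and np.all(gap > 0):
                lab[e1:s2] = HIGH
    out.stage = max(track.stage, 3)
    return out


def prune_short(track: CallTrack, params: CallerParams = CallerParams()) -> CallTrack:
    """Step 4: erase labeled runs shorter than ``min_call_windows``."""
    out = track.copy()
    for _, sl in _per_chrom(track.grid):
        lab = out.labels[sl]
        for start, stop, value in label_runs(lab):
            if value != NONE and stop - start < params.min_call_windows:
                lab[start:stop] = NONE
    out.stage = max(track.stage, 4)
    return out


def extract_calls(track: CallTrack) -> list[IntrogressionCall]:
    """Emit each maximal labeled run as one :class:`IntrogressionCall`."""
    calls = []
    grid = track.grid
    for chrom, sl in _per_chrom(grid):
        lab = track.labels[sl]
        dev = track.deviation[sl]
        starts = grid.starts[sl]
        ends = grid.ends[sl]
        for start, stop, value in label_runs(lab):
            if value == NONE:
                continue
            calls.append(
                IntrogressionCall(
                    sample=track.sample,
                    chromosome=chrom.name,
                    start=int(starts[start]),
                    end=int(ends[stop - 1]),
                    label=LABEL_NAMES[value],
                    n_windows=stop - start,
                    size=int(ends[stop - 1] - starts[start]),
                    mean_deviation=float(np.nanmean(dev[start:stop])),
                )
            )
    return calls


def compute_call_track(
    profile: CoverageProfile,
    mode: str = "wgs",
    reference: CoverageProfile | None = None,
    params: CallerParams = CallerParams(),
) -> CallTrack:
    """Run all four steps and return the final per-window track."""
    if mode == "wgs":
        track = initial_call_wgs(profile, params)
    elif mode == "gbs":
        if reference is None:
            raise ValueError("GBS mode requires a reference-genotype profile (--reference)")
        track = initial_call_gbs(profile, reference, params)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'wgs' or 'gbs'")
    track = denoise_seeds(track, params)
    track = fill_gaps(track, params)
    track = prune_short(track, params)
    return track


def call_introgressions(
    profile: CoverageProfile,
    mode: str = "wgs",
    reference: CoverageProfile | None = None,
    params: CallerParams = CallerParams(),
) -> list[IntrogressionCall]:
    """Four-step calling: step1(mode) -> denoise -> fill -> prune -> calls."""
    return extract_calls(compute_call_track(profile, mode, reference, params))


# -- per-window track tables ---------------------------------------------

TRACK_COLUMNS = ["sample", "chromosome", "start", "end", "value", "deviation", "label"]


def write_track_table(track: CallTrack, path) -> None:
    """Per-window TSV of value, raw deviation and final label (1-Mb-resolution release format)."""
    grid = track.grid
    pd.DataFrame(
        {
            "sample": track.sample,
            "chromosome": grid.chrom_names,
            "start": grid.starts,
            "end": grid.ends,
            "value": track.values,
            "deviation": track.deviation,
            "label": [LABEL_NAMES[int(l)] for l in track.labels],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_track_table(path, grid: WindowGrid) -> CallTrack:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str}, float_precision="round_trip")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track table {path} lacks columns {missing}")
    samples = df["sample"].unique()
    if len(samples) != 1:
        raise ValueError(f"track table {path} holds {len(samples)} samples; expected one")
    n = grid.n_windows
    values = np.full(n, np.nan)
    dev = np.full(n, np.nan)
    labels = np.zeros(n, dtype=np.int8)
    for row in df.itertuples(index=False):
        try:
            idx = grid.window_index(row.chromosome, int(row.start))
        except KeyError:
            raise ValueError(
                f"window {row.chromosome}:{row.start} in {path} does not match the grid"
            ) from None
        values[idx] = row.value
        dev[idx] = row.deviation
        labels[idx] = LABEL_CODES[str(row.label)]
    if np.isnan(values).any():
        raise ValueError(f"track table {path} does not cover the full grid")
    return CallTrack(
        sample=str(samples[0]),
        grid=grid,
        values=values,
        deviation=dev,
        labels=labels,
        masked=np.isnan(dev),
        stage=4,
    )
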