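"""Synthetic coverage profiles, truth sets, and toy SAM fixtures.

Two fidelity tiers:

* **Profile level** — window breadth drawn as
  ``clip(baseline * capture_efficiency * segment_factor + noise, 0, 1)``
  with truncated-Gaussian noise.  LOW segments scale breadth by a
  donor-similarity factor (a distant donor retains little mappable sequence,
  so similarity 0.3 leaves 30% of the baseline breadth); HIGH segments scale
  it up by the reciprocal (capped so the noise-free value stays <= 1);
  a "substitution" pairs a LOW segment with a HIGH segment on a designated
  homoeologue, modeling a whole-chromosome substitution whose reads pile onto
  the most similar host chromosome.  In GBS mode a matched reference profile
  shares the per-window capture-efficiency field (restriction-site density
  and methylation pattern are properties of the genome, not the sample) but
  draws its own noise.

* **Read level** — toy SAM text with placed primary alignments plus decoy
  secondary/supplementary records, and a uniform read subsampler, so the
  coverage module and depth-titration experiments can be exercised end to end.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .caller import CallerParams, call_introgressions
from .coverage import CoverageProfile
from .genome_windows import GenomeSpec, WindowGrid, build_grid

__all__ = [
    "Segment",
    "SimulationConfig",
    "SimulationResult",
    "simulate_profile",
    "make_capture_field",
    "simulate_toy_sam",
    "subsample_reads",
    "depth_titration",
    "minimum_detectable_reads",
    "config_from_dict",
    "write_truth_bed",
]

# Study-condition defaults: windowed breadth around 10% of bases covered per
# 1-Mb window is typical of the low-pass regimes targeted (GBS / ulcWGS), with
# per-window noise an order of magnitude below the baseline.
DEFAULT_BASELINE = 0.10
DEFAULT_NOISE_SD = 0.01

# Toy scale: 3 "subgenomes" x 2 chromosomes x 100 windows of 10 kb.
TOY_SUBGENOMES = ("A", "B", "D")
TOY_CHROMS_PER_SUBGENOME = 2
TOY_WINDOWS_PER_CHROM = 100
TOY_WINDOW_SIZE = 10_000


@dataclass(frozen=True)
class Segment:
    """One implanted introgression segment.

    kind 'LOW': breadth deficit (donor material absent from the reference);
    kind 'HIGH': breadth excess; kind 'substitution': LOW here plus HIGH on
    the homoeologous ``partner`` chromosome.
    """

    chromosome: str
    start_window: int
    n_windows: int
    kind: str = "LOW"
    similarity: float = 0.5
    partner: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("LOW", "HIGH", "substitution"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not (0 < self.similarity <= 1):
            raise ValueError(f"similarity must be in (0, 1], got {self.similarity}")
        if self.kind == "substitution" and self.partner is None:
            raise ValueError("substitution segments need a partner chromosome")
        if self.n_windows <= 0 or self.start_window < 0:
            raise ValueError("segment must have positive extent within the chromosome")


def toy_genome(
    n_subgenomes: int = len(TOY_SUBGENOMES),
    chroms_per_subgenome: int = TOY_CHROMS_PER_SUBGENOME,
    windows_per_chrom: int = TOY_WINDOWS_PER_CHROM,
    window_size: int = TOY_WINDOW_SIZE,
    donor_subgenome: str | None = None,
) -> list[GenomeSpec]:
    """Desk-scale genome: chromosomes named <group><tag>, e.g. 1A, 2A, 1B ..."""
    chroms = []
    for si in range(n_subgenomes):
        tag = TOY_SUBGENOMES[si] if si < len(TOY_SUBGENOMES) else chr(ord("A") + si)
        for g in range(1, chroms_per_subgenome + 1):
            chroms.append(
                GenomeSpec(f"{g}{tag}", windows_per_chrom * window_size, subgenome=tag)
            )
    if donor_subgenome:
        for g in range(1, chroms_per_subgenome + 1):
            chroms.append(
                GenomeSpec(
                    f"{g}{donor_subgenome}",
                    windows_per_chrom * window_size,
                    subgenome=donor_subgenome,
                    is_donor=True,
                )
            )
    return chroms


@dataclass
class SimulationConfig:
    chromosomes: list[GenomeSpec] = field(default_factory=toy_genome)
    window_size: int = TOY_WINDOW_SIZE
    baseline: float = DEFAULT_BASELINE
    noise_sd: float = DEFAULT_NOISE_SD
    capture_efficiency: np.ndarray | None = None
    segments: list[Segment] = field(default_factory=list)
    mode: str = "wgs"
    seed: int = 0
    sample: str = "sim"

    def __post_init__(self) -> None:
        if not (0 <= self.baseline <= 1):
            raise ValueError(f"baseline must be in [0,1], got {self.baseline}")
        if self.mode not in ("wgs", "gbs"):
            raise ValueError(f"mode must be 'wgs' or 'gbs', got {self.mode!r}")


@dataclass
class SimulationResult:
    profile: CoverageProfile
    reference: CoverageProfile | None
    truth: pd.DataFrame
    grid: WindowGrid


def make_capture_field(
    grid: WindowGrid,
    rng: np.random.Generator,
    end_depression: float = 0.7,
    end_fraction: float = 0.15,
    jitter_sd: float = 0.1,
) -> np.ndarray:
    """Per-window capture-efficiency field in [0, 1] for GBS simulations.

    Methylation-sensitive restriction enzymes deplete telomeric and
    centromeric windows, modeled as cosine-shaped dips of depth
    ``end_depression`` over the terminal ``end_fraction`` of each chromosome
    and around its midpoint, plus multiplicative log-normal jitter.
    """
    eff = np.ones(grid.n_windows)
    for chrom in grid.chromosomes:
        sl = grid.chrom_slice(chrom.name)
        n = sl.stop - sl.start
        x = np.arange(n)
        dip = np.zeros(n)
        w = max(1, int(round(end_fraction * n)))
        ramp = 0.5 * (1 + np.cos(np.pi * np.arange(w) / w))  # 1 -> 0
        dip[:w] = np.maximum(dip[:w], end_depression * ramp)
        dip[n - w :] = np.maximum(dip[n - w :], end_depression * ramp[::-1])
        mid = n // 2
        half = max(1, w // 2)
        lo, hi = max(0, mid - half), min(n, mid + half)
        centro = 0.5 * (1 + np.cos(np.pi * (np.arange(lo, hi) - mid) / half))
        dip[lo:hi] = np.maximum(dip[lo:hi], end_depression * centro)
        eff[sl] = 1.0 - dip
    eff *= np.exp(rng.normal(0.0, jitter_sd, grid.n_windows))
    return np.clip(eff, 0.0, 1.0)


def _segment_factors(config: SimulationConfig, grid: WindowGrid) -> tuple[np.ndarray, pd.DataFrame]:
    """Noise-free multiplicative factor per window plus the truth table."""
    factors = np.ones(grid.n_windows)
    occupied: dict[str, np.ndarray] = {
        c.name: np.zeros(len(range(grid.chrom_slice(c.name).start, grid.chrom_slice(c.name).stop)), dtype=bool)
        for c in grid.chromosomes
    }
    truth_rows = []

    def place(chrom: str, start_w: int, n_w: int, kind: str, similarity: float, seg_id: int):
        sl = grid.chrom_slice(chrom)
        n_chrom = sl.stop - sl.start
        if start_w + n_w > n_chrom:
            raise ValueError(
                f"segment {seg_id} exceeds chromosome {chrom} ({start_w}+{n_w} > {n_chrom} windows)"
            )
        occ = occupied[chrom][start_w : start_w + n_w]
        if occ.any():
            raise ValueError(f"overlapping segments on chromosome {chrom}")
        occupied[chrom][start_w : start_w + n_w] = True
        if kind == "LOW":
            factor = similarity
        else:  # HIGH
            cap = (1.0 / config.baseline) if config.baseline > 0 else np.inf
            factor = min(1.0 / similarity, cap)
        factors[sl.start + start_w : sl.start + start_w + n_w] = factor
        truth_rows.append(
            {
                "segment_id": seg_id,
                "chromosome": chrom,
                "start": int(grid.starts[sl.start + start_w]),
                "end": int(grid.ends[sl.start + start_w + n_w - 1]),
                "kind": kind,
                "similarity": similarity,
            }
        )

    for i, seg in enumerate(config.segments):
        if seg.kind == "substitution":
            place(seg.chromosome, seg.start_window, seg.n_windows, "LOW", seg.similarity, i)
            place(seg.partner, seg.start_window, seg.n_windows, "HIGH", seg.similarity, i)
        else:
            place(seg.chromosome, seg.start_window, seg.n_windows, seg.kind, seg.similarity, i)

    truth = pd.DataFrame(
        truth_rows,
        columns=["segment_id", "chromosome", "start", "end", "kind", "similarity"],
    )
    return factors, truth


def simulate_profile(config: SimulationConfig) -> SimulationResult:
    """Draw a breadth profile (and, in GBS mode, a matched reference) plus truth.

    Deterministic given ``config.seed``; the reference shares the
    capture-efficiency field with the sample but has its own noise draw and
    no implanted segments.
    """
    grid = build_grid(config.chromosomes, config.window_size)
    rng = np.random.default_rng(config.seed)
    eff = (
        np.asarray(config.capture_efficiency, dtype=float)
        if config.capture_efficiency is not None
        else np.ones(grid.n_windows)
    )
    if eff.shape != (grid.n_windows,):
        raise ValueError("capture_efficiency must hold one factor per grid window")
    factors, truth = _segment_factors(config, grid)

    clean = config.baseline * eff * factors
    values = np.clip(clean + rng.normal(0.0, config.noise_sd, grid.n_windows), 0.0, 1.0)
    profile = CoverageProfile(sample=config.sample, grid=grid, values=values)

    reference = None
    if config.mode == "gbs":
        ref_clean = config.baseline * eff
        ref_values = np.clip(
            ref_clean + rng.normal(0.0, config.noise_sd, grid.n_windows), 0.0, 1.0
        )
        reference = CoverageProfile(sample="reference", grid=grid, values=ref_values)
    return SimulationResult(profile=profile, reference=reference, truth=truth, grid=grid)


def write_truth_bed(truth: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for row in truth.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\t{row.start}\t{row.end}\t"
                f"seg{row.segment_id}|{row.kind}|{row.similarity}\t0\t.\n"
            )


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a config from a parsed YAML/JSON mapping (the CLI entry path)."""
    chroms = [
        GenomeSpec(
            name=str(c["name"]),
            length=int(c["length"]),
            subgenome=str(c.get("subgenome", "")),
            is_donor=bool(c.get("donor", False)),
        )
        for c in data.get("chromosomes", [])
    ] or toy_genome()
    segments = [
        Segment(
            chromosome=str(s["chromosome"]),
            start_window=int(s["start_window"]),
            n_windows=int(s["n_windows"]),
            kind=str(s.get("kind", "LOW")),
            similarity=float(s.get("similarity", 0.5)),
            partner=s.get("partner"),
        )
        for s in data.get("segments", [])
    ]
    return SimulationConfig(
        chromosomes=chroms,
        window_size=int(data.get("window_size", TOY_WINDOW_SIZE)),
        baseline=float(data.get("baseline", DEFAULT_BASELINE)),
        noise_sd=float(data.get("noise_sd", DEFAULT_NOISE_SD)),
        segments=segments,
        mode=str(data.get("mode", "wgs")),
        seed=int(data.get("seed", 0)),
        sample=str(data.get("sample", "sim")),
    )


# -- read-level tier ------------------------------------------------------


def simulate_toy_sam(
    grid: WindowGrid,
    targets: np.ndarray,
    read_length: int = 100,
    n_decoys: int = 4,
    seed: int = 0,
) -> tuple[str, np.ndarray]:
    """Emit SAM text whose primary alignments realise per-window breadth targets.

    Each window receives ``round(target * window_length / read_length)``
    non-overlapping reads packed from its start, so the achieved breadth (the
    second return value) matches the target to within one
    read-length/window-length quantum.  ``n_decoys`` secondary (FLAG 256) and
    supplementary (FLAG 2048) records are interleaved at random positions;
    a correct FLAG filter must ignore them.
    """
    targets = np.asarray(targets, dtype=float)
    if targets.shape != (grid.n_windows,):
        raise ValueError("targets must hold one breadth per grid window")
    if read_length > grid.window_size:
        raise ValueError("read length must not exceed the window size")
    rng = np.random.default_rng(seed)

    records: list[tuple[int, int, str]] = []  # (chrom order, pos, line)
    achieved = np.zeros(grid.n_windows)
    chrom_order = {c.name: i for i, c in enumerate(grid.chromosomes)}
    qid = 0
    for w in range(grid.n_windows):
        chrom = grid.chrom_names[w]
        wstart, wend = int(grid.starts[w]), int(grid.ends[w])
        wlen = wend - wstart
        n_reads = int(round(targets[w] * wlen / read_length))
        if n_reads * read_length > wlen:
            raise ValueError(
                f"target {targets[w]:.3f} unachievable with non-overlapping "
                f"{read_length}-bp reads in a {wlen}-bp window"
            )
        for i in range(n_reads):
            pos = wstart + i * read_length
            records.append((chrom_order[chrom], pos, _sam_line(f"r{qid}", 0, chrom, pos, read_length)))
            qid += 1
        achieved[w] = n_reads * read_length / wlen

    for i in range(n_decoys):
        flag = 256 if i % 2 == 0 else 2048
        ci = int(rng.integers(len(grid.chromosomes)))
        chrom = grid.chromosomes[ci]
        pos = int(rng.integers(0, max(1, chrom.length - read_length)))
        records.append((ci, pos, _sam_line(f"decoy{i}", flag, chrom.name, pos, read_length)))

    records.sort(key=lambda r: (r[0], r[1]))
    header = ["@HD\tVN:1.6\tSO:coordinate"]
    header += [f"@SQ\tSN:{c.name}\tLN:{c.length}" for c in grid.chromosomes]
    return "\n".join(header + [r[2] for r in records]) + "\n", achieved


def _sam_line(qname: str, flag: int, chrom: str, pos: int, read_length: int) -> str:
    seq = "A" * read_length
    return (
        f"{qname}\t{flag}\t{chrom}\t{pos + 1}\t60\t{read_length}M\t*\t0\t0\t{seq}\t*"
    )


def subsample_reads(in_path, n_reads: int, seed: int, out_path) -> int:
    """Write a uniform random subset of primary records (decoys dropped).

    Header is preserved; record order is preserved.  Returns the number of
    records written.  Rejects ``n_reads`` beyond the available primaries.
    """
    import pysam

    with pysam.AlignmentFile(str(in_path)) as af:
        header = af.header
        primaries = [r for r in af if not (r.flag & 2308)]
    if n_reads > len(primaries):
        raise ValueError(f"requested {n_reads} reads but only {len(primaries)} primaries available")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(primaries), size=n_reads, replace=False))
    mode = "wb" if str(out_path).endswith(".bam") else "w"
    with pysam.AlignmentFile(str(out_path), mode, header=header) as out:
        for i in keep:
            out.write(primaries[i])
    return int(n_reads)


# -- depth-titration harness ----------------------------------------------

# Titration runs on 100-kb windows (not the 10-kb toy default): with 100-bp
# reads, per-window read counts are then large enough that a 10% breadth
# deficit (similarity 0.9) rises above read-sampling noise at read budgets a
# desk machine can draw.  The genome must also dwarf the implanted segment
# (as a real substitution is a few percent of the wheat genome) so the
# genome-wide median/MAD stay anchored to unaffected windows.
TITRATION_WINDOW_SIZE = 100_000
TITRATION_WINDOWS_PER_CHROM = 100


def _titration_genome() -> list[GenomeSpec]:
    length = TITRATION_WINDOWS_PER_CHROM * TITRATION_WINDOW_SIZE
    return [
        GenomeSpec("1A", length, subgenome="A"),
        GenomeSpec("1B", length, subgenome="B"),
        GenomeSpec("2A", length, subgenome="A"),
        GenomeSpec("2B", length, subgenome="B"),
    ]


def depth_titration(
    similarity: float,
    read_budgets: Sequence[int],
    seed: int,
    read_length: int = 100,
    segment_start_window: int = 10,
    segment_n_windows: int = 50,
    params: CallerParams | None = None,
) -> dict[int, bool]:
    """Detection of a simulated substitution across read budgets.

    A LOW segment of ``segment_n_windows`` windows (default 50, emulating the
    chromosome-arm-scale substitutions the titration question is about) with
    the given donor similarity is implanted on chromosome 1A; its homoeologue
    1B gains the re-mapped reads (weight ``1 + (1 - similarity)``).  For each budget,
    reads are placed by weighted position sampling, per-window breadth is
    computed, and WGS calling is run.  Detection = a LOW call covering at
    least half of the truth windows on 1A.  Each budget uses an independent
    seed derived from (seed, budget), so the detection outcome at one budget
    does not depend on which other budgets were evaluated.
    """
    if params is None:
        params = CallerParams()
    grid = build_grid(_titration_genome(), TITRATION_WINDOW_SIZE)

    weights = grid.window_lengths.astype(float).copy()
    sl_a = grid.chrom_slice("1A")
    sl_b = grid.chrom_slice("1B")
    seg = slice(sl_a.start + segment_start_window, sl_a.start + segment_start_window + segment_n_windows)
    weights[seg] *= similarity
    partner = slice(sl_b.start + segment_start_window, sl_b.start + segment_start_window + segment_n_windows)
    weights[partner] *= 1.0 + (1.0 - similarity)
    weights /= weights.sum()

    genome_offsets = np.zeros(len(grid.chromosomes) + 1, dtype=np.int64)
    for i, c in enumerate(grid.chromosomes):
        genome_offsets[i + 1] = genome_offsets[i] + c.length
    total_len = int(genome_offsets[-1])
    win_global_start = genome_offsets[grid.chrom_index] + grid.starts

    truth_lo, truth_hi = int(grid.starts[seg.start]), int(grid.ends[seg.stop - 1])
    out: dict[int, bool] = {}
    for budget in read_budgets:
        rng = np.random.default_rng([seed, int(budget)])
        win = rng.choice(grid.n_windows, size=int(budget), p=weights)
        max_off = grid.window_lengths[win] - read_length
        off = (rng.random(int(budget)) * np.maximum(max_off, 1)).astype(np.int64)
        starts = win_global_start[win] + off
        delta = np.zeros(total_len + 1, dtype=np.int32)
        np.add.at(delta, starts, 1)
        np.add.at(delta, np.minimum(starts + read_length, total_len), -1)
        depth = np.cumsum(delta[:-1])
        covered = depth > 0
        counts = np.add.reduceat(covered.astype(np.int64), win_global_start)
        values = counts / grid.window_lengths
        profile = CoverageProfile("titration", grid, values)
        calls = call_introgressions(profile, mode="wgs", params=params)
        detected = any(
            c.label == "LOW"
            and c.chromosome == "1A"
            and min(c.end, truth_hi) - max(c.start, truth_lo)
            >= (truth_hi - truth_lo) / 2
            for c in calls
        )
        out[int(budget)] = detected
    return out


def minimum_detectable_reads(
    similarity: float,
    read_budgets: Sequence[int],
    seed: int,
    **kwargs,
) -> int | None:
    """Smallest budget in the ascending ladder at which detection succeeds."""
    for budget in sorted(int(b) for b in read_budgets):
        if depth_titration(similarity, [budget], seed, **kwargs)[budget]:
            return budget
    return None
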