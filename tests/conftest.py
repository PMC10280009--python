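import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from introscan.caller import CallTrack
from introscan.genome_windows import GenomeSpec, WindowGrid, build_grid


@pytest.fixture
def toy_grid() -> WindowGrid:
    """Two host chromosomes, 100 windows of 10 kb each."""
    return build_grid(
        [
            GenomeSpec("1A", 1_000_000, subgenome="A"),
            GenomeSpec("1B", 1_000_000, subgenome="B"),
        ],
        10_000,
    )


@pytest.fixture
def wheatlike_grid() -> WindowGrid:
    """Three subgenomes x two chromosomes plus two donor chromosomes."""
    chroms = [
        GenomeSpec(f"{g}{tag}", 500_000, subgenome=tag)
        for tag in "ABD"
        for g in (1, 2)
    ]
    chroms += [
        GenomeSpec(f"{g}R", 500_000, subgenome="R", is_donor=True) for g in (1, 2)
    ]
    return build_grid(chroms, 10_000)


def grid_for(n_windows_by_chrom: dict[str, int], window_size: int = 10_000) -> WindowGrid:
    return build_grid(
        [GenomeSpec(name, n * window_size) for name, n in n_windows_by_chrom.items()],
        window_size,
    )


def track_from_arrays(
    labels_by_chrom: dict[str, np.ndarray],
    devs_by_chrom: dict[str, np.ndarray] | None = None,
    window_size: int = 10_000,
    sample: str = "t",
) -> CallTrack:
    """Build a CallTrack directly from per-chromosome label/deviation vectors."""
    grid = grid_for({k: len(v) for k, v in labels_by_chrom.items()}, window_size)
    labels = np.concatenate([np.asarray(v, dtype=np.int8) for v in labels_by_chrom.values()])
    if devs_by_chrom is None:
        dev = labels.astype(float)  # sign-consistent deviations by default
    else:
        dev = np.concatenate([np.asarray(devs_by_chrom[k], dtype=float) for k in labels_by_chrom])
    values = np.clip(0.1 + 0.05 * dev, 0.0, 1.0)
    return CallTrack(
        sample=sample,
        grid=grid,
        values=values,
        deviation=dev,
        labels=labels,
        masked=np.isnan(dev),
        stage=1,
    )
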