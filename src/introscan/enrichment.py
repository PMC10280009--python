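"""Per-window enrichment of introgression frequency between sample groups.

For every genome window, samples of two groups (e.g. elite cultivars versus
genebank accessions) are cross-tabulated by whether any of their calls
overlap the window, and a one-sided Fisher's exact test asks whether group 1
carries introgressions there more often.  Significant windows (after
multiple-testing adjustment) are merged into regions.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .caller import IntrogressionCall
from .genome_windows import WindowGrid

__all__ = ["window_enrichment", "fisher_one_sided", "adjust_and_merge", "presence_matrix"]


def fisher_one_sided(a, b, c, d):
    """Exact one-sided (greater-in-group-1) Fisher p for 2x2 tables.

    Under the null the count ``a`` of group-1 carriers follows a
    hypergeometric law with population a+b+c+d, a+c carriers, a+b draws;
    p = P(X >= a).  Vectorised over array inputs.
    """
    a, b, c, d = (np.asarray(x, dtype=np.int64) for x in (a, b, c, d))
    total = a + b + c + d
    carriers = a + c
    draws = a + b
    return stats.hypergeom.sf(a - 1, total, carriers, draws)


def presence_matrix(
    calls_by_sample: Mapping[str, Sequence[IntrogressionCall]],
    samples: Sequence[str],
    grid: WindowGrid,
) -> np.ndarray:
    """Boolean (sample, window) matrix: does any call of the sample overlap the window."""
    mat = np.zeros((len(samples), grid.n_windows), dtype=bool)
    for i, s in enumerate(samples):
        for call in calls_by_sample.get(s, ()):
            mat[i, grid.overlapping_windows(call.chromosome, call.start, call.end)] = True
    return mat


def window_enrichment(
    calls_by_sample: Mapping[str, Sequence[IntrogressionCall]],
    group1: Sequence[str],
    group2: Sequence[str],
    grid: WindowGrid,
) -> pd.DataFrame:
    """Per-window 2x2 counts and one-sided Fisher exact p-values.

    Columns: chromosome, start, end, a (group-1 carriers), b, c, d, p.
    """
    group1, group2 = list(group1), list(group2)
    if not group1 or not group2:
        raise ValueError("both sample groups must be non-empty")
    overlap = set(group1) & set(group2)
    if overlap:
        raise ValueError(f"groups are not disjoint: {sorted(overlap)}")
    m1 = presence_matrix(calls_by_sample, group1, grid)
    m2 = presence_matrix(calls_by_sample, group2, grid)
    a = m1.sum(axis=0)
    c = m2.sum(axis=0)
    b = len(group1) - a
    d = len(group2) - c
    return pd.DataFrame(
        {
            "chromosome": grid.chrom_names,
            "start": grid.starts,
            "end": grid.ends,
            "a": a,
            "b": b,
            "c": c,
            "d": d,
            "p": fisher_one_sided(a, b, c, d),
        }
    )


def adjust_and_merge(
    table: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "bh",
    gap_tolerance: int = 0,
) -> pd.DataFrame:
    """Adjust p-values, flag significant windows, merge them into regions.

    ``method``: 'bh' (Benjamini-Hochberg), 'bonferroni', or 'none'.  Flagged
    windows on one chromosome are merged into maximal regions allowing up to
    ``gap_tolerance`` unflagged windows between them.  Adds ``p_adj`` and
    ``significant`` columns to ``table`` in place; returns the region table
    (chromosome, start, end, n_windows, min_p_adj).
    """
    p = table["p"].to_numpy()
    if method == "bh":
        p_adj = stats.false_discovery_control(p, method="bh")
    elif method == "bonferroni":
        p_adj = np.minimum(p * p.size, 1.0)
    elif method == "none":
        p_adj = p.copy()
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    sig = p_adj <= alpha
    table["p_adj"] = p_adj
    table["significant"] = sig

    regions = []
    for chrom, sub in table.groupby("chromosome", sort=False):
        idx = np.flatnonzero(sub["significant"].to_numpy())
        if idx.size == 0:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        padj = sub["p_adj"].to_numpy()
        run = [idx[0]]
        for i in idx[1:]:
            if i - run[-1] - 1 <= gap_tolerance:
                run.append(i)
            else:
                regions.append(_region_row(chrom, run, starts, ends, padj))
                run = [i]
        regions.append(_region_row(chrom, run, starts, ends, padj))
    return pd.DataFrame(
        regions, columns=["chromosome", "start", "end", "n_windows", "min_p_adj"]
    )


def _region_row(chrom, run, starts, ends, padj):
    return {
        "chromosome": chrom,
        "start": int(starts[run[0]]),
        "end": int(ends[run[-1]]),
        "n_windows": len(run),
        "min_p_adj": float(padj[run].min()),
    }
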