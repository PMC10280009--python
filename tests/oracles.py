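"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: explicit while-loops over Python lists for the run
operations, and direct hypergeometric enumeration with exact integer
binomials for the one-sided Fisher p-value.  No numpy, no scipy.
"""

from math import comb


def _runs(labels):
    out = []
    i, n = 0, len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        out.append((i, j, labels[i]))
        i = j
    return out


def oracle_denoise(labels, min_seed_run):
    out = list(labels)
    for start, stop, value in _runs(labels):
        if value != 0 and stop - start < min_seed_run:
            for k in range(start, stop):
                out[k] = 0
    return out


def oracle_fill(labels, deviations):
    out = list(labels)
    labeled = [r for r in _runs(labels) if r[2] != 0]
    for (s1, e1, v1), (s2, e2, v2) in zip(labeled, labeled[1:]):
        if v1 != v2 or e1 == s2:
            continue
        gap = deviations[e1:s2]
        if any(d != d for d in gap):  # NaN: undefined evidence blocks filling
            continue
        if v1 == -1 and all(d < 0 for d in gap):
            for k in range(e1, s2):
                out[k] = -1
        elif v1 == 1 and all(d > 0 for d in gap):
            for k in range(e1, s2):
                out[k] = 1
    return out


def oracle_prune(labels, min_call_windows):
    out = list(labels)
    for start, stop, value in _runs(labels):
        if value != 0 and stop - start < min_call_windows:
            for k in range(start, stop):
                out[k] = 0
    return out


def oracle_fisher_greater(a, b, c, d):
    """P(X >= a) for X hypergeometric, by exact enumeration over the support."""
    r1, k = a + b, a + c
    n = a + b + c + d
    denom = comb(n, r1)
    hi = min(r1, k)
    return sum(comb(k, x) * comb(n - k, r1 - x) for x in range(a, hi + 1)) / denom


def oracle_fisher_less(a, b, c, d):
    r1, k = a + b, a + c
    n = a + b + c + d
    denom = comb(n, r1)
    lo = max(0, r1 - (n - k))
    return sum(comb(k, x) * comb(n - k, r1 - x) for x in range(lo, a + 1)) / denom
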