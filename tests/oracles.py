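"""Independent brute-force oracles the real implementations are checked against."""

from __future__ import annotations

import math

import numpy as np


def per_basepair_window_mean(arr: np.ndarray, bin_size: int, start: int, end: int) -> float | None:
    """Mean signal over [start, end) computed by looping over base pairs.

    Positions beyond the stored array read 0; the window is truncated at
    coordinate 0 and renormalized by the covered length.
    """
    start0 = max(start, 0)
    if end <= start0:
        return None
    total = 0.0
    for pos in range(start0, end):
        i = pos // bin_size
        total += arr[i] if i < len(arr) else 0.0
    return total / (end - start0)


def per_basepair_gene_signal(track_data, bin_size, tss_records, upstream, downstream,
                             strand_aware=True) -> dict[str, float]:
    """Max-over-TSS promoter means via the base-pair loop."""
    out: dict[str, float] = {}
    for gene_id, chrom, tss, strand in tss_records:
        if strand_aware and strand == "-":
            start, end = tss - downstream, tss + upstream
        else:
            start, end = tss - upstream, tss + downstream
        arr = track_data.get(chrom)
        if arr is None:
            m = 0.0
        else:
            m = per_basepair_window_mean(arr, bin_size, start, end)
            assert m is not None
        if gene_id not in out or m > out[gene_id]:
            out[gene_id] = m
    return out


def sweep_calibrate(b: np.ndarray, target: int) -> tuple[float, int]:
    """Exhaustive threshold search over every candidate (all distinct b values).

    Returns (theta, achieved_count) under the rule: exact match when
    attainable, otherwise minimize |count - target| breaking ties toward the
    larger count; target 0 places theta just above the maximum.
    """
    b = np.asarray(b, dtype=float)
    n = b.size
    if target == 0:
        return math.nextafter(float(b.max()), math.inf), 0
    candidates = sorted(set(float(x) for x in b))  # ascending
    best = None
    for theta in candidates:
        count = int((b >= theta).sum())
        diff = abs(count - target)
        # ascending candidates scan large counts first; strict improvement
        # keeps the larger-count (smaller-theta) tie winner
        if best is None or diff < best[0]:
            best = (diff, theta, count)
    _, theta, count = best
    if best[0] == 0:
        # exact: theta must equal the target-th largest b
        theta_expected = float(np.sort(b)[::-1][target - 1])
        assert theta == theta_expected
    return theta, count
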