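"""Independent brute-force oracles for burst search and peak alignment.

Deliberately naive: plain Python loops over bins and all-against-all
pair checks, sharing no code with the implementation they cross-check.
"""

from __future__ import annotations

import math


def brute_force_baseline(counts: list[int]) -> tuple[float, float]:
    """Median baseline and floored MAD sigma, by explicit sorting."""
    ordered = sorted(counts)
    n = len(ordered)

    def median(xs: list[float]) -> float:
        m = len(xs) // 2
        return float(xs[m]) if len(xs) % 2 else (xs[m - 1] + xs[m]) / 2.0

    base = median(ordered)
    mad = median(sorted(abs(x - base) for x in counts))
    sigma = max(1.4826 * mad, math.sqrt(max(base, 1.0)))
    return base, sigma


def brute_force_peaks(
    counts: list[int],
    bin_ms: float = 1.0,
    k_sigma: float = 5.0,
    min_width_bins: int = 1,
    merge_gap_bins: int = 0,
) -> list[tuple[int, int, int, float, float]]:
    """Enumerate threshold crossings bin by bin.

    Returns (start, end, apex, max_intensity, integrated_photons) tuples
    in order of start bin.
    """
    base, sigma = brute_force_baseline(list(counts))
    threshold = base + k_sigma * sigma

    runs: list[list[int]] = []
    in_run = False
    for i, c in enumerate(counts):
        if c > threshold:
            if not in_run:
                runs.append([i, i])
                in_run = True
            else:
                runs[-1][1] = i
        else:
            in_run = False

    if merge_gap_bins > 0:
        merged: list[list[int]] = []
        for run in runs:
            if merged and run[0] - merged[-1][1] - 1 <= merge_gap_bins:
                merged[-1][1] = run[1]
            else:
                merged.append(run)
        runs = merged

    out = []
    for start, end in runs:
        if end - start + 1 < min_width_bins:
            continue
        apex = start
        for i in range(start, end + 1):
            if counts[i] > counts[apex]:
                apex = i
        integral = sum(counts[start : end + 1]) - base * (end - start + 1)
        out.append(
            (start, end, apex, counts[apex] / bin_ms, max(0.0, integral))
        )
    return out


def brute_force_align(
    green_spans: list[tuple[int, int]],
    red_spans: list[tuple[int, int]],
    tolerance_bins: int = 0,
) -> list[tuple[int, int]]:
    """All-against-all overlap check on dilated spans, O(n*m)."""
    pairs = []
    for i, (gs, ge) in enumerate(green_spans):
        for j, (rs, re) in enumerate(red_spans):
            if max(gs - tolerance_bins, rs - tolerance_bins) <= min(
                ge + tolerance_bins, re + tolerance_bins
            ):
                pairs.append((i, j))
    return pairs
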