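"""Two-colour coincidence analysis: peak alignment and the colourQ statistic.

Simultaneous bursts in the two spectral channels indicate a heteromeric
assembly carrying both fluorophores. The directional interaction measure
is

    colourQ = (number of Colour-A peaks aligned with Colour-B peaks)
              / (total number of Colour-A peaks)

with redQ the fraction of green peaks aligned with red peaks and greenQ
the converse. Two peaks are *aligned* when their spans, each dilated by
a tolerance, intersect; an A peak overlapping several B peaks still
counts once, because the statistic counts peaks, not pairs. A chance
coincidence rate — the alignment fraction expected were the B channel an
independent uniform process — is reported alongside colourQ as a
diagnostic but never subtracted from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bursts import DetectionParams, Peak, detect_peaks
from .exceptions import UndefinedStatisticError, ValidationError
from .simulate import TimeTrace


@dataclass
class CoincidenceResult:
    """Peak counts, aligned pairs and the directional colourQ statistics.

    ``redq`` (fraction of green peaks aligned with red) or ``greenq`` is
    ``None`` when the corresponding channel detected no peaks, in which
    case the ratio is undefined.
    """

    n_green: int
    n_red: int
    n_green_aligned: int
    n_red_aligned: int
    redq: float | None
    greenq: float | None
    pairs: list[tuple[int, int]]
    chance_rate: float
    green_peaks: list[Peak]
    red_peaks: list[Peak]


def _check_sorted_disjoint(peaks: list[Peak], label: str) -> None:
    for prev, cur in zip(peaks, peaks[1:]):
        if cur.start_bin <= prev.end_bin:
            raise ValidationError(
                f"{label} peaks must be sorted and non-overlapping"
            )


def align_peaks(
    green_peaks: list[Peak], red_peaks: list[Peak], tolerance_bins: int = 0
) -> list[tuple[int, int]]:
    """All (green index, red index) pairs whose dilated spans intersect.

    Both lists must be sorted by start bin and non-overlapping within
    their channel (as ``detect_peaks`` returns them); the sweep is then a
    single linear pass plus the size of the output.
    """
    if tolerance_bins < 0:
        raise ValidationError("tolerance_bins must be >= 0")
    _check_sorted_disjoint(green_peaks, "green")
    _check_sorted_disjoint(red_peaks, "red")

    pairs: list[tuple[int, int]] = []
    j = 0
    for i, g in enumerate(green_peaks):
        g_start = g.start_bin - tolerance_bins
        g_end = g.end_bin + tolerance_bins
        while j < len(red_peaks) and red_peaks[j].end_bin + tolerance_bins < g_start:
            j += 1
        k = j
        while k < len(red_peaks) and red_peaks[k].start_bin - tolerance_bins <= g_end:
            pairs.append((i, k))
            k += 1
    return pairs


def colour_q(
    peaks_a: list[Peak], peaks_b: list[Peak], tolerance_bins: int = 0
) -> float:
    """Fraction of A peaks aligned with at least one B peak.

    Raises :class:`UndefinedStatisticError` when there are no A peaks:
    the ratio has no value then and returning 0 would fake a measurement.
    """
    if not peaks_a:
        raise UndefinedStatisticError(
            "colourQ is undefined when the A channel has no peaks"
        )
    pairs = align_peaks(peaks_a, peaks_b, tolerance_bins)
    aligned_a = {i for i, _ in pairs}
    return len(aligned_a) / len(peaks_a)


def chance_coincidence(
    n_red_peaks: int,
    mean_red_width_bins: float,
    n_bins: int,
    tolerance_bins: int = 0,
    mean_green_width_bins: float = 1.0,
) -> float:
    """Expected aligned fraction of A peaks under an independent B channel.

    If B peaks were placed uniformly over the record, a given A peak of
    width w_A intersects a B peak of width w_B (both dilated by the
    alignment tolerance) unless the B start avoids a window of
    w_A + w_B - 1 + 2*tol bins, so the chance of touching none of n_B
    independent peaks is the Poisson void probability:

        P(aligned by chance) = 1 - exp(-n_B * (w_A + w_B - 1 + 2*tol) / n_bins).

    The default w_A = 1 treats the A peak as point-like; pass the mean
    detected A width (as :func:`run_ccs` does) for extended bursts.
    Monotone increasing in every argument and -> 1 as occupancy grows.
    """
    if n_bins <= 0:
        raise ValidationError("n_bins must be > 0")
    if (
        n_red_peaks < 0
        or mean_red_width_bins < 0
        or tolerance_bins < 0
        or mean_green_width_bins < 1
    ):
        raise ValidationError("counts, widths and tolerance out of range")
    window = mean_green_width_bins + mean_red_width_bins - 1 + 2 * tolerance_bins
    return 1.0 - math.exp(-n_red_peaks * window / n_bins)


def run_ccs(
    trace: TimeTrace,
    det: DetectionParams | None = None,
    tolerance_bins: int = 0,
) -> CoincidenceResult:
    """Full coincidence analysis of one trace.

    Detects peaks in both channels, aligns them, and computes redQ,
    greenQ and the chance-coincidence diagnostic. Deterministic for a
    fixed trace.
    """
    green = detect_peaks(trace, "green", det)
    red = detect_peaks(trace, "red", det)
    pairs = align_peaks(green, red, tolerance_bins)
    aligned_g = {i for i, _ in pairs}
    aligned_r = {j for _, j in pairs}

    mean_red_width = (
        float(np.mean([p.width_bins for p in red])) if red else 0.0
    )
    mean_green_width = (
        float(np.mean([p.width_bins for p in green])) if green else 1.0
    )
    chance = chance_coincidence(
        len(red),
        mean_red_width,
        trace.n_bins,
        tolerance_bins,
        mean_green_width_bins=max(1.0, mean_green_width),
    )
    return CoincidenceResult(
        n_green=len(green),
        n_red=len(red),
        n_green_aligned=len(aligned_g),
        n_red_aligned=len(aligned_r),
        redq=len(aligned_g) / len(green) if green else None,
        greenq=len(aligned_r) / len(red) if red else None,
        pairs=pairs,
        chance_rate=chance,
        green_peaks=green,
        red_peaks=red,
    )
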