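"""Brute-force reference implementations used to cross-check the package.

These stay independent of the code paths they validate: local maxima and
prominences are found by exhaustive scanning from the definitions (a local
maximum is a sample whose neighbouring samples are smaller; prominence is
the height above the lowest contour line to higher terrain or the array
edge), and N50 by testing every candidate length against its definition.
"""

from __future__ import annotations

import numpy as np


def brute_force_local_maxima(y) -> list[tuple[int, int, int]]:
    """All strict local maxima of y as (midpoint, start, end) index triples.

    Plateaus (runs of equal values) count as a single maximum when the
    samples on both sides of the run are strictly smaller; the reported
    position is the plateau midpoint (rounded down).  Samples at the array
    edges cannot be maxima.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    out = []
    i = 1
    while i < n - 1:
        if y[i - 1] < y[i]:
            start = i
            while i < n - 1 and y[i + 1] == y[i]:
                i += 1
            if i < n - 1 and y[i + 1] < y[i]:
                out.append(((start + i) // 2, start, i))
        i += 1
    return out


def brute_force_prominence(y, peak_idx: int) -> float:
    """Prominence of the peak at peak_idx, from the contour-line definition.

    Extend left/right from the peak until the array edge or a strictly
    higher sample; the higher of the two interval minima is the contour
    base; prominence is the peak height minus that base.
    """
    y = np.asarray(y, dtype=float)
    h = y[peak_idx]
    i = peak_idx
    left_min = h
    while i > 0 and y[i - 1] <= h:
        i -= 1
        left_min = min(left_min, y[i])
    j = peak_idx
    right_min = h
    while j < len(y) - 1 and y[j + 1] <= h:
        j += 1
        right_min = min(right_min, y[j])
    return float(h - max(left_min, right_min))


def brute_force_peaks(y, min_height: float = 0.0, min_prominence: float = 0.0):
    """Filtered (position, height, prominence) triples, sorted by position."""
    y = np.asarray(y, dtype=float)
    out = []
    for mid, start, _end in brute_force_local_maxima(y):
        h = float(y[start])
        prom = brute_force_prominence(y, start)
        if h >= min_height and prom >= min_prominence:
            out.append((mid, h, prom))
    return out


def brute_force_width_crossings(y, peak_idx: int, eval_height: float) -> tuple[float, float]:
    """Interpolated x where the curve crosses eval_height on each side of the peak.

    Scans outward from the peak for the first sample below the evaluation
    height and interpolates linearly; clips to the array edges.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    i = peak_idx
    while i > 0 and y[i] > eval_height:
        i -= 1
    if y[i] > eval_height:
        left = 0.0
    else:
        left = i + (eval_height - y[i]) / (y[i + 1] - y[i])
    j = peak_idx
    while j < n - 1 and y[j] > eval_height:
        j += 1
    if y[j] > eval_height:
        right = float(n - 1)
    else:
        right = j - (eval_height - y[j]) / (y[j - 1] - y[j])
    return float(left), float(right)


def brute_force_n50(lengths) -> int:
    """Largest contig length L with sum(lengths >= L) covering half the total."""
    lengths = list(lengths)
    half = sum(lengths) / 2.0
    candidates = [L for L in set(lengths) if sum(x for x in lengths if x >= L) >= half]
    return max(candidates)


def brute_force_tail_filter(counts: dict, quantile: float) -> dict:
    """Ascending cumulative scan keeping bins up to the quantile crossing."""
    total = sum(counts.values())
    kept, cum = {}, 0
    for cov in sorted(counts):
        kept[cov] = counts[cov]
        cum += counts[cov]
        if cum >= quantile * total:
            break
    return kept
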