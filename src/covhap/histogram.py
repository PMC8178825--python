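"""Coverage histograms and the two pre-filters applied before peak finding.

The central data structure is a frequency histogram mapping integer read
depth (coverage, in X) to the number of assembly bases observed at that
depth.  Before any peak detection the histogram is (1) truncated at the
high-coverage tail, which otherwise contains sparse repeat-driven bins that
confuse peak finding, and (2) smoothed with a Savitzky-Golay filter, a
moving least-squares polynomial smoother that preserves peak shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "CoverageHistogram",
    "TailFilterParams",
    "SmoothingParams",
    "SmoothedCurve",
    "build_histogram",
    "filter_tail",
    "smooth",
]


@dataclass(frozen=True)
class CoverageHistogram:
    """Frequency histogram of per-base read depth.

    Parameters
    ----------
    counts
        Mapping from coverage value (integer >= 0, units: X) to the number
        of bases observed at that coverage.
    source
        Free-text provenance tag (file name, simulation id, ...).
    """

    counts: dict[int, int]
    source: str = ""

    def __post_init__(self) -> None:
        for cov, n in self.counts.items():
            if cov < 0:
                raise ValueError(f"negative coverage bin: {cov}")
            if n < 0:
                raise ValueError(f"negative count at coverage {cov}: {n}")

    @property
    def total_bases(self) -> int:
        return sum(self.counts.values())

    @property
    def max_coverage(self) -> int:
        if not self.counts:
            raise ValueError("empty histogram has no max coverage")
        return max(self.counts)

    def to_dense(self) -> np.ndarray:
        """Dense count array over 0..max_coverage; absent bins are zero."""
        arr = np.zeros(self.max_coverage + 1, dtype=np.int64)
        for cov, n in self.counts.items():
            arr[cov] = n
        return arr


@dataclass(frozen=True)
class TailFilterParams:
    """Cumulative-mass truncation threshold for the high-coverage tail."""

    quantile: float = 0.99

    def __post_init__(self) -> None:
        if not 0 < self.quantile <= 1:
            raise ValueError(f"quantile must be in (0, 1], got {self.quantile}")


@dataclass(frozen=True)
class SmoothingParams:
    """Savitzky-Golay filter settings (units of window: coverage bins)."""

    window_length: int = 41
    poly_degree: int = 3

    def __post_init__(self) -> None:
        if self.window_length < 1 or self.window_length % 2 == 0:
            raise ValueError(f"window_length must be odd positive, got {self.window_length}")
        if self.poly_degree < 0:
            raise ValueError(f"poly_degree must be >= 0, got {self.poly_degree}")
        if self.poly_degree >= self.window_length:
            raise ValueError("poly_degree must be smaller than window_length")


@dataclass(frozen=True)
class SmoothedCurve:
    """Dense smoothed frequency curve over an ascending coverage axis."""

    coverage_bins: np.ndarray
    values: np.ndarray
    params: SmoothingParams = field(default_factory=SmoothingParams)

    def __post_init__(self) -> None:
        if len(self.coverage_bins) != len(self.values):
            raise ValueError("coverage_bins and values must have equal length")
        if len(self.coverage_bins) > 1 and not np.all(np.diff(self.coverage_bins) > 0):
            raise ValueError("coverage_bins must be strictly ascending")


def build_histogram(
    depths, *, include_zero: bool = False, source: str = ""
) -> CoverageHistogram:
    """Count per-base depths into a coverage histogram.

    Depth-0 positions are unmapped or uncalled bases; by default they are
    excluded so they cannot seed a spurious low-coverage peak.  Pass
    ``include_zero=True`` to keep them.
    """
    arr = np.asarray(depths)
    if arr.size == 0:
        raise ValueError("no coverage data")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError("depths must be integers")
        arr = arr.astype(np.int64)
    if np.any(arr < 0):
        raise ValueError("negative depth values are not valid")
    values, freqs = np.unique(arr, return_counts=True)
    counts = {int(v): int(f) for v, f in zip(values, freqs)}
    if not include_zero:
        counts.pop(0, None)
    if not counts:
        raise ValueError("no coverage data (all positions at depth 0)")
    return CoverageHistogram(counts=counts, source=source)


def filter_tail(
    hist: CoverageHistogram, params: TailFilterParams = TailFilterParams()
) -> CoverageHistogram:
    """Truncate the sparse high-coverage tail of the histogram.

    Scanning bins in ascending coverage order, a running sum of counts is
    kept; the first bin at which the running sum reaches ``quantile`` of the
    total is retained, and all strictly higher bins are dropped.  At least
    ``quantile`` of the base mass is always kept, and applying the filter
    twice equals applying it once.
    """
    if not hist.counts:
        raise ValueError("empty histogram")
    threshold = params.quantile * hist.total_bases
    kept: dict[int, int] = {}
    running = 0
    for cov in sorted(hist.counts):
        kept[cov] = hist.counts[cov]
        running += hist.counts[cov]
        if running >= threshold:
            break
    return CoverageHistogram(counts=kept, source=hist.source)


def smooth(
    hist: CoverageHistogram, params: SmoothingParams = SmoothingParams()
) -> SmoothedCurve:
    """Savitzky-Golay smooth of the dense histogram curve.

    The histogram is densified over 0..max_coverage (absent bins = 0)
    because the filter assumes equally spaced samples.  If the dense curve
    is shorter than the window, the window shrinks to the largest odd
    integer <= curve length (the polynomial degree is reduced below it if
    necessary), so small fixtures remain smoothable.  Negative filtered
    values are clamped to 0: frequencies cannot be negative.
    """
    if len(hist.counts) < 2:
        raise ValueError("curve too short to smooth")
    dense = hist.to_dense().astype(float)
    n = len(dense)
    window = params.window_length
    degree = params.poly_degree
    if window > n:
        window = n if n % 2 == 1 else n - 1
        if degree >= window:
            degree = window - 1
    smoothed = savgol_filter(dense, window_length=window, polyorder=degree)
    np.clip(smoothed, 0.0, None, out=smoothed)
    effective = SmoothingParams(window_length=window, poly_degree=degree)
    return SmoothedCurve(
        coverage_bins=np.arange(n, dtype=np.int64),
        values=smoothed,
        params=effective,
    )
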